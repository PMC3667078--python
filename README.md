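# accmine

Rule-based mining and analysis of biological database accession-number
citations in full-text JATS XML articles.

## The problem

Life-science articles cite database records — nucleotide sequences in the
European Nucleotide Archive (ENA/GenBank/DDBJ), proteins in UniProt,
macromolecular structures in the PDB — by their accession numbers.  Some
publishers tag these citations structurally in the article XML
(`<ext-link ext-link-type="pdb" xlink:href="1EWK">1EWK</ext-link>`), but
most accession mentions exist only as plain text.  Recovering them by text
mining roughly doubles the number of machine-readable literature–database
links, which matters for data-citation metrics, database curation and
integrated literature services.

`accmine` is for corpus maintainers and text-mining researchers who want a
deterministic, high-precision accession tagger plus the evaluation and
reporting machinery to measure it.

## The method

Annotation is a three-step filter cascade:

1. **Article gate.** An article is processed only if a trigger term
   (a database cue word or *accession*) occurs somewhere in its minable
   text. Reference lists are never mined; back-matter footnotes are mined
   only on request.
2. **Sentence-level candidates.** Cue words present in a sentence (or,
   by default, its enclosing paragraph) select which databases' shape
   grammars apply. A shape is a positional character-class pattern, e.g.
   ENA `[A-Z]{2}[0-9]{6}`, UniProt `[OPQ][0-9][A-Z0-9]{3}[0-9]`, PDB
   `[0-9][A-Z0-9]{3}`. Tokens must be delimited by non-alphanumerics;
   accession ranges (`EF151088–EF151123`) contribute their endpoints, or
   the full inclusive sequence with `expand_ranges`. A token that fails
   the cued database's shapes but uniquely matches another enabled
   database is *rescued* to that database.
3. **Validation.** Each candidate is looked up in its target database
   (a whitelist file stands in for the live resource); candidates not
   found are removed. This is what eliminates shape-valid decoys such as
   four-digit years, which match the PDB shape.

Scoring uses precision = TP/(TP+FP), recall = TP/(TP+FN) and
F = 2PR/(P+R) over unique (article, database, accession) tuples, with an
*automatic* protocol (publisher tags as gold) and a *manual* protocol in
which human-adjudicated false positives are reassigned as true positives.
Corpus analytics cover publisher/mined Venn overlaps, annotated-article
fractions, per-year citation trends, citations per database record and
per-journal mark-up efficacy.

Extension databases (Ensembl, Pfam, InterPro, ArrayExpress) are supported
with shapes taken from the public identifier-format guidelines.

## Worked example

```sh
accmine simulate --n 8 --seed 1 --out corpus/
accmine mine --in corpus/articles --whitelist corpus/whitelist.tsv --out mined.jsonl
accmine publisher-tags --in corpus/articles --out publisher.jsonl
accmine evaluate --mined mined.jsonl --gold publisher.jsonl --out report.tsv
accmine stats --in corpus/articles --publisher publisher.jsonl --mined mined.jsonl --out stats/
```

which prints

```
wrote 8 articles to corpus/articles
12 mentions -> mined.jsonl
7 publisher mentions -> publisher.jsonl
report -> report.tsv
reports -> stats
```

This corpus plants 14 accession citations with same-sentence cue words (12
in body text, 2 in footnotes), wraps a journal-policy-dependent subset (7)
in publisher `ext-link` mark-up, and adds shape-matching decoys.  Default
mining finds exactly the 12 body citations and no decoys.  `report.tsv`
then reads

```
scope	tp	fp	fn	precision	recall	f_score
ENA	4	5	2	44.44%	66.67%	53.33%
PDB	1	2	0	33.33%	100.00%	50.00%
```

against the publisher tags as gold: the two false negatives are the
footnote citations (publisher tagging covers footnotes, default mining
does not — rerun `mine` with `--include-footnotes` to recover them), and
the nominal "false positives" are correct mined citations the publisher
never tagged — exactly the situation the manual adjudication protocol
exists for.  `stats/` holds the publisher-vs-mined overlap, per-year and
per-journal tables.

The same operations are available as a library:

```python
from accmine import AnaConfig, Whitelist, annotate_article, Database
wl = Whitelist.from_pairs([(Database.PDB, a) for a in ("1J4N", "1FX8", "1RC2")])
mentions = annotate_article(article, AnaConfig(), resolver=wl)
```

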