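# Methods

## The annotation model

`accmine` treats accession-number recognition as a three-stage filter
cascade rather than a statistical tagger. The design premise is that an
accession citation is jointly signalled by three nearly independent kinds
of evidence — a token whose *shape* fits a database's identifier format, a
nearby *cue word* naming the database, and *existence* of the identifier in
the database — and that requiring all three yields very high precision at
some cost in recall. Each stage is deterministic, so identical input and
configuration always produce identical mentions.

**Stage 1 — article gate.** An article yields candidates only if at least
one trigger term occurs as a whole, case-insensitive token in its minable
sentences. The trigger vocabulary is the union of all sentence-level cues
plus the word *accession*. The gate is global (any term opens the article
for all databases); per-database gating would interact badly with
cross-database rescue, which by construction involves a token cued by one
database and resolved by another.

**Stage 2 — candidates.** Sentences come from the zoned document model
(below). A sentence's cued databases are those with a cue token in the
sentence itself; if a sentence has none, the union of cues over its
enclosing paragraph is used (`cue_scope="sentence-then-paragraph"`,
the default). The strict `"sentence"` scope is available because multi-
sentence deposition statements ("Accessions are listed below. The list is
…") are common enough that the paragraph fallback is the more useful
default, but the sentence-only behaviour is the purer reading of the
cue model. For every cued database, all shape-matching tokens delimited by
non-alphanumerics become candidates. Hyphens count as delimiters, which is
what makes a structure subchain spelled `1RC2-B` yield the bare accession
`1RC2` (the chain letter can be kept in mention provenance with
`record_chain_suffix`).

**Stage 3 — validation.** A candidate survives only if the resolver
confirms the (database, accession) pair. The resolver contract is exact
set membership over normalized accessions (uppercased, `.N` version
suffix stripped); the shipped implementation is a whitelist TSV, standing
in for live ENA/UniProt/PDBe lookups so that runs are deterministic and
testable offline. Identifier families absent from the whitelist — e.g.
RefSeq accessions, which are GenBank-cued in articles but are not ENA
records — are silently removed at this stage, which is the desired
behaviour.

### Cross-database rescue

A token that fails every cued database's shapes but matches the shape
grammar of exactly one other enabled database is reassigned to that
database, flagged `rescued` in provenance. Rescue exists because stated
sources are sometimes wrong (a protein accession cited "[Genbank Q8WUM6]"
is really a UniProt record). Rescue is deliberately conservative: it
requires a unique alternative shape match *and* successful validation, so
it is generated only when validation is enabled; with `--no-validate`
rescued candidates are suppressed rather than emitted unchecked, since
without the existence check the rescue heuristic alone would admit noise
(any four-digit year in a GenBank-cued sentence matches the PDB shape).

### Ranges

Two same-database shape matches joined by only a dash (hyphen-minus, en
dash, em dash or minus sign, optionally spaced) form a range. By default
only the endpoints are tagged — the paper-faithful behaviour of tagging
what is literally written. With `expand_ranges` the full inclusive
arithmetic sequence over the numeral part is generated, zero-padded to the
endpoints' width; endpoints must share letter prefix and numeral width and
be non-descending, else the range is rejected and the endpoints stand
alone. Interior accessions carry the whole range's character span and
`range` provenance, and are validated individually like any candidate.

## Shape grammars

Shapes are stored structurally (runs of character classes with repeat
bounds), not as opaque regex strings. One definition drives three
consumers: compilation to an anchored regex alternation for matching, a
recursive position-by-position reference checker used as an independent
oracle in tests, and uniform random sampling of valid accessions in the
synthetic generator.

Core shapes: ENA uses five letter+digit profiles (1+5, 2+6, 3+5, 4+8–10,
5+7); the 8–10 bound is read as an inclusive range. UniProt uses the two
six-character profiles `[A-N,R-Z][0-9][A-Z][A-Z0-9]{2}[0-9]` and
`[OPQ][0-9][A-Z0-9]{3}[0-9]`; PDB uses `[0-9][A-Z0-9]{3}`. The PDB shape
intentionally matches four-digit years — disambiguation is the job of
cues and validation, not the shape matcher. Extension shapes (Pfam
`PF\d{5}`, InterPro `IPR\d{6}`, ArrayExpress `E-XXXX-n`, Ensembl
`ENS[letters][GTPE]\d{11}`, with the species and feature-type letters
folded into one bounded letter run) follow the public format guidelines of
each resource and are marked `provenance="external-guideline"`; all shapes
and cue vocabularies are overridable through a YAML config
(`dump_grammar_config`/`load_grammar_config`).

Matching is case-insensitive with spans over the original sentence text;
the matched token is normalized (uppercased, version-stripped) separately,
so offsets never shift. Tokens must be delimited by non-alphanumerics on
both sides: `(AY762362)` matches, `XAY762362` does not.

## Document model

JATS XML is reduced to ordered sentences, each labelled with a zone:
`front`, `body`, `back`, `footnote` or `reference_list`. Mining consumes
`body` by default; `footnote` is opt-in; `reference_list` is never mined
(bibliographies are full of accession-shaped tokens in a citation context
that does not assert use of the record). Publisher `ext-link` extraction
runs over the whole tree regardless of zoning, because publisher tagging
does cover footnotes. Figure and table captions are zoned as body text;
whether the original pipeline did the same is not documented, so this
choice is flagged as unverified.

Sentence segmentation is a rule-based splitter: split after `.!?` followed
by whitespace and an uppercase/digit/bracket opener, then re-join splits
whose left side ends in a guarded abbreviation (Fig., et al., no., e.g.,
…). It conserves non-whitespace characters and never emits an empty
sentence. Articles with no parseable publication year are mined normally
but excluded from per-year statistics.

## Evaluation semantics

TP/FP/FN are counted over unique (article, database, accession) tuples by
default, because publisher tags and mined tags can differ in multiplicity
for the same citation; an occurrence-level mode exists behind a flag.
Metrics with a zero denominator are reported as explicitly undefined,
never silently zero; F is undefined unless both P and R are defined, and
F = 0 when P = R = 0. Percentages are formatted half-up at two decimals.
Adjudication moves one FP to TP per verified verdict and never touches FN,
conserving TP+FP — the arithmetic of the manual protocol exactly as the
benchmark table applies it.

## The synthetic corpus

The generator emulates the features of a real open-access corpus that the
pipeline is sensitive to, and nothing else: deposition-statement sentences
with same-sentence cues, a publisher-tagged subset governed by per-journal
policy (`high` journals tag everything, `zero` journals nothing,
`partial` journals at the configured fraction), citations placed in
back-matter footnotes at a configurable fraction, and three decoy classes
drawn from the pipeline's false-positive risk surface: calendar years
under a PDB cue, shape-valid tokens with no cue, and cued shape-valid
tokens absent from the whitelist. Default rates (50 articles; mean
citations per article ENA 1.2, PDB 0.6, UniProt 0.3; publisher-tag
fraction 0.6; one decoy per article; footnote fraction 0.05; years
1990–2012) mirror the qualitative structure of the real corpus: ENA
citations most numerous, publisher tagging covering a majority but not
all citations, footnote placement rare.

All randomness flows from one seed through a single PRNG, so a spec is
byte-reproducible. Citation planning happens in a first pass and decoy
sampling in a second, so "unlisted" decoys can be rejection-sampled
against the completed whitelist; accession sampling also rejects all-digit
draws (possible under the PDB shape) so a planted accession can never
collide with a year decoy.

What the generator does *not* model — and therefore what passing tests do
not show about real articles: linguistic variety beyond the template bank,
cue-less citation constructs, OCR noise, tables, accession ranges in
running text, and the real corpus's scale. End-to-end synthetic results
(100% precision with a complete whitelist, 100% recall on cue-complete
body plantings) verify the pipeline's mechanics under its own model
assumptions; published corpus-scale performance figures are reproduced
only at the level of their arithmetic, not re-measured.

## Numerical and interface choices

- Character spans are 0-based half-open over normalized sentence text.
- Mentions are ordered by sentence index, span start, database, accession.
- When `xlink:href` and element text disagree in an `ext-link`, href wins
  and the disagreement is logged.
- A token matching shapes of several cued databases is emitted for every
  database whose validation succeeds, flagged `ambiguous`.
- Duplicate occurrences of an accession within an article are all
  recorded; de-duplication happens at evaluation/reporting level.
- Problem sizes in the test suite and the acceptance script (50-article
  corpora, exhaustive shape-oracle comparison over strings of length ≤ 6
  on a four-letter alphabet) are chosen as the smallest sizes at which
  every modelled behaviour (footnote misses, decoy rejection, per-journal
  banding) actually occurs.

## Known limitations

- RefSeq identifiers are handled only negatively (discarded at
  validation); there is no RefSeq grammar.
- Live REST validation is specified by the resolver contract but not
  shipped; the whitelist is the only bundled implementation.
- The per-journal "high" band threshold (>98% of the publisher∪mined
  superset) reproduces a qualitative description; it is configuration,
  not a measured constant.
- Sentence segmentation is heuristic; pathological abbreviation patterns
  can still split or merge sentences, which only affects cue locality,
  not shape matching.
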