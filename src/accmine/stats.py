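"""Corpus-level reporting on accession citations.

Covers the analytics a corpus maintainer wants from a mined article set:
how publisher tagging and text mining overlap, what fraction of articles
cite database records at all, how citation volume develops per publication
year, how heavily each database's records are cited relative to database
size, how tagging efficacy varies by journal, and how article-to-database
citations compare with the reverse links registered inside databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .databases import Database
from .jats import Article, Mention


@dataclass(frozen=True)
class OverlapReport:
    only_a: int
    only_b: int
    both: int
    key: str = ""

    @property
    def total(self) -> int:
        return self.only_a + self.only_b + self.both

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both

    def recovery_of_a(self) -> float | None:
        """Fraction of A's elements also found in B (e.g. publisher tags
        recovered by mining)."""
        return self.both / self.size_a if self.size_a else None


@dataclass(frozen=True)
class RateStats:
    database: Database
    total_annotations: int
    database_size: int
    citations_per_record: float


@dataclass(frozen=True)
class LinkRecord:
    database: Database
    accession: str
    article_id: str
    direction: str  # "article_to_db" | "db_to_article"

    def __post_init__(self) -> None:
        if self.direction not in ("article_to_db", "db_to_article"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def key(self) -> tuple:
        return (self.database, self.accession, self.article_id)


def _round(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def mention_key(m: Mention, key: str) -> tuple:
    if key == "pair":
        return (m.database, m.accession, m.article_id)
    if key == "accession":
        return (m.database, m.accession)
    raise ValueError(f"unknown overlap key {key!r}")


def overlap(a: Iterable, b: Iterable, key: str = "pair") -> OverlapReport:
    """Venn counts between two mention or link collections.

    ``key='pair'`` compares (database, accession, article) tuples --
    appropriate both for publisher-vs-mined and for article↔database link
    comparison; ``key='accession'`` collapses to (database, accession).
    Plain tuples/hashables pass through unchanged.
    """

    def keyed(items: Iterable) -> set:
        out = set()
        for item in items:
            if isinstance(item, Mention):
                out.add(mention_key(item, key))
            elif isinstance(item, LinkRecord):
                out.add(item.key())
            else:
                out.add(item)
        return out

    sa, sb = keyed(a), keyed(b)
    return OverlapReport(
        only_a=len(sa - sb), only_b=len(sb - sa), both=len(sa & sb), key=key
    )


def annotated_fraction(n_annotated: int, n_total: int, decimals: int = 2) -> float:
    """Percentage of articles carrying accession citations, half-up rounded."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_annotated > n_total:
        raise ValueError("n_annotated exceeds n_total")
    return _round(100.0 * n_annotated / n_total, decimals)


def citations_per_record(
    total_annotations: int, database_size: int, decimals: int | None = None
) -> float:
    """Citation count relative to the number of records in the database."""
    if database_size <= 0:
        raise ValueError("database_size must be positive")
    ratio = total_annotations / database_size
    return ratio if decimals is None else _round(ratio, decimals)


def rate_stats(
    totals: Mapping[Database, int],
    db_sizes: Mapping[Database, int],
    decimals: Mapping[Database, int] | None = None,
) -> list[RateStats]:
    out = []
    for db in sorted(totals, key=lambda d: d.value):
        nd = (decimals or {}).get(db, 2)
        out.append(
            RateStats(db, totals[db], db_sizes[db],
                      citations_per_record(totals[db], db_sizes[db], nd))
        )
    return out


def per_year_stats(
    articles: Iterable[Article],
    mentions: Iterable[Mention],
    exclude_years: Sequence[int] = (),
) -> pd.DataFrame:
    """Per (year, database): total citations and mean per citing article.

    Articles without a parseable year are excluded; the mean is computed
    over citing articles only (articles with ≥1 mention of that database in
    that year).  ``exclude_years`` drops incomplete years from the report.
    """
    year_of = {a.article_id: a.year for a in articles if a.year is not None}
    rows = [
        {"year": year_of[m.article_id], "database": m.database.value,
         "article_id": m.article_id}
        for m in mentions
        if m.article_id in year_of
    ]
    if not rows:
        return pd.DataFrame(
            columns=["year", "database", "total_citations",
                     "n_citing_articles", "mean_per_citing_article"]
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["year", "database"])
        .agg(
            total_citations=("article_id", "size"),
            n_citing_articles=("article_id", "nunique"),
        )
        .reset_index()
    )
    grouped = grouped[~grouped["year"].isin(list(exclude_years))]
    grouped["mean_per_citing_article"] = (
        grouped["total_citations"] / grouped["n_citing_articles"]
    )
    return grouped.sort_values(["year", "database"]).reset_index(drop=True)


def per_journal_report(
    articles: Iterable[Article],
    publisher_mentions: Iterable[Mention],
    mined_mentions: Iterable[Mention],
    high_threshold: float = 0.98,
) -> pd.DataFrame:
    """Publisher mark-up efficacy per journal.

    For each journal: article count, publisher-annotated article count, and
    the fraction of the publisher∪mined citation superset that carries
    publisher tags.  Journals split into bands: ``high`` (fraction above the
    threshold), ``zero`` (no publisher tags despite mined citations) and
    ``partial`` in between; journals whose superset is empty band as
    ``none``.
    """
    journal_of = {a.article_id: (a.journal or "<unknown>") for a in articles}
    pub_keys = {
        (m.database, m.accession, m.article_id) for m in publisher_mentions
    }
    superset = pub_keys | {
        (m.database, m.accession, m.article_id) for m in mined_mentions
    }
    rows = []
    for journal in sorted({j for j in journal_of.values()}):
        ids = {aid for aid, j in journal_of.items() if j == journal}
        sup_j = {k for k in superset if k[2] in ids}
        pub_j = {k for k in pub_keys if k[2] in ids}
        if sup_j:
            frac = len(pub_j) / len(sup_j)
            if frac > high_threshold:
                band = "high"
            elif frac == 0.0:
                band = "zero"
            else:
                band = "partial"
        else:
            frac, band = None, "none"
        rows.append(
            {
                "journal": journal,
                "n_articles": len(ids),
                "n_publisher_annotated_articles": len({k[2] for k in pub_j}),
                "superset_citations": len(sup_j),
                "publisher_citations": len(pub_j),
                "publisher_fraction": frac,
                "band": band,
            }
        )
    return pd.DataFrame(rows)


def load_link_table(path: Path | str) -> list[LinkRecord]:
    """Read a link TSV: database, accession, article_id, direction."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("database\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                LinkRecord(Database.from_string(parts[0]), parts[1], parts[2], parts[3])
            )
    return out
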