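"""Scoring mined mentions against a gold standard.

Two assessment protocols are supported.  The *automatic* protocol takes
publisher-supplied structured citations as gold and computes TP/FP/FN by
set arithmetic over unique (article, database, accession) tuples.  The
*manual* protocol applies adjudications: false positives that a human
reader verified as genuine citations are moved to true positives (publisher
tagging is incomplete, so an "FP" may simply be a citation the publisher
missed); false negatives are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .databases import Database
from .jats import Mention


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F as fractions in [0, 1]; None encodes 'undefined'."""

    precision: float | None
    recall: float | None
    f_score: float | None


@dataclass(frozen=True)
class Adjudication:
    article_id: str
    database: Database
    accession: str
    verdict: str  # "true_positive" | "false_positive"

    def __post_init__(self) -> None:
        if self.verdict not in ("true_positive", "false_positive"):
            raise ValueError(f"unknown verdict {self.verdict!r}")


def mention_keys(
    mentions: Iterable[Mention], occurrence_level: bool = False
) -> set:
    """Reduce mentions to comparison keys.

    Default: unique (article, database, accession) tuples, so multiplicity
    differences between publisher tags and mined tags do not distort counts.
    ``occurrence_level=True`` keeps each located occurrence distinct.
    """
    if occurrence_level:
        return {
            (m.article_id, m.database, m.accession, m.sentence_index, m.char_span)
            for m in mentions
        }
    return {(m.article_id, m.database, m.accession) for m in mentions}


def compare_to_gold(mined: set, gold: set) -> ConfusionCounts:
    """TP/FP/FN from set arithmetic over comparison keys."""
    mined, gold = set(mined), set(gold)
    return ConfusionCounts(
        tp=len(mined & gold), fp=len(mined - gold), fn=len(gold - mined)
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = 2PR/(P+R).

    A zero denominator makes the corresponding metric undefined (None), and
    F is undefined unless both P and R are defined; P = R = 0 gives F = 0.
    """
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    if p is None or r is None:
        f = None
    elif p + r == 0:
        f = 0.0
    else:
        f = 2 * p * r / (p + r)
    return MetricsReport(p, r, f)


def apply_adjudications(
    c: ConfusionCounts, adjudications: Sequence[Adjudication]
) -> ConfusionCounts:
    """Move human-verified false positives to true positives.

    Each ``true_positive`` verdict reassigns one FP as a TP; FN is
    unchanged.  tp+fp is conserved.
    """
    n_relabelled = sum(1 for a in adjudications if a.verdict == "true_positive")
    if n_relabelled > c.fp:
        raise ValueError(
            f"{n_relabelled} relabelled true positives exceed {c.fp} false positives"
        )
    return ConfusionCounts(c.tp + n_relabelled, c.fp - n_relabelled, c.fn)


def percent(value: float | None, decimals: int = 2) -> str:
    """Format a fraction as a half-up rounded percentage string."""
    if value is None:
        return "undefined"
    q = Decimal(1).scaleb(-decimals)
    d = (Decimal(str(value)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{d}%"


def percent_value(value: float | None, decimals: int = 2) -> float | None:
    """A fraction on the 0–100 scale, half-up rounded to ``decimals``."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(str(value)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def evaluate(
    mined: Iterable[Mention],
    gold: Iterable[Mention],
    per_database: bool = True,
    adjudications: Sequence[Adjudication] = (),
    occurrence_level: bool = False,
) -> dict:
    """Full evaluation: counts and metrics, optionally per database.

    Returns ``{scope: (ConfusionCounts, MetricsReport)}`` where scope is a
    Database or the string "all".  Adjudications apply to their database's
    counts.
    """
    mined, gold = list(mined), list(gold)
    scopes: list = ["all"]
    if per_database:
        scopes = sorted(
            {m.database for m in mined} | {m.database for m in gold},
            key=lambda d: d.value,
        ) or ["all"]
    out = {}
    for scope in scopes:
        if scope == "all":
            m_set, g_set = mention_keys(mined, occurrence_level), mention_keys(gold, occurrence_level)
            adj = list(adjudications)
        else:
            m_set = mention_keys((m for m in mined if m.database is scope), occurrence_level)
            g_set = mention_keys((m for m in gold if m.database is scope), occurrence_level)
            adj = [a for a in adjudications if a.database is scope]
        counts = compare_to_gold(m_set, g_set)
        if adj:
            counts = apply_adjudications(counts, adj)
        out[scope] = (counts, compute_metrics(counts))
    return out


def load_adjudications(path) -> list[Adjudication]:
    """Read an adjudication TSV: article_id, database, accession, verdict."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("article_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                Adjudication(parts[0], Database.from_string(parts[1]), parts[2], parts[3])
            )
    return out
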