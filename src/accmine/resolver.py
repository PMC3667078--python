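"""Validation of candidate accessions against a database stand-in.

The third pipeline step checks each candidate accession for existence in its
target database; candidates that fail lookup are discarded, which is what
keeps precision high (shape + cue alone would accept years, grant codes and
typos).  At desk scale the lookup is a whitelist file; the ``contains``
contract is the pluggable surface a live REST resolver would implement.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .databases import Database
from .grammar import normalize_accession

logger = logging.getLogger(__name__)


class WhitelistError(ValueError):
    """Malformed or inconsistent whitelist file."""


@dataclass
class Whitelist:
    """Exact-membership accession lookup, one set per database."""

    entries: dict[Database, set] = field(default_factory=dict)
    provenance: str = "<memory>"

    @classmethod
    def from_pairs(cls, pairs, provenance: str = "<memory>") -> "Whitelist":
        wl = cls(provenance=provenance)
        for db, acc in pairs:
            if not isinstance(db, Database):
                db = Database.from_string(db)
            wl.entries.setdefault(db, set()).add(normalize_accession(acc))
        return wl

    def contains(self, database: Database, accession: str) -> bool:
        return accession in self.entries.get(database, ())

    def sizes(self) -> dict[Database, int]:
        return {db: len(s) for db, s in self.entries.items()}

    def __len__(self) -> int:
        return sum(len(s) for s in self.entries.values())


def load_whitelist(path: Path | str) -> Whitelist:
    """Load a two-column TSV ``<database>\\t<accession>`` whitelist.

    ``#`` comment lines and blank lines are allowed; duplicate rows collapse;
    unknown database labels or malformed rows raise WhitelistError naming the
    line number.
    """
    path = Path(path)
    wl = Whitelist(provenance=f"{path}@{time.strftime('%Y-%m-%dT%H:%M:%S')}")
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise WhitelistError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                db = Database.from_string(parts[0])
            except ValueError as exc:
                raise WhitelistError(f"{path}:{lineno}: {exc}") from exc
            wl.entries.setdefault(db, set()).add(normalize_accession(parts[1]))
            n_rows += 1
    logger.info(
        "loaded whitelist %s: %d rows, sizes %s",
        path, n_rows, {db.value: n for db, n in wl.sizes().items()},
    )
    return wl
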