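"""Closed vocabulary of supported databases.

The core trio (ENA, UniProt, PDB) is what publishers structurally tag via
``ext-link`` elements; the extension databases are mined only.
"""

from __future__ import annotations

from enum import Enum


class Database(str, Enum):
    """A biological database whose records are cited by accession number."""

    ENA = "ENA"
    UNIPROT = "UniProt"
    PDB = "PDB"
    ENSEMBL = "Ensembl"
    PFAM = "Pfam"
    INTERPRO = "InterPro"
    ARRAYEXPRESS = "ArrayExpress"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value

    @classmethod
    def from_string(cls, label: str) -> "Database":
        """Parse a database label case-insensitively.

        Raises
        ------
        ValueError
            If ``label`` is not one of the known database names.
        """
        norm = label.strip().lower()
        for member in cls:
            if member.value.lower() == norm:
                return member
        raise ValueError(f"unknown database label: {label!r}")


CORE_DATABASES = frozenset({Database.ENA, Database.UNIPROT, Database.PDB})
EXTENSION_DATABASES = frozenset(set(Database) - CORE_DATABASES)
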