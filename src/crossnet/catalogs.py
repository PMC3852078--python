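"""Gene-set catalogs (pathways, complexes, tumor suppressors) and drug tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParameterError

DRUG_COLUMNS = ["drug_id", "gene", "drug_name", "drug_class"]


@dataclass
class AnnotationCatalog:
    """Named gene sets: set id -> (description, genes). GMT-serializable."""

    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None) -> "AnnotationCatalog":
        descriptions = descriptions or {}
        entries = {}
        for set_id, genes in sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ParameterError(f"catalog set {set_id!r} is empty")
            entries[set_id] = (descriptions.get(set_id, ""), genes)
        return cls(entries)

    def genes(self, set_id: str) -> frozenset[str]:
        return self.entries[set_id][1]

    def description(self, set_id: str) -> str:
        return self.entries[set_id][0]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.entries.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.entries


@dataclass
class DrugTargetTable:
    """(drug_id, gene, drug_name, drug_class) rows, unique on (drug_id, gene)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DRUG_COLUMNS))

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "DrugTargetTable":
        df = pd.DataFrame(list(rows), columns=DRUG_COLUMNS)
        df = df.drop_duplicates(subset=["drug_id", "gene"], keep="first").reset_index(drop=True)
        return cls(df)

    def __post_init__(self):
        missing = [c for c in DRUG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParameterError(f"drug table missing columns: {missing}")
        self.table = (
            self.table[DRUG_COLUMNS]
            .drop_duplicates(subset=["drug_id", "gene"], keep="first")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    def targets_of(self, drug_id: str) -> set[str]:
        return set(self.table.loc[self.table["drug_id"] == drug_id, "gene"])
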