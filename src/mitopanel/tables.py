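"""In-memory containers and CSV I/O for abundance panels.

The central input is a wide table of relative protein abundances
(samples x proteins, normalized so that wild-type baseline is ~1) plus
sample metadata (genotype, treatment) and a protein -> pathway panel map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

GENOTYPES = ("WT", "RC_het", "RC_RC", "RC_null")
TREATMENTS = ("vector", "mCAT")

META_COLUMNS = ("sample_id", "genotype", "treatment")


@dataclass
class AbundanceTable:
    """Samples x proteins relative-abundance matrix with metadata and panel.

    Attributes
    ----------
    abundance : DataFrame indexed by sample_id, one column per protein.
    meta : DataFrame indexed by sample_id with columns genotype, treatment.
    panel : DataFrame indexed by protein_id with a single column ``pathway``.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    panel: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.abundance.index.equals(self.meta.index):
            raise ValidationError("abundance and meta must share the same sample index")
        if self.abundance.index.has_duplicates:
            raise ValidationError("sample_ids must be unique")
        bad_geno = set(self.meta["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(f"unknown genotype values: {sorted(bad_geno)}")
        bad_trt = set(self.meta["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise ValidationError(f"unknown treatment values: {sorted(bad_trt)}")
        missing = set(self.panel.index) - set(self.abundance.columns)
        if missing:
            raise ValidationError(
                f"panel proteins missing from abundance table: {sorted(missing)}"
            )

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def proteins(self) -> list[str]:
        return list(self.panel.index)

    @property
    def pathways(self) -> list[str]:
        # preserve first-appearance order of the panel file
        return list(dict.fromkeys(self.panel["pathway"]))

    def pathway_proteins(self, pathway: str) -> list[str]:
        sel = self.panel.index[self.panel["pathway"] == pathway]
        if len(sel) == 0:
            raise ValidationError(f"pathway {pathway!r} has no proteins in the panel")
        return list(sel)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, abundance_path: str | Path, panel_path: str | Path) -> None:
        """Write the wide abundance CSV (sample_id, genotype, treatment,
        then one column per protein) and the 2-column panel CSV."""
        wide = self.meta.copy()
        wide = pd.concat([wide, self.abundance], axis=1)
        wide.index.name = "sample_id"
        wide.to_csv(abundance_path, encoding="utf-8")
        panel = self.panel.copy()
        panel.index.name = "protein_id"
        panel.to_csv(panel_path, encoding="utf-8")

    @classmethod
    def from_csv(cls, abundance_path: str | Path, panel_path: str | Path) -> "AbundanceTable":
        wide = pd.read_csv(abundance_path, index_col="sample_id", encoding="utf-8")
        for col in ("genotype", "treatment"):
            if col not in wide.columns:
                raise ValidationError(f"abundance CSV is missing the {col!r} column")
        panel = pd.read_csv(panel_path, index_col="protein_id", encoding="utf-8")
        if "pathway" not in panel.columns:
            raise ValidationError("panel CSV is missing the 'pathway' column")
        meta = wide[["genotype", "treatment"]]
        abundance = wide.drop(columns=["genotype", "treatment"])
        return cls(abundance=abundance, meta=meta, panel=panel[["pathway"]])
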