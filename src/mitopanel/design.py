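"""Regression covariate encoding and per-pathway grouped design matrices.

Each sample's genotype/treatment pair maps to four 0/1 covariates:

* ``x_pkd``  — carries a disease-causing PKD1 genotype (RC/RC or RC/null);
* ``x_dose`` — carries the severe, rapidly progressive genotype (RC/null),
  capturing the gene-dosage effect on top of ``x_pkd``;
* ``x_mcat`` — received mitochondria-targeted catalase (mCAT);
* ``x_mcat_dose`` — the mCAT x dose interaction.

Heterozygous RC/+ animals are phenotypically normal controls and encode as
``x_pkd = 0``.

Per pathway, the responses of all member proteins are stacked into one long
vector and each protein contributes a 5-column bundle (its own baseline
indicator plus the four covariates restricted to its rows), so the design is
block-diagonal by protein and the coefficient groups are the proteins.
Baseline columns are never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import GENOTYPES, TREATMENTS, AbundanceTable

EFFECT_NAMES = ("baseline", "pkd", "dose", "mcat", "mcat_dose")
#: effect columns that enter the composite penalty (everything but baseline)
PENALIZED_EFFECTS = ("pkd", "dose", "mcat", "mcat_dose")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    treatment: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )


def encode_sample(meta: SampleMeta) -> tuple[int, int, int, int]:
    """Return ``(x_pkd, x_dose, x_mcat, x_mcat_dose)`` for one sample."""
    x_pkd = 1 if meta.genotype in ("RC_RC", "RC_null") else 0
    x_dose = 1 if meta.genotype == "RC_null" else 0
    x_mcat = 1 if meta.treatment == "mCAT" else 0
    return (x_pkd, x_dose, x_mcat, x_mcat * x_dose)


def encode_cohort(samples: list[SampleMeta]) -> np.ndarray:
    """Covariate matrix (n_samples x 4) in sample order."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample_ids must be unique")
    return np.array([encode_sample(s) for s in samples], dtype=float)


def samples_from_meta(meta: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(sample_id=str(idx), genotype=row["genotype"], treatment=row["treatment"])
        for idx, row in meta.iterrows()
    ]


@dataclass
class DesignMatrix:
    """Stacked per-pathway design with protein-grouped columns.

    ``X`` holds the standardized design actually handed to the solver;
    ``center``/``scale`` record the per-column transform (identity for
    unpenalized columns) so that solutions can be mapped back exactly.
    """

    X: np.ndarray                      # (n_rows, 5 * n_proteins), standardized
    y: np.ndarray                      # stacked response
    columns: list[tuple[str, str]]     # (protein, effect) per column
    group_index: np.ndarray            # column -> protein group id
    penalized: np.ndarray              # bool per column
    center: np.ndarray
    scale: np.ndarray
    proteins: list[str]
    row_index: pd.MultiIndex           # (sample_id, protein) per row
    covariates: np.ndarray = field(repr=False, default=None)  # (n_samples, 4) raw
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.proteins)

    def X_original(self) -> np.ndarray:
        """Undo the standardization (round-trips to the raw design)."""
        return self.X * self.scale + self.center

    def destandardize(self, beta_std: np.ndarray) -> np.ndarray:
        """Map coefficients for the standardized design back to the raw scale.

        Centering subtracts ``c_j`` times the all-ones vector from column j;
        the ones vector is the sum of the (unpenalized) baseline indicators,
        so every baseline coefficient absorbs ``sum_j c_j * beta_j``.
        """
        beta = np.asarray(beta_std, dtype=float).copy()
        beta[self.penalized] = beta[self.penalized] / self.scale[self.penalized]
        shift = float(np.dot(self.center[self.penalized], beta[self.penalized]))
        baseline_cols = ~self.penalized
        beta[baseline_cols] = beta[baseline_cols] - shift
        return beta


def build_design(
    samples: list[SampleMeta],
    proteins: list[str],
    table: AbundanceTable,
    standardize: bool = True,
) -> DesignMatrix:
    """Assemble the stacked (long) design for one pathway.

    One response row per (sample, protein); per protein a 5-column bundle
    (baseline indicator + the four covariates on that protein's rows).
    Penalized columns are centered and scaled to unit root-mean-square so the
    solver sees a correlation-scale problem.
    """
    if not proteins:
        raise ValidationError("pathway must contain at least one protein")
    cov = encode_cohort(samples)
    sample_ids = [s.sample_id for s in samples]
    n, p = len(samples), len(proteins)

    missing = [pr for pr in proteins if pr not in table.abundance.columns]
    if missing:
        raise ValidationError(f"abundance table lacks proteins: {missing}")

    y = np.empty(n * p, dtype=float)
    X = np.zeros((n * p, 5 * p), dtype=float)
    columns: list[tuple[str, str]] = []
    group_index = np.empty(5 * p, dtype=np.int64)
    penalized = np.zeros(5 * p, dtype=bool)

    for g, protein in enumerate(proteins):
        vals = table.abundance.loc[sample_ids, protein].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = [sample_ids[i] for i in np.nonzero(~np.isfinite(vals))[0]]
            raise ValidationError(
                f"missing abundance for protein {protein!r} in samples {bad}"
            )
        rows = slice(g * n, (g + 1) * n)
        y[rows] = vals
        base = 5 * g
        X[rows, base] = 1.0                      # baseline indicator
        X[rows, base + 1 : base + 5] = cov       # pkd, dose, mcat, mcat_dose
        for k, eff in enumerate(EFFECT_NAMES):
            columns.append((protein, eff))
            group_index[base + k] = g
            penalized[base + k] = eff != "baseline"

    center = np.zeros(5 * p)
    scale = np.ones(5 * p)
    if standardize:
        pen = np.nonzero(penalized)[0]
        center[pen] = X[:, pen].mean(axis=0)
        sd = np.sqrt(np.mean((X[:, pen] - center[pen]) ** 2, axis=0))
        zero = sd <= 0
        if np.any(zero):
            bad = [columns[pen[i]] for i in np.nonzero(zero)[0]]
            raise ValidationError(
                f"constant penalized design columns (cohort lacks contrast): {bad}"
            )
        scale[pen] = sd
        X = X.copy()
        X[:, pen] = (X[:, pen] - center[pen]) / sd

    row_index = pd.MultiIndex.from_arrays(
        [np.repeat(proteins, n), np.tile(sample_ids, p)][::-1],
        names=["sample_id", "protein"],
    )
    return DesignMatrix(
        X=X,
        y=y,
        columns=columns,
        group_index=group_index,
        penalized=penalized,
        center=center,
        scale=scale,
        proteins=list(proteins),
        row_index=row_index,
        covariates=cov,
        sample_ids=sample_ids,
    )
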