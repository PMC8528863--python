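"""Synthetic targeted-proteomics panels and flux-assay traces.

The proteomics generator realizes exactly the linear model the pathway fits
assume: for sample i and protein j,

    y_ij = alpha_j + beta_j*x_pkd + gamma_j*x_dose + delta_j*x_mcat
           + eta_j*x_mcat*x_dose + eps_ij,      eps_ij ~ N(0, sigma_j^2)

on the relative-abundance scale (wild-type baseline ~ 1, so an effect of
-0.31 reads as "decreased by 31%").  Per-protein effects are drawn around
per-pathway means; the default configuration mirrors the study cohort:
27 samples (4 WT, 9 RC/RC, 7 RC/RC+mCAT, 4 RC/null, 3 RC/null+mCAT) and a
137-protein panel over 8 pathways (22 FAO, 26 TCA), with pathway-mean
mutation effects of -0.31 (TCA), -0.29 (FAO) and -0.28 (respiratory
complexes), treatment effects implied by the corresponding restoration
percentages, and a catalase protein whose mCAT effect is +0.64 (the
delivered transgene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleMeta, encode_cohort
from .errors import ValidationError
from .tables import AbundanceTable

#: (genotype, treatment) -> n, in the study's cohort order
DEFAULT_GROUPS: dict[tuple[str, str], int] = {
    ("WT", "vector"): 4,
    ("RC_RC", "vector"): 9,
    ("RC_RC", "mCAT"): 7,
    ("RC_null", "vector"): 4,
    ("RC_null", "mCAT"): 3,
}

#: pathway -> panel size; sums to 137 with FAO = 22 and TCA = 26
DEFAULT_PATHWAY_SIZES: dict[str, int] = {
    "TCA_cycle": 26,
    "FAO": 22,
    "respiratory_complexes": 30,
    "antioxidants": 12,
    "glycolysis": 15,
    "peroxisome": 10,
    "proteostasis": 12,
    "other_metabolic": 10,
}

#: pathway -> mean (beta_pkd, gamma_dose, delta_mcat, eta_inter); the
#: mutation means are the pathway-average suppressions the analysis is built
#: to recover, treatment means follow from the restoration fractions
#: (e.g. FAO: 0.807 * 0.29 ~ 0.234).
DEFAULT_EFFECT_MEANS: dict[str, tuple[float, float, float, float]] = {
    "TCA_cycle": (-0.31, -0.155, 0.148, 0.0),
    "FAO": (-0.29, -0.145, 0.234, 0.0),
    "respiratory_complexes": (-0.28, -0.14, 0.150, 0.0),
    "antioxidants": (-0.25, -0.125, 0.155, 0.0),
    "glycolysis": (-0.15, -0.075, 0.06, 0.0),
    "peroxisome": (-0.10, -0.05, 0.04, 0.0),
    "proteostasis": (-0.05, -0.025, 0.02, 0.0),
    "other_metabolic": (-0.10, -0.05, 0.04, 0.0),
}

#: fixed per-protein overrides applied after the pathway-level draw;
#: catalase itself is overexpressed ~64% under mCAT delivery.
DEFAULT_SPECIAL_EFFECTS: dict[str, dict[str, float]] = {
    "Cat": {"delta_mcat": 0.64},
}


@dataclass
class SimConfig:
    """Generator settings; the defaults encode the study conditions."""

    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    pathway_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_SIZES))
    effect_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MEANS))
    effect_sd: tuple[float, float, float, float] = (0.10, 0.10, 0.10, 0.05)
    noise_sd: float = 0.08
    baseline_mean: float = 1.0
    baseline_sd: float = 0.10
    special_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPECIAL_EFFECTS.items()})
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return sum(self.pathway_sizes.values())

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group.values())

    def validate(self) -> None:
        for key, n in self.n_per_group.items():
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise ValidationError(f"group count for {key} must be >= 0")
        for pw, k in self.pathway_sizes.items():
            if not (isinstance(k, (int, np.integer)) and k >= 0):
                raise ValidationError(f"pathway size for {pw} must be >= 0")
        if set(self.effect_means) != set(self.pathway_sizes):
            raise ValidationError("effect_means must cover exactly the pathways")
        vals = [self.noise_sd, self.baseline_mean, self.baseline_sd,
                *self.effect_sd]
        for pw, means in self.effect_means.items():
            vals.extend(means)
        if not all(math.isfinite(float(v)) for v in vals):
            raise ValidationError("SimConfig contains non-finite values")
        if self.noise_sd < 0 or self.baseline_sd < 0 or any(
                s < 0 for s in self.effect_sd):
            raise ValidationError("standard deviations must be >= 0")


@dataclass
class TrueEffects:
    """Ground-truth per-protein parameters, exactly as used to generate."""

    table: pd.DataFrame  # index protein; alpha, beta_pkd, gamma_dose,
                         # delta_mcat, eta_inter, sigma, pathway

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "TrueEffects":
        return cls(pd.read_csv(path, index_col="protein_id", encoding="utf-8"))


def _panel_proteins(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Protein ids and pathway labels; special proteins get their own names."""
    proteins: list[str] = []
    pathways: list[str] = []
    specials = {"antioxidants": [k for k in cfg.special_effects
                                 if k in DEFAULT_SPECIAL_EFFECTS]}
    for pw, k in cfg.pathway_sizes.items():
        named = specials.get(pw, []) if pw == "antioxidants" else []
        for i in range(k):
            if i < len(named):
                proteins.append(named[i])
            else:
                proteins.append(f"{pw}_{i + 1:03d}")
            pathways.append(pw)
    return proteins, pathways


def simulate_proteomics(cfg: SimConfig) -> tuple[AbundanceTable, TrueEffects]:
    """Draw one synthetic cohort; returns the table and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    samples: list[SampleMeta] = []
    for (geno, trt), n in cfg.n_per_group.items():
        for i in range(n):
            samples.append(SampleMeta(f"{geno}_{trt}_{i + 1:02d}", geno, trt))
    if not samples:
        raise ValidationError("cohort is empty")
    cov = encode_cohort(samples)  # (n_samples, 4)

    proteins, pathway_of = _panel_proteins(cfg)
    n_prot = len(proteins)
    sd_b, sd_g, sd_d, sd_e = cfg.effect_sd

    alpha = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_prot)
    beta = np.empty(n_prot)
    gamma = np.empty(n_prot)
    delta = np.empty(n_prot)
    eta = np.empty(n_prot)
    for j, pw in enumerate(pathway_of):
        mb, mg, md, me = cfg.effect_means[pw]
        beta[j] = rng.normal(mb, sd_b)
        gamma[j] = rng.normal(mg, sd_g)
        delta[j] = rng.normal(md, sd_d)
        eta[j] = rng.normal(me, sd_e)
    sigma = np.full(n_prot, float(cfg.noise_sd))

    name_to_ix = {p: j for j, p in enumerate(proteins)}
    arrays = {"alpha": alpha, "beta_pkd": beta, "gamma_dose": gamma,
              "delta_mcat": delta, "eta_inter": eta, "sigma": sigma}
    for prot, overrides in cfg.special_effects.items():
        if prot not in name_to_ix:
            continue
        for eff, val in overrides.items():
            key = {"alpha": "alpha", "beta_pkd": "beta_pkd",
                   "gamma_dose": "gamma_dose", "delta_mcat": "delta_mcat",
                   "eta_inter": "eta_inter"}.get(eff)
            if key is None:
                raise ValidationError(f"unknown special effect {eff!r}")
            arrays[key][name_to_ix[prot]] = float(val)

    mean = (alpha[None, :]
            + np.outer(cov[:, 0], beta)
            + np.outer(cov[:, 1], gamma)
            + np.outer(cov[:, 2], delta)
            + np.outer(cov[:, 3], eta))
    noise = rng.normal(0.0, 1.0, mean.shape) * sigma[None, :]
    values = mean + noise

    sample_ids = [s.sample_id for s in samples]
    abundance = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                             columns=proteins)
    meta = pd.DataFrame(
        {"genotype": [s.genotype for s in samples],
         "treatment": [s.treatment for s in samples]},
        index=pd.Index(sample_ids, name="sample_id"))
    panel = pd.DataFrame({"pathway": pathway_of},
                         index=pd.Index(proteins, name="protein_id"))
    truth = pd.DataFrame(arrays, index=pd.Index(proteins, name="protein_id"))
    truth["pathway"] = pathway_of
    return AbundanceTable(abundance, meta, panel), TrueEffects(truth)


# --------------------------------------------------------------------------
# flux traces
# --------------------------------------------------------------------------

def simulate_ocr_trace(phase_rates, n_cycles: int = 5, noise_sd: float = 0.0,
                       seed: int = 0, protein_ug: float = 4.0,
                       cycle_minutes: float = 6.0, t0: float = 0.0):
    """Piecewise-constant OCR trace with Gaussian noise and injections.

    ``phase_rates`` is an ordered sequence of ``(reagent, label, rate)``
    with ``label`` in {"baseline", "substrate", "inhibitor"}; an injection
    event is recorded at the start of every phase after the first.
    """
    from .flux import Injection, OCRTrace  # local import to avoid a cycle

    phase_rates = list(phase_rates)
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if not phase_rates:
        raise ValidationError("at least one phase is required")
    for reagent, label, rate in phase_rates:
        if not math.isfinite(float(rate)):
            raise ValidationError(f"non-finite rate for phase {reagent!r}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    times, ocr, injections = [], [], []
    t = float(t0)
    for k, (reagent, label, rate) in enumerate(phase_rates):
        if k > 0:
            injections.append(Injection(reagent=reagent, label=label, time_min=t))
        for _ in range(n_cycles):
            times.append(t)
            ocr.append(rate + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
            t += cycle_minutes
    first_label = phase_rates[0][1]
    return OCRTrace(time_min=np.array(times), ocr=np.array(ocr, dtype=float),
                    injections=injections, protein_ug=protein_ug,
                    initial_label=first_label, initial_reagent=phase_rates[0][0])
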