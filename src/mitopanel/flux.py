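"""Respiratory-complex activities from OCR traces and enzyme kinetics.

Frozen-tissue extracellular flux assays probe one complex at a time: a
substrate injection (NADH for complex I, succinate for II, duroquinol for
III, TMPD/ascorbate for IV) stimulates oxygen consumption and a downstream
inhibitor (rotenone, antimycin A, azide) removes the complex-specific part.
Complex activity is the substrate-phase mean minus the inhibitor-phase
mean, per microgram of loaded protein, optionally expressed relative to
citrate synthase activity (a mitochondrial-mass proxy).

Enzyme activities (citrate synthase via DTNB at 412 nm, LDH via NADH at
340 nm) come from the slope of an absorbance time series through the
Beer-Lambert chain: dA/min / (epsilon * l) -> mM/min, times reaction volume
-> nmol/min, divided by protein mass -> nmol/min/mg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

PHASE_LABELS = ("baseline", "substrate", "inhibitor")

#: literature molar extinction coefficients, mM^-1 cm^-1
EXTINCTION_DTNB_412 = 13.6
EXTINCTION_NADH_340 = 6.22


@dataclass(frozen=True)
class Injection:
    reagent: str
    label: str  # one of PHASE_LABELS[1:]
    time_min: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValidationError(
                f"injection label {self.label!r} not in {PHASE_LABELS}")


@dataclass
class OCRTrace:
    """Ordered oxygen-consumption measurements for one well."""

    time_min: np.ndarray
    ocr: np.ndarray                  # pmol O2 / min
    injections: list[Injection] = field(default_factory=list)
    protein_ug: float = 4.0
    well: str = "A1"
    initial_label: str = "baseline"
    initial_reagent: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.time_min.shape != self.ocr.shape or self.time_min.ndim != 1:
            raise ValidationError("time and OCR arrays must be 1-d and equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("measurement times must be strictly increasing")
        if not self.protein_ug > 0:
            raise ValidationError("protein loaded per well must be > 0")
        times = [inj.time_min for inj in self.injections]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("injection times must be strictly increasing")


@dataclass
class PhaseMean:
    label: str
    reagent: str
    mean: float
    n_used: int


@dataclass
class ComplexActivityResult:
    complex_id: str
    raw: float                      # pmol O2 / min / ug
    cs_normalized: float | None
    substrate_mean: float
    inhibitor_mean: float
    negative: bool


def segment_rates(trace: OCRTrace, last_k: int = 3) -> list[PhaseMean]:
    """Per-phase mean OCR; phases are half-open [injection, next injection).

    The mean uses the last ``last_k`` measurement cycles of each phase (all
    of them if the phase is shorter), discarding early post-injection
    equilibration.
    """
    bounds = [trace.time_min[0]] + [inj.time_min for inj in trace.injections]
    bounds.append(np.inf)
    labels = [trace.initial_label] + [inj.label for inj in trace.injections]
    reagents = [trace.initial_reagent] + [inj.reagent for inj in trace.injections]
    out: list[PhaseMean] = []
    for k in range(len(labels)):
        lo, hi = bounds[k], bounds[k + 1]
        mask = (trace.time_min >= lo) & (trace.time_min < hi)
        vals = trace.ocr[mask]
        if vals.size == 0:
            raise ValidationError(
                f"phase {k} ({labels[k]}/{reagents[k]}) contains no measurements")
        use = vals[-last_k:] if last_k >= 1 else vals
        out.append(PhaseMean(label=labels[k], reagent=reagents[k],
                             mean=float(np.mean(use)), n_used=len(use)))
    return out


def complex_activity(substrate_mean: float, inhibitor_mean: float,
                     protein_ug: float) -> float:
    """Inhibitor-sensitive OCR per microgram of protein.

    Negative values (inhibitor phase above substrate phase) are returned
    unclipped with a warning.
    """
    if not protein_ug > 0:
        raise ValidationError("protein_ug must be > 0")
    activity = (substrate_mean - inhibitor_mean) / protein_ug
    if activity < 0:
        warnings.warn(
            f"negative complex activity ({activity:.3g}); inhibitor phase "
            "exceeded substrate phase", stacklevel=2)
    return activity


def normalize_to_cs(raw_activity: float, cs_activity: float) -> float:
    """Express a complex activity relative to citrate synthase activity."""
    if not cs_activity > 0:
        raise ValidationError("citrate synthase activity must be > 0")
    return raw_activity / cs_activity


def complex_activity_from_trace(trace: OCRTrace, complex_id: str = "I",
                                cs_activity: float | None = None,
                                last_k: int = 3) -> ComplexActivityResult:
    """Segment a single-complex assay trace and compute its activity.

    Uses the last substrate-labeled and last inhibitor-labeled phases.
    """
    phases = segment_rates(trace, last_k=last_k)
    sub = [p for p in phases if p.label == "substrate"]
    inh = [p for p in phases if p.label == "inhibitor"]
    if not sub or not inh:
        raise ValidationError("trace needs one substrate and one inhibitor phase")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = complex_activity(sub[-1].mean, inh[-1].mean, trace.protein_ug)
    return ComplexActivityResult(
        complex_id=complex_id, raw=raw,
        cs_normalized=(normalize_to_cs(raw, cs_activity)
                       if cs_activity is not None else None),
        substrate_mean=sub[-1].mean, inhibitor_mean=inh[-1].mean,
        negative=raw < 0)


# --------------------------------------------------------------------------
# absorbance kinetics
# --------------------------------------------------------------------------

def read_ocr_csv(ocr_path, injections_path, protein_ug: float = 4.0,
                 initial_label: str = "baseline") -> dict[str, OCRTrace]:
    """Load per-well OCR traces from the long-format CSVs.

    ``ocr_path`` columns: well, time_min, ocr_pmol_min (a ``group`` column
    is carried through if present).  ``injections_path`` columns:
    well_or_plate ('*' or 'plate' applies to every well), reagent, label,
    time_min.
    """
    import pandas as pd

    ocr = pd.read_csv(ocr_path, encoding="utf-8")
    inj = pd.read_csv(injections_path, encoding="utf-8")
    for col in ("well", "time_min", "ocr_pmol_min"):
        if col not in ocr.columns:
            raise ValidationError(f"OCR CSV is missing column {col!r}")
    for col in ("well_or_plate", "reagent", "label", "time_min"):
        if col not in inj.columns:
            raise ValidationError(f"injections CSV is missing column {col!r}")

    traces: dict[str, OCRTrace] = {}
    for well, sub in ocr.groupby("well", sort=False):
        sub = sub.sort_values("time_min")
        mine = inj[(inj["well_or_plate"] == well)
                   | (inj["well_or_plate"].isin(["*", "plate"]))]
        mine = mine.sort_values("time_min")
        injections = [Injection(reagent=str(r.reagent), label=str(r.label),
                                time_min=float(r.time_min))
                      for r in mine.itertuples()]
        traces[str(well)] = OCRTrace(
            time_min=sub["time_min"].to_numpy(),
            ocr=sub["ocr_pmol_min"].to_numpy(),
            injections=injections, protein_ug=protein_ug, well=str(well),
            initial_label=initial_label)
    return traces


@dataclass
class EnzymeKineticTrace:
    """Absorbance time series with the constants of the Beer-Lambert chain."""

    time_min: np.ndarray
    absorbance: np.ndarray
    extinction_mM_cm: float         # e.g. 13.6 for DTNB/TNB, 6.22 for NADH
    volume_ml: float
    protein_ug: float
    wavelength_nm: float = 412.0
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_min.shape != self.absorbance.shape or self.time_min.ndim != 1:
            raise ValidationError("time and absorbance must be 1-d, equal length")
        if len(self.time_min) < 3:
            raise ValidationError("kinetic trace needs at least 3 points")
        if not self.extinction_mM_cm > 0:
            raise ValidationError("extinction coefficient must be > 0")
        if not (self.volume_ml > 0 and self.protein_ug > 0 and self.path_cm > 0):
            raise ValidationError("volume, protein mass and path length must be > 0")


def enzyme_activity_from_slope(trace: EnzymeKineticTrace,
                               window: tuple[float, float] | None = None) -> float:
    """Specific enzyme activity (nmol/min/mg) from the absorbance slope.

    The slope (delta-A per minute, least squares over ``window`` or the full
    trace) is converted to a concentration rate via the extinction
    coefficient and path length, to an amount rate via the reaction volume,
    and normalized to protein mass.  Reported as a positive magnitude:
    DTNB-based assays gain absorbance while NADH-based assays lose it.
    """
    t, a = trace.time_min, trace.absorbance
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, a = t[mask], a[mask]
        if len(t) < 3:
            raise ValidationError("selected window holds fewer than 3 points")
    if np.ptp(t) <= 0:
        raise ValidationError("zero time span in kinetic trace")
    slope = stats.linregress(t, a).slope          # delta-A / min
    rate_mM_min = abs(slope) / (trace.extinction_mM_cm * trace.path_cm)
    rate_nmol_min = rate_mM_min * trace.volume_ml * 1e3   # mM * mL = umol
    protein_mg = trace.protein_ug / 1e3
    return rate_nmol_min / protein_mg
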