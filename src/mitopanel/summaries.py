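"""Post-selection refit and pathway-level effect summarization.

After the composite-MCP step chooses, per protein, which of the four
effects (mutation, gene dosage, treatment, treatment x dosage) to keep, the
reported estimates come from ordinary least squares restricted to the
selected effects.  The stacked per-pathway design is block-diagonal by
protein, so the refit decomposes into independent per-protein OLS fits,
each with its own residual variance and t tests.

Summaries follow the study's reporting conventions on the relative scale:
an unselected effect is an exact zero, the restoration percentage is
100 * (treatment effect) / (-(mutation effect)), and pathway rows average
effects over the full pathway membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import EFFECT_NAMES, DesignMatrix
from .errors import ValidationError

_COVARIATE_IX = {"pkd": 0, "dose": 1, "mcat": 2, "mcat_dose": 3}

FLAG_NAMES = ("altered", "suppressed", "dose_prominent", "ameliorated",
              "reversed_gt10")


@dataclass
class RefitResult:
    """Unpenalized OLS on the selected support.

    ``table`` has one row per (protein, effect) over the full 5-effect
    bundle; unselected effects carry estimate 0 and NaN inference columns.
    ``protein_stats`` records each protein's residual variance and degrees
    of freedom.
    """

    table: pd.DataFrame
    protein_stats: pd.DataFrame

    def effect(self, protein: str, effect: str, column: str = "estimate") -> float:
        return float(self.table.loc[(protein, effect), column])


def refit_unpenalized(design: DesignMatrix, support) -> RefitResult:
    """OLS refit restricted to the selected columns.

    ``support`` lists selected design-column indices; baseline columns are
    always retained whether or not they are listed.  Unselected penalized
    coefficients are fixed at exactly 0.
    """
    support = np.asarray(list(support), dtype=int)
    selected_effects: dict[str, set[str]] = {p: set() for p in design.proteins}
    for j in support:
        protein, eff = design.columns[j]
        if eff != "baseline":
            selected_effects[protein].add(eff)

    n = len(design.sample_ids)
    rows = []
    prot_rows = []
    for g, protein in enumerate(design.proteins):
        effs = sorted(selected_effects[protein], key=EFFECT_NAMES.index)
        cols = [_COVARIATE_IX[e] for e in effs]
        Xp = np.column_stack([np.ones(n)] + [design.covariates[:, c] for c in cols])
        if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
            raise ValidationError(
                f"collinear refit design for protein {protein!r}: "
                f"columns {['baseline', *effs]}")
        yp = design.y[g * n:(g + 1) * n]
        fit = sm.OLS(yp, Xp).fit()
        names = ["baseline", *effs]
        est = dict(zip(names, fit.params))
        se = dict(zip(names, fit.bse))
        tv = dict(zip(names, fit.tvalues))
        pv = dict(zip(names, fit.pvalues))
        for eff in EFFECT_NAMES:
            sel = eff in names
            rows.append({
                "protein": protein, "effect": eff, "selected": sel,
                "estimate": est.get(eff, 0.0),
                "se": se.get(eff, np.nan),
                "t": tv.get(eff, np.nan),
                "p": pv.get(eff, np.nan),
            })
        prot_rows.append({"protein": protein,
                          "sigma2": float(fit.scale),
                          "df_resid": int(fit.df_resid)})
    table = pd.DataFrame(rows).set_index(["protein", "effect"])
    protein_stats = pd.DataFrame(prot_rows).set_index("protein")
    return RefitResult(table=table, protein_stats=protein_stats)


def percent_restored(pkd_effect: float, mcat_effect: float) -> float:
    """100 * treatment effect / (-(mutation effect)).

    Positive when the treatment opposes the mutation.  Undefined (NaN) when
    the mutation effect is zero — reported as missing, never as 0.
    """
    if pkd_effect == 0:
        return float("nan")
    return 100.0 * mcat_effect / (-pkd_effect)


def protein_effect_table(refit: RefitResult, panel: pd.DataFrame,
                         alpha: float = 0.05,
                         reversal_threshold: float = 10.0,
                         p_adjust: str = "none") -> pd.DataFrame:
    """Per-protein effects, restoration percentage and significance flags.

    Flags (all based on two-sided refit t tests at level ``alpha``):

    * ``altered`` — mutation or dosage effect selected and significant;
    * ``suppressed`` — altered with a negative mutation effect;
    * ``dose_prominent`` — significant dosage effect with the same sign as
      the mutation effect (stronger change in the severe genotype);
    * ``ameliorated`` — significant treatment effect opposing the mutation
      effect;
    * ``reversed_gt10`` — ameliorated and restoration strictly above the
      ``reversal_threshold`` percentage.

    ``p_adjust="bh"`` applies a Benjamini-Hochberg correction across
    proteins within each effect type before flagging (off by default).
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if p_adjust not in ("none", "bh"):
        raise ValidationError("p_adjust must be 'none' or 'bh'")

    tab = refit.table.reset_index().pivot(index="protein", columns="effect")
    proteins = [p for p in panel.index if p in tab.index]
    if len(proteins) != len(tab.index):
        extra = sorted(set(tab.index) - set(panel.index))
        raise ValidationError(f"proteins missing from the panel: {extra}")

    def col(field, eff):
        return tab[(field, eff)].reindex(proteins)

    pvals = {}
    for eff in ("pkd", "dose", "mcat", "mcat_dose"):
        p = col("p", eff).to_numpy(dtype=float)
        if p_adjust == "bh":
            mask = np.isfinite(p)
            if mask.any():
                p = p.copy()
                p[mask] = multipletests(p[mask], method="fdr_bh")[1]
        pvals[eff] = p

    est = {eff: col("estimate", eff).to_numpy(dtype=float)
           for eff in ("pkd", "dose", "mcat", "mcat_dose")}
    sel = {eff: col("selected", eff).to_numpy(dtype=bool)
           for eff in ("pkd", "dose", "mcat", "mcat_dose")}

    def sig(eff):
        return sel[eff] & (np.nan_to_num(pvals[eff], nan=1.0) < alpha)

    pkd = est["pkd"]
    mcat_rcrc = est["mcat"]
    mcat_rcnull = est["mcat"] + est["mcat_dose"]
    restored = np.array([percent_restored(b, d) if b != 0 else np.nan
                         for b, d in zip(pkd, mcat_rcrc)])
    restored_null = np.array([percent_restored(b, d) if b != 0 else np.nan
                              for b, d in zip(pkd, mcat_rcnull)])

    altered = sig("pkd") | sig("dose")
    suppressed = altered & (pkd < 0)
    dose_prominent = sig("dose") & (est["dose"] * pkd > 0)
    ameliorated = sig("mcat") & (mcat_rcrc * pkd < 0)
    reversed_gt10 = ameliorated & (np.nan_to_num(restored, nan=-np.inf)
                                   > reversal_threshold)

    out = pd.DataFrame({
        "pathway": panel.loc[proteins, "pathway"].to_numpy(),
        "pkd_effect": pkd,
        "dose_effect": est["dose"],
        "mcat_effect_rcrc": mcat_rcrc,
        "mcat_effect_rcnull": mcat_rcnull,
        "percent_restored": restored,
        "percent_restored_rcnull": restored_null,
        "p_pkd": pvals["pkd"], "p_dose": pvals["dose"],
        "p_mcat": pvals["mcat"], "p_mcat_dose": pvals["mcat_dose"],
        "altered": altered, "suppressed": suppressed,
        "dose_prominent": dose_prominent, "ameliorated": ameliorated,
        "reversed_gt10": reversed_gt10,
    }, index=pd.Index(proteins, name="protein"))
    return out


def pathway_summary(effects: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Pathway-level averages mirroring the study's summary table.

    Means run over the *full* pathway membership (unselected effects enter
    as exact zeros); the pathway restoration percentage is the ratio of the
    pathway-mean treatment effect to minus the pathway-mean mutation effect.
    """
    unassigned = sorted(set(effects.index) - set(panel.index))
    if unassigned:
        raise ValidationError(f"proteins not assigned to any pathway: {unassigned}")
    rows = []
    for pathway in dict.fromkeys(panel["pathway"]):
        members = [p for p in panel.index[panel["pathway"] == pathway]
                   if p in effects.index]
        if not members:
            continue
        sub = effects.loc[members]
        mean_pkd = float(sub["pkd_effect"].mean())
        mean_mcat = float(sub["mcat_effect_rcrc"].mean())
        mean_mcat_null = float(sub["mcat_effect_rcnull"].mean())
        rows.append({
            "pathway": pathway,
            "n_proteins": len(members),
            "mean_pkd_effect": mean_pkd,
            "mean_mcat_effect": mean_mcat,
            "percent_restored": percent_restored(mean_pkd, mean_mcat),
            "percent_restored_rcnull": percent_restored(mean_pkd, mean_mcat_null),
            **{f"n_{flag}": int(sub[flag].sum()) for flag in FLAG_NAMES},
        })
    return pd.DataFrame(rows).set_index("pathway")


def significance_counts(effects: pd.DataFrame) -> dict[str, int]:
    """Panel-wide counts of each significance class."""
    return {flag: int(effects[flag].sum()) if len(effects) else 0
            for flag in FLAG_NAMES}


def power_two_sample_t(n_per_group: int, standardized_effect_d: float,
                       alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test via the noncentral t.

    Noncentrality ``d * sqrt(n/2)`` with ``2n - 2`` degrees of freedom for
    equal group sizes ``n``.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if not np.isfinite(standardized_effect_d):
        raise ValidationError("standardized effect size must be finite")
    df = 2 * n_per_group - 2
    nc = standardized_effect_d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def write_effect_heatmap_table(effects: pd.DataFrame, summaries: pd.DataFrame,
                               effects_path: str | Path,
                               summary_path: str | Path) -> None:
    """Write the tidy per-protein effect table and the pathway summary CSV."""
    effects.to_csv(effects_path, encoding="utf-8")
    summaries.to_csv(summary_path, encoding="utf-8")


def read_effect_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="protein", encoding="utf-8")
    for flag in FLAG_NAMES:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df
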