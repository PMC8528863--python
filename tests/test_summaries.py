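"""Post-selection refit, restoration percentages, flags, and power."""

import numpy as np
import pandas as pd
import pytest

import mitopanel as mp
from mitopanel.summaries import FLAG_NAMES, RefitResult


def _design_for(table, proteins):
    samples = mp.samples_from_meta(table.meta)
    return mp.build_design(samples, proteins, table)


def _full_support(design):
    return np.nonzero(design.penalized)[0]


# ------------------------------------------------------------------- refit

def test_noiseless_full_support_refit_is_exact():
    cfg = mp.SimConfig(
        pathway_sizes={"pw": 3},
        effect_means={"pw": (-0.3, -0.1, 0.2, 0.05)},
        effect_sd=(0.05, 0.05, 0.05, 0.02),
        noise_sd=0.0, special_effects={}, seed=2)
    table, truth = mp.simulate_proteomics(cfg)
    design = _design_for(table, table.proteins)
    refit = mp.refit_unpenalized(design, _full_support(design))
    key = {"baseline": "alpha", "pkd": "beta_pkd", "dose": "gamma_dose",
           "mcat": "delta_mcat", "mcat_dose": "eta_inter"}
    for (protein, eff), row in refit.table.iterrows():
        assert row["estimate"] == pytest.approx(
            truth.table.loc[protein, key[eff]], abs=1e-8)


def test_empty_support_gives_grand_means(study):
    _, table, _ = study
    proteins = table.pathway_proteins("peroxisome")
    design = _design_for(table, proteins)
    refit = mp.refit_unpenalized(design, [])
    for protein in proteins:
        assert refit.effect(protein, "baseline") == pytest.approx(
            table.abundance[protein].mean())
        for eff in ("pkd", "dose", "mcat", "mcat_dose"):
            assert refit.effect(protein, eff) == 0.0
            assert np.isnan(refit.table.loc[(protein, eff), "p"])


def test_refit_matches_normal_equations(study):
    """Estimates and standard errors agree with a direct normal-equations
    computation on random supports (independent linear-algebra oracle)."""
    _, table, _ = study
    proteins = table.pathway_proteins("glycolysis")
    design = _design_for(table, proteins)
    rng = np.random.default_rng(5)
    pen_cols = np.nonzero(design.penalized)[0]
    n = len(design.sample_ids)
    for _ in range(5):
        support = rng.choice(pen_cols, size=rng.integers(0, 20), replace=False)
        refit = mp.refit_unpenalized(design, support)
        chosen = {}
        for j in support:
            chosen.setdefault(design.columns[j][0], []).append(
                design.columns[j][1])
        for g, protein in enumerate(proteins):
            effs = sorted(chosen.get(protein, []),
                          key=["pkd", "dose", "mcat", "mcat_dose"].index)
            ix = [["pkd", "dose", "mcat", "mcat_dose"].index(e) for e in effs]
            Xp = np.column_stack([np.ones(n), design.covariates[:, ix]])
            yp = design.y[g * n:(g + 1) * n]
            XtX_inv = np.linalg.inv(Xp.T @ Xp)
            beta = XtX_inv @ Xp.T @ yp
            resid = yp - Xp @ beta
            s2 = resid @ resid / (n - Xp.shape[1])
            se = np.sqrt(s2 * np.diag(XtX_inv))
            for k, eff in enumerate(["baseline", *effs]):
                assert refit.effect(protein, eff) == pytest.approx(
                    beta[k], abs=1e-10)
                assert refit.effect(protein, eff, "se") == pytest.approx(
                    se[k], abs=1e-10)


def test_collinear_support_rejected(study):
    _, table, _ = study
    design = _design_for(table, ["Cat"])
    bad = design.covariates.copy()
    bad[:, 1] = bad[:, 0]                     # duplicate covariate
    design.covariates = bad
    with pytest.raises(mp.ValidationError, match="Cat"):
        mp.refit_unpenalized(design, _full_support(design))


# ------------------------------------------------------------- restoration

def test_percent_restored_values():
    assert mp.percent_restored(-0.5, 0.25) == pytest.approx(50.0)
    assert mp.percent_restored(-0.3, 0.3) == pytest.approx(100.0)
    # the FAO pathway pair: -0.29 suppression, 80.7% restoration
    assert mp.percent_restored(-0.29, 0.23403) == pytest.approx(80.7, abs=1e-9)
    assert np.isnan(mp.percent_restored(0.0, 0.2))


# ------------------------------------------------------------------- flags

def _manual_refit(rows):
    """Hand-built RefitResult: rows = {protein: {effect: (est, p)}}."""
    recs = []
    for protein, effs in rows.items():
        for eff in ("baseline", "pkd", "dose", "mcat", "mcat_dose"):
            if eff in effs:
                est, p = effs[eff]
                recs.append({"protein": protein, "effect": eff,
                             "selected": True, "estimate": est, "se": 0.01,
                             "t": est / 0.01, "p": p})
            else:
                recs.append({"protein": protein, "effect": eff,
                             "selected": False, "estimate": 0.0,
                             "se": np.nan, "t": np.nan, "p": np.nan})
    table = pd.DataFrame(recs).set_index(["protein", "effect"])
    stats = pd.DataFrame({"protein": list(rows), "sigma2": 1e-4,
                          "df_resid": 22}).set_index("protein")
    return RefitResult(table=table, protein_stats=stats)


def _panel(protein_to_pathway):
    return pd.DataFrame({"pathway": list(protein_to_pathway.values())},
                        index=pd.Index(protein_to_pathway, name="protein_id"))


def test_flags_from_hand_built_fixture():
    refit = _manual_refit({
        "p_null": {"baseline": (1.0, 0.5)},
        "p_full": {"baseline": (1.0, 0.5), "pkd": (-0.4, 1e-5),
                   "dose": (-0.2, 1e-4), "mcat": (0.2, 1e-4)},
        "p_boundary": {"baseline": (1.0, 0.5), "pkd": (-0.4, 1e-5),
                       "mcat": (0.03996, 1e-4)},   # 9.99% restored
    })
    panel = _panel({"p_null": "a", "p_full": "a", "p_boundary": "a"})
    eff = mp.protein_effect_table(refit, panel)

    assert not eff.loc["p_null", list(FLAG_NAMES)].any()
    full = eff.loc["p_full"]
    assert full[["altered", "suppressed", "dose_prominent", "ameliorated",
                 "reversed_gt10"]].all()
    assert full["percent_restored"] == pytest.approx(50.0)
    boundary = eff.loc["p_boundary"]
    assert boundary["ameliorated"]
    assert not boundary["reversed_gt10"]       # 9.99 is strictly below 10

    counts = mp.significance_counts(eff)
    assert counts == {"altered": 2, "suppressed": 2, "dose_prominent": 1,
                      "ameliorated": 2, "reversed_gt10": 1}
    # counts are invariant under protein reordering
    assert mp.significance_counts(eff.iloc[::-1]) == counts


def test_alpha_validation():
    refit = _manual_refit({"p": {"baseline": (1.0, 0.5)}})
    with pytest.raises(mp.ValidationError):
        mp.protein_effect_table(refit, _panel({"p": "a"}), alpha=1.5)


def test_strong_protein_flagged_consistently():
    """A protein with beta = -0.4, delta = +0.2 and tiny noise is flagged
    altered/suppressed/ameliorated/reversed in >= 95% of replicates."""
    hits = 0
    reps = 100
    for seed in range(reps):
        cfg = mp.SimConfig(
            pathway_sizes={"pw": 4},
            effect_means={"pw": (-0.4, 0.0, 0.2, 0.0)},
            effect_sd=(0.0, 0.0, 0.0, 0.0),
            noise_sd=0.01, special_effects={}, seed=seed)
        table, _ = mp.simulate_proteomics(cfg)
        design = _design_for(table, table.proteins)
        model = mp.select_model(mp.fit_cmcp_path(design))
        refit = mp.refit_unpenalized(design, model.selected_members)
        eff = mp.protein_effect_table(refit, table.panel)
        row = eff.iloc[0]
        hits += bool(row["altered"] and row["suppressed"]
                     and row["ameliorated"] and row["reversed_gt10"])
    assert hits >= 0.95 * reps


# ----------------------------------------------------------- pathway table

def test_pathway_summary_means_and_counts():
    refit = _manual_refit({
        "a1": {"baseline": (1.0, 0.5), "pkd": (-0.2, 1e-4)},
        "a2": {"baseline": (1.0, 0.5), "pkd": (-0.4, 1e-4)},
        "b1": {"baseline": (1.0, 0.5)},
    })
    panel = _panel({"a1": "A", "a2": "A", "b1": "B"})
    eff = mp.protein_effect_table(refit, panel)
    summ = mp.pathway_summary(eff, panel)
    assert summ.loc["A", "mean_pkd_effect"] == pytest.approx(-0.3)
    assert summ.loc["A", "n_suppressed"] == 2
    assert summ.loc["B", "mean_pkd_effect"] == 0.0
    assert np.isnan(summ.loc["B", "percent_restored"])

    with pytest.raises(mp.ValidationError):
        mp.pathway_summary(eff, panel.drop("b1"))


def test_pathway_mean_recovery_low_noise():
    """A 26-protein pathway generated at mean beta = -0.31 with low noise is
    recovered within 0.03 through the full fit/select/refit chain."""
    cfg = mp.SimConfig(
        pathway_sizes={"pw": 26},
        effect_means={"pw": (-0.31, -0.15, 0.15, 0.0)},
        effect_sd=(0.03, 0.03, 0.03, 0.0),
        noise_sd=0.02, special_effects={}, seed=12)
    table, truth = mp.simulate_proteomics(cfg)
    design = _design_for(table, table.proteins)
    model = mp.select_model(mp.fit_cmcp_path(design))
    refit = mp.refit_unpenalized(design, model.selected_members)
    eff = mp.protein_effect_table(refit, table.panel)
    summ = mp.pathway_summary(eff, table.panel)
    assert summ.loc["pw", "mean_pkd_effect"] == pytest.approx(
        truth.table["beta_pkd"].mean(), abs=0.03)


def test_scale_equivariance_of_effects(study):
    """Multiplying all abundances by c scales effects by c and leaves the
    restoration percentage and flags unchanged."""
    _, table, _ = study
    proteins = table.pathway_proteins("antioxidants")
    c = 2.5
    scaled = mp.AbundanceTable(table.abundance * c, table.meta, table.panel)

    outs = []
    for t in (table, scaled):
        design = _design_for(t, proteins)
        model = mp.select_model(mp.fit_cmcp_path(design))
        refit = mp.refit_unpenalized(design, model.selected_members)
        outs.append(mp.protein_effect_table(refit, t.panel.loc[proteins]))
    base, scl = outs
    assert np.allclose(scl["pkd_effect"], c * base["pkd_effect"], atol=1e-6)
    pr_b, pr_s = base["percent_restored"], scl["percent_restored"]
    both = pr_b.notna() & pr_s.notna()
    assert both.equals(pr_b.notna())
    assert np.allclose(pr_s[both], pr_b[both], atol=1e-6)
    for flag in FLAG_NAMES:
        assert (scl[flag] == base[flag]).all()


# ------------------------------------------------------------------- power

def test_power_size_equals_level():
    assert mp.power_two_sample_t(6, 0.0, 0.05) == pytest.approx(0.05, abs=1e-6)


def test_power_monotone_limits():
    assert mp.power_two_sample_t(6, 10.0, 0.05) > 0.999
    assert (mp.power_two_sample_t(6, 1.0, 0.05)
            < mp.power_two_sample_t(12, 1.0, 0.05))


def test_power_validation():
    with pytest.raises(mp.ValidationError):
        mp.power_two_sample_t(1, 1.0, 0.05)
    with pytest.raises(mp.ValidationError):
        mp.power_two_sample_t(6, 1.0, 0.0)


# --------------------------------------------------------------------- I/O

def test_effect_table_round_trip(tmp_path, study):
    _, table, _ = study
    proteins = table.pathway_proteins("FAO")
    design = _design_for(table, proteins)
    model = mp.select_model(mp.fit_cmcp_path(design))
    refit = mp.refit_unpenalized(design, model.selected_members)
    eff = mp.protein_effect_table(refit, table.panel.loc[proteins])
    summ = mp.pathway_summary(eff, table.panel.loc[proteins])
    epath, spath = tmp_path / "effects.csv", tmp_path / "summary.csv"
    mp.write_effect_heatmap_table(eff, summ, epath, spath)
    back = mp.summaries.read_effect_table(epath)
    assert len(back) == len(proteins)
    assert np.allclose(back["pkd_effect"], eff["pkd_effect"], atol=1e-12)
    for flag in FLAG_NAMES:
        assert (back[flag] == eff[flag]).all()
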