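"""End-to-end pipeline: configuration, validation, and the per-pathway run.

One call (or the ``mitopanel run-all`` command) takes an abundance table —
simulated or loaded from CSV — and, pathway by pathway, builds the grouped
design, fits the composite-MCP path, selects a model by BIC, refits the
selected effects by OLS, and assembles the per-protein and per-pathway
summary tables plus solver diagnostics and a provenance record.  The
default pipeline is fully deterministic given the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cmcp import PenaltyParams, fit_cmcp_path, kkt_check, select_model
from .design import build_design, samples_from_meta
from .errors import ValidationError
from .simulate import SimConfig, simulate_proteomics
from .summaries import (pathway_summary, protein_effect_table,
                        refit_unpenalized, significance_counts,
                        write_effect_heatmap_table)
from .tables import GENOTYPES, TREATMENTS, AbundanceTable

log = logging.getLogger("mitopanel")


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of the simulate block or the input
    paths must be present."""

    simulate: SimConfig | None = None
    abundance_path: str | None = None
    panel_path: str | None = None
    solver: PenaltyParams = field(default_factory=PenaltyParams)
    criterion: str = "bic"
    alpha: float = 0.05
    reversal_threshold: float = 10.0
    p_adjust: str = "none"
    out_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        sim = kwargs.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            if "n_per_group" in sim:
                sim["n_per_group"] = {
                    tuple(k.split("/")): int(v)
                    for k, v in sim["n_per_group"].items()}
            if "effect_means" in sim:
                sim["effect_means"] = {k: tuple(v)
                                       for k, v in sim["effect_means"].items()}
            if "effect_sd" in sim:
                sim["effect_sd"] = tuple(sim["effect_sd"])
            sim = SimConfig(**sim)
        solver = kwargs.pop("solver", None)
        if isinstance(solver, dict):
            solver = PenaltyParams(**solver)
        return cls(simulate=sim, solver=solver or PenaltyParams(), **kwargs)

    def canonical_dict(self) -> dict:
        d = {
            "simulate": None, "abundance_path": self.abundance_path,
            "panel_path": self.panel_path,
            "solver": {k: (v.tolist() if hasattr(v, "tolist") else v)
                       for k, v in asdict(self.solver).items()},
            "criterion": self.criterion, "alpha": self.alpha,
            "reversal_threshold": self.reversal_threshold,
            "p_adjust": self.p_adjust, "seed": self.seed,
            "version": __version__,
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["n_per_group"] = {"/".join(k): v
                                  for k, v in sim["n_per_group"].items()}
            d["simulate"] = sim
        return d


def validate_inputs(cfg: RunConfig) -> list[dict]:
    """Machine-readable validation report; an empty list means pass."""
    errors: list[dict] = []
    has_sim = cfg.simulate is not None
    has_files = cfg.abundance_path is not None or cfg.panel_path is not None
    if has_sim == has_files:
        errors.append({"code": "input_mode",
                       "message": "provide exactly one of a simulate block "
                                  "or abundance/panel paths"})
        return errors
    if has_sim:
        try:
            cfg.simulate.validate()
        except ValidationError as exc:
            errors.append({"code": "sim_config", "message": str(exc)})
        return errors

    for name, path in (("abundance", cfg.abundance_path),
                       ("panel", cfg.panel_path)):
        if path is None:
            errors.append({"code": "missing_path",
                           "message": f"{name} CSV path not given"})
        elif not Path(path).exists():
            errors.append({"code": "missing_file",
                           "message": f"{name} file not found: {path}"})
    if errors:
        return errors
    try:
        table = AbundanceTable.from_csv(cfg.abundance_path, cfg.panel_path)
    except ValidationError as exc:
        errors.append({"code": "schema", "message": str(exc)})
        return errors
    bad_geno = sorted(set(table.meta["genotype"]) - set(GENOTYPES))
    for g in bad_geno:  # unreachable via from_csv, kept for direct use
        errors.append({"code": "enum", "message": f"unknown genotype {g!r}"})
    bad_trt = sorted(set(table.meta["treatment"]) - set(TREATMENTS))
    for t in bad_trt:
        errors.append({"code": "enum", "message": f"unknown treatment {t!r}"})
    missing = sorted(set(table.panel.index) - set(table.abundance.columns))
    for prot in missing:
        errors.append({"code": "panel_protein",
                       "message": f"panel protein {prot!r} absent from "
                                  "abundance table"})
    return errors


@dataclass
class PipelineResult:
    table: AbundanceTable
    effects: pd.DataFrame
    summaries: pd.DataFrame
    counts: dict[str, int]
    diagnostics: pd.DataFrame
    provenance: dict
    truth: object | None = None


def _load_table(cfg: RunConfig) -> tuple[AbundanceTable, object | None]:
    if cfg.simulate is not None:
        sim = cfg.simulate
        if cfg.seed is not None:
            sim = SimConfig(**{**asdict(sim), "seed": cfg.seed})
            sim.n_per_group = dict(cfg.simulate.n_per_group)
        table, truth = simulate_proteomics(sim)
        return table, truth
    try:
        return AbundanceTable.from_csv(cfg.abundance_path, cfg.panel_path), None
    except ValidationError as exc:
        raise ValidationError(f"input loading failed: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full per-pathway analysis and (optionally) write artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    report = validate_inputs(cfg)
    if report:
        raise ValidationError("; ".join(e["message"] for e in report))

    table, truth = _load_table(cfg)
    samples = samples_from_meta(table.meta)
    effect_frames = []
    diag_rows = []
    for pathway in table.pathways:
        try:
            proteins = table.pathway_proteins(pathway)
            design = build_design(samples, proteins, table)
            path = fit_cmcp_path(design, params=cfg.solver)
            model = select_model(path, criterion=cfg.criterion)
            refit = refit_unpenalized(design, model.selected_members)
            effects = protein_effect_table(
                refit, table.panel.loc[proteins],
                alpha=cfg.alpha, reversal_threshold=cfg.reversal_threshold,
                p_adjust=cfg.p_adjust)
        except Exception as exc:
            raise type(exc)(f"pathway {pathway!r}: {exc}") from exc
        effect_frames.append(effects)
        diag_rows.append({
            "pathway": pathway,
            "n_proteins": len(proteins),
            "lambda": model.lam,
            "df": int((model.coef_std != 0).sum()),
            "n_selected_groups": len(model.selected_groups),
            "criterion": cfg.criterion,
            "criterion_value": model.criterion_value,
            "frac_converged": float(path.converged.mean()),
            "kkt_max_violation": kkt_check(model, design, params=cfg.solver),
        })
        log.info("pathway %s: lambda=%.4g, %d/%d proteins selected",
                 pathway, model.lam, len(model.selected_groups), len(proteins))

    effects = pd.concat(effect_frames)
    effects = effects.loc[[p for p in table.panel.index if p in effects.index]]
    summaries = pathway_summary(effects, table.panel)
    counts = significance_counts(effects)
    diagnostics = pd.DataFrame(diag_rows).set_index("pathway")

    cfg_dict = cfg.canonical_dict()
    provenance = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": cfg.seed if cfg.seed is not None else (
            cfg.simulate.seed if cfg.simulate else None),
        "versions": _versions(),
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "abundance.csv", out / "panel.csv")
        if truth is not None:
            truth.to_csv(out / "true_effects.csv")
        write_effect_heatmap_table(effects, summaries,
                                   out / "protein_effects.csv",
                                   out / "pathway_summary.csv")
        pd.Series(counts, name="count").rename_axis("flag").to_csv(
            out / "significance_counts.csv", encoding="utf-8")
        diagnostics.to_csv(out / "solver_diagnostics.csv", encoding="utf-8")
        with open(out / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)

    return PipelineResult(table=table, effects=effects, summaries=summaries,
                          counts=counts, diagnostics=diagnostics,
                          provenance=provenance, truth=truth)


def _versions() -> dict[str, str]:
    import numpy
    import scipy
    import statsmodels
    return {"mitopanel": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}
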