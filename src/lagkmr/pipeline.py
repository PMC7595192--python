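"""End-to-end analysis orchestration: configuration, staging, outputs.

``run_analysis`` executes load/simulate -> prepare -> fit -> estimands
(pooled, then sex-stratified if requested) -> parametric corroboration, and
writes a result bundle: effect-estimate table (CSV), dose-response curves
(CSV), corroboration coefficients (CSV), fit diagnostics (JSON) and a run
manifest (JSON: config echo, seed, package version, input checksum).  The
manifest suffices to reproduce the bundle exactly.  Multiple outcomes are
analyzed as independent runs sharing one input table; no multiple-testing
adjustment is applied, but the report prints the number of contrasts
examined.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corroboration import fit_corroboration, select_terms
from .estimands import (
    all_interaction_effects,
    all_main_effects,
    dose_response,
    effects_to_frame,
)
from .kernels import KernelSpec
from .model import LKMRHyperparameters, fit_mfvb
from .preprocessing import CohortTable, prepare
from .synthetic import (
    DEFAULT_METALS,
    DEFAULT_WINDOWS,
    GeneratorConfig,
    SurfaceSpec,
    generate_cohort,
    read_cohort,
    write_cohort,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Field-for-field mirror of the YAML configuration file."""

    input_csv: str | None = None
    simulate: GeneratorConfig | None = None
    metals: list = field(default_factory=lambda: list(DEFAULT_METALS))
    windows: list = field(default_factory=lambda: list(DEFAULT_WINDOWS))
    outcomes: list = field(default_factory=lambda: ["outcome"])
    covariates: dict = field(default_factory=dict)  # name -> role
    covariate_levels: dict = field(default_factory=dict)
    stratum: str | None = "sex"
    stratify: bool = False
    min_stratum_n: int = 50
    hyper: LKMRHyperparameters = field(default_factory=LKMRHyperparameters)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    interactions: bool = True
    dose_response_requests: list = field(default_factory=list)  # [(metal, window), ...] or "all"
    corroborate: bool = True
    solver: str = "auto"
    strict_convergence: bool = True
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of input_csv or simulate must be given")
        order = {w: i for i, w in enumerate(self.windows)}
        if list(order) != self.windows:
            raise ValueError("window labels must be unique and chronologically ordered")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if raw.get("simulate") is not None:
            sim = dict(raw["simulate"])
            if "surface" in sim and sim["surface"] is not None and not isinstance(sim["surface"], SurfaceSpec):
                s = dict(sim["surface"])
                sim["surface"] = SurfaceSpec(
                    linear=tuple(tuple(t) for t in s.get("linear", ())),
                    quadratic=tuple(tuple(t) for t in s.get("quadratic", ())),
                    interactions=tuple(tuple(t) for t in s.get("interactions", ())),
                    covariate_effects=dict(s.get("covariate_effects", {})),
                )
            raw["simulate"] = GeneratorConfig(**sim)
        if raw.get("hyper") is not None and not isinstance(raw["hyper"], LKMRHyperparameters):
            raw["hyper"] = LKMRHyperparameters(**raw["hyper"])
        if raw.get("kernel") is not None and not isinstance(raw["kernel"], KernelSpec):
            raw["kernel"] = KernelSpec(**raw["kernel"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_or_simulate(config: AnalysisConfig, out: Path):
    if config.simulate is not None:
        gen = config.simulate
        gen.seed = config.seed
        table, truth = generate_cohort(gen)
        write_cohort(table, out / "cohort.csv")
        write_truth(truth, out / "truth.json")
        logger.info("simulated cohort of n=%d written to %s", table.n, out / "cohort.csv")
        config.metals = list(gen.metals)
        config.windows = list(gen.windows)
        config.outcomes = [gen.outcome_name]
        config.covariates = dict(table.covariates)
        config.covariate_levels = dict(table.covariate_levels)
        config.stratum = table.stratum
        return table, out / "cohort.csv"
    path = Path(config.input_csv)
    table = read_cohort(
        path, config.metals, config.windows, outcome=config.outcomes[0],
        covariates=config.covariates, stratum=config.stratum,
        covariate_levels=config.covariate_levels,
    )
    missing = [c for c in config.outcomes if c not in table.data.columns]
    if missing:
        raise ValueError(f"outcome column(s) not in input table: {missing}")
    return table, path


def _analyze_table(table: CohortTable, config: AnalysisConfig):
    design = prepare(table)
    fit = fit_mfvb(design, config.hyper, config.kernel, solver=config.solver)
    allow = not config.strict_convergence
    if not fit.converged and config.strict_convergence:
        raise RuntimeError(
            f"fit for outcome {table.outcome!r} did not converge in "
            f"{fit.n_iterations} iterations (strict convergence requested)"
        )
    effects = all_main_effects(fit, allow_nonconverged=allow)
    if config.interactions:
        effects += all_interaction_effects(fit, allow_nonconverged=allow)
    return fit, effects_to_frame(effects)


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict with the bundle path, per-outcome convergence flags and
    the main tables.  Deterministic given (config, seed): byte-identical
    bundles on re-runs.
    """
    config.validate()
    logging.basicConfig(
        level=getattr(logging, str(config.log_level).upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table0, input_path = _load_or_simulate(config, out)

    effect_frames, corro_frames, diagnostics = [], [], {}
    curves_dir = out / "dose_response"
    converged_all = True

    for outcome in config.outcomes:
        tbl = table0.copy()
        tbl.outcome = outcome
        fit, eff = _analyze_table(tbl, config)
        eff.insert(0, "outcome", outcome)
        eff.insert(1, "stratum", "pooled")
        effect_frames.append(eff)
        diagnostics[outcome] = {
            "pooled": {
                "converged": bool(fit.converged),
                "n_iterations": int(fit.n_iterations),
                "elbo_trace": [float(v) for v in fit.elbo_trace],
            }
        }
        converged_all &= fit.converged

        requests = config.dose_response_requests
        if requests == "all":
            requests = [(m, w) for w in config.windows for m in config.metals]
        if requests:
            curves_dir.mkdir(exist_ok=True)
            for metal, window in requests:
                curve = dose_response(fit, metal, window,
                                      allow_nonconverged=not config.strict_convergence)
                curve.to_frame().to_csv(
                    curves_dir / f"{outcome}_{metal}_{curve.window}.csv", index=False
                )

        if config.corroborate:
            spec = select_terms(eff)
            corro = fit_corroboration(tbl, spec)
            corro.insert(0, "outcome", outcome)
            corro_frames.append(corro)

        if config.stratify and config.stratum is not None:
            levels = pd.unique(table0.data[config.stratum])
            if len(levels) < 2:
                logger.warning(
                    "stratification column %r has a single level; skipping "
                    "stratified stage", config.stratum,
                )
            else:
                for level in levels:
                    sub = tbl.subset(table0.data[config.stratum] == level)
                    if sub.n < config.min_stratum_n:
                        logger.warning(
                            "skipping stratum %s=%r with n=%d below floor %d",
                            config.stratum, level, sub.n, config.min_stratum_n,
                        )
                        continue
                    sub.covariates = {
                        k: v for k, v in sub.covariates.items() if k != config.stratum
                    }
                    sfit, seff = _analyze_table(sub, config)
                    seff.insert(0, "outcome", outcome)
                    seff.insert(1, "stratum", str(level))
                    effect_frames.append(seff)
                    diagnostics[outcome][str(level)] = {
                        "converged": bool(sfit.converged),
                        "n_iterations": int(sfit.n_iterations),
                        "elbo_trace": [float(v) for v in sfit.elbo_trace],
                    }
                    converged_all &= sfit.converged

    effects = pd.concat(effect_frames, ignore_index=True)
    effects.to_csv(out / "effects.csv", index=False)
    if corro_frames:
        pd.concat(corro_frames, ignore_index=True).to_csv(out / "corroboration.csv", index=False)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)

    checksum = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "input_checksum_sha256": checksum,
        "n_subjects": int(table0.n),
        "n_contrasts": int(len(effects)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "out_dir": str(out),
        "effects": effects,
        "corroboration": pd.concat(corro_frames, ignore_index=True) if corro_frames else None,
        "diagnostics": diagnostics,
        "converged": bool(converged_all),
    }


def summarize_run(bundle_path) -> str:
    """Human-readable markdown report for a result bundle."""
    out = Path(bundle_path)
    eff_path = out / "effects.csv"
    if not eff_path.exists():
        raise FileNotFoundError(f"missing effect table: {eff_path}")
    effects = pd.read_csv(eff_path)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    with open(out / "diagnostics.json") as fh:
        diagnostics = json.load(fh)

    lines = ["# Analysis summary", ""]
    lines.append(f"Package version {manifest['package_version']}, seed {manifest['seed']}, "
                 f"n = {manifest['n_subjects']}, {manifest['n_contrasts']} contrasts examined "
                 "(no multiple-testing adjustment).")
    lines.append("")
    for outcome, diag in diagnostics.items():
        conv = all(d["converged"] for d in diag.values())
        lines.append(f"## Outcome: {outcome}" + ("" if conv else "  (WARNING: non-converged fits)"))
        sub = effects[(effects.outcome == outcome) & (effects.stratum == "pooled")]
        mains = sub[sub.contrast_type == "main"]
        if len(mains):
            worst = mains.loc[mains.estimate.idxmax()]
            best = mains.loc[mains.estimate.idxmin()]
            lines.append(
                f"- strongest adverse main effect: {worst.metal} ({worst.window}), "
                f"{worst.estimate:+.3f} (95% CrI {worst.cri95_lower:.3f}, {worst.cri95_upper:.3f})"
            )
            lines.append(
                f"- strongest protective main effect: {best.metal} ({best.window}), "
                f"{best.estimate:+.3f} (95% CrI {best.cri95_lower:.3f}, {best.cri95_upper:.3f})"
            )
            tendency = (
                mains.assign(a=mains.estimate.abs()).groupby("window")["a"].mean()
                .sort_values(ascending=False)
            )
            order = ", ".join(f"{w} ({v:.3f})" for w, v in tendency.items())
            lines.append(f"- mean |main effect| by window: {order}")
        inters = sub[sub.contrast_type == "interaction"]
        sig = inters[(inters.cri95_lower > 0) | (inters.cri95_upper < 0)]
        if len(sig):
            for r in sig.itertuples():
                lines.append(
                    f"- interaction {r.metal} x {r.partner_metal} ({r.window}): "
                    f"{r.estimate:+.3f} (95% CrI {r.cri95_lower:.3f}, {r.cri95_upper:.3f})"
                )
        else:
            lines.append("- interactions with 95% CrI excluding zero: none")
        lines.append("")

    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
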