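"""End-to-end analysis pipeline.

Runs the whole published-style analysis from a single config: load (or
synthesise) the cohort, apply exclusions and missing-indicator handling,
emit the baseline tertile table and the univariate odds-ratio table, fit the
smooth dose-response curve, run the one-line vs two-piecewise threshold
analysis with the turning-point bootstrap, rescale to per-SD effects, and
attach the E-value sensitivity analysis.  Every stochastic stage is seeded
from the config, so reruns of the same config are bit-identical.  Rendered
CSV/Markdown tables are views over ``results.json``; no number appears in a
table that is not in the JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .data import (DEFAULT_REFERENCES, FormulaSpec, assign_tertiles, build_design,
                   drop_missing_exposure, read_cohort_csv, write_cohort_csv)
from .descriptives import (TwoByTwo, baseline_table_frame, build_baseline_table,
                           odds_ratio_2x2, proportion_wald_ci)
from .evalue import evalue_report
from .smooth import detect_turning_region, fit_smooth_logistic
from .synthetic import CohortSpec, generate_cohort
from .threshold import GridSpec, threshold_effect_analysis

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "load_config"]

DEFAULT_CONTINUOUS = ["age", "weight", "heart_rate", "lactate", "apache_iv", "sofa",
                      "septic_shock"]
DEFAULT_CATEGORICAL = {"sex": "male", "infection_site": "pulmonary"}


class AnalysisConfig(BaseModel):
    """Everything a pipeline run needs, serializable to YAML/JSON."""

    input_csv: Optional[str] = None
    synthetic: Optional[CohortSpec] = None
    outcome: Literal["death28", "death14"] = "death28"
    exposure: str = "ratio"
    adjust_continuous: list[str] = Field(default_factory=lambda: list(DEFAULT_CONTINUOUS))
    adjust_categorical: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_CATEGORICAL))
    baseline_variables: Optional[list[str]] = None
    grid: GridSpec = Field(default_factory=GridSpec)
    n_boot: int = 500
    seed: int = 0
    conf: float = 0.95
    smooth_df: int = 20
    adjusted: bool = True  # adjust threshold/smooth models for the covariates
    output_dir: str = "sepsisthresh_out"
    make_plot: bool = True

    @model_validator(mode="after")
    def _check(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv or synthetic must be given")
        return self


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    return AnalysisConfig.model_validate(raw)


def _load_table(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return read_cohort_csv(config.input_csv)
    return generate_cohort(config.synthetic)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis; writes the report bundle and returns the
    consolidated results dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("sepsisthresh")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"package_version": __version__, "seed": config.seed,
                     "outcome": config.outcome}
    stage = "load"
    try:
        table = _load_table(config)
        if config.exposure != "ratio":
            table = table.rename(columns={config.exposure: "ratio"})
        if config.outcome not in table.columns:
            raise KeyError(f"outcome column {config.outcome!r} not in cohort")
        table, n_dropped = drop_missing_exposure(table)
        results["exclusions"] = {"missing_exposure": n_dropped, "n_analysed": len(table)}
        logger.info("loaded cohort: n=%d (%d dropped for missing exposure)",
                    len(table), n_dropped)
        write_cohort_csv(table, out / "cohort.csv")

        stage = "mortality"
        y = table[config.outcome].to_numpy(dtype=int)
        k, n = int(y.sum()), len(y)
        p, lo, hi = proportion_wald_ci(k, n, config.conf)
        results["mortality"] = {"deaths": k, "n": n, "rate_pct": 100 * p,
                                "ci_pct": [100 * lo, 100 * hi]}

        stage = "tertiles"
        tert = assign_tertiles(table["ratio"])
        results["tertiles"] = {"boundaries": list(tert.boundaries),
                               "counts": list(tert.counts)}

        stage = "baseline_table"
        summaries = build_baseline_table(table, tert, variables=config.baseline_variables)
        t1 = baseline_table_frame(summaries)
        t1.to_csv(out / "table1.csv", index=False)
        (out / "table1.md").write_text(t1.to_markdown(index=False))
        results["baseline_table"] = t1.to_dict(orient="records")

        stage = "unadjusted_tertile_or"
        tert_or = {}
        deaths = [int(y[tert.mask(kk)].sum()) for kk in (1, 2, 3)]
        surv = [int((1 - y)[tert.mask(kk)].sum()) for kk in (1, 2, 3)]
        for kk, label in ((2, "middle_vs_low"), (3, "high_vs_low")):
            try:
                orr, lo2, hi2 = odds_ratio_2x2(
                    TwoByTwo(deaths[kk - 1], surv[kk - 1], deaths[0], surv[0]), config.conf)
                tert_or[label] = {"or": orr, "lower": lo2, "upper": hi2}
            except ValueError as exc:
                tert_or[label] = {"error": str(exc)}
        results["unadjusted_tertile_or"] = tert_or
        results["tertile_deaths"] = {"deaths": deaths, "survivors": surv}

        stage = "design"
        covariates = None
        if config.adjusted:
            spec = FormulaSpec(continuous=config.adjust_continuous,
                               categorical=config.adjust_categorical or DEFAULT_REFERENCES)
            design = build_design(table, spec, outcome=config.outcome)
            covariates = design.X.drop(columns=["intercept"])

        stage = "smooth_curve"
        curve = fit_smooth_logistic(y, table["ratio"].to_numpy(), covariates,
                                    df=config.smooth_df, conf=config.conf)
        argmin_x, pattern = detect_turning_region(curve)
        curve.to_frame().to_csv(out / "curve.csv", index=False)
        results["smooth"] = {"effective_df": curve.effective_df,
                             "smoothing_parameter": curve.smoothing_parameter,
                             "argmin": argmin_x, "slope_pattern": pattern}
        if config.make_plot:
            _plot_curve(curve, out / "curve.png")

        stage = "threshold"
        thresh = threshold_effect_analysis(
            y, table["ratio"].to_numpy(), covariates,
            grid_spec=config.grid, n_boot=config.n_boot, seed=config.seed,
            conf=config.conf,
        )
        results["threshold"] = thresh.to_dict()
        t3 = thresh.to_table()
        t3.to_csv(out / "table3.csv", index=False)
        (out / "table3.md").write_text(t3.to_markdown(index=False))

        stage = "evalue"
        ev = evalue_report(thresh.or_above.or_,
                           (thresh.or_above.lower, thresh.or_above.upper))
        ev_below = evalue_report(thresh.or_below.or_,
                                 (thresh.or_below.lower, thresh.or_below.upper))
        results["evalue"] = {"above_threshold": ev.to_dict(),
                             "below_threshold": ev_below.to_dict()}
        (out / "evalue.md").write_text(
            f"- above threshold: {ev}\n- below threshold: {ev_below}\n")

        stage = "write"
        (out / "results.json").write_text(json.dumps(results, indent=2, default=_json_default))
        logger.info("pipeline complete; bundle written to %s", out)
        return results
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        (out / "FAILED.json").write_text(json.dumps(
            {"stage": stage, "error": str(exc)}, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _plot_curve(curve, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.x_grid, curve.ci_lower, curve.ci_upper,
                    alpha=0.3, label="95% pointwise CI")
    ax.plot(curve.x_grid, curve.partial_logit, lw=2, label="smooth fit")
    ax.set_xlabel("non-HDLc/HDLc ratio")
    ax.set_ylabel("partial effect on log-odds of death")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
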