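"""End-to-end analysis pipeline: data in, curves, tables and manifest out.

Runs, separately per field of study (general studies / vocational tracks),
the three analyses of completion effects:

* **unadjusted** — transition-specific Nelson-Aalen estimators per exposure
  group, fed through the product integral into state occupation probability
  curves;
* **cox_conditional** — per-transition Cox models (univariate exposure-only,
  multivariate with the 24-column design, and IPT-weighted univariate with
  robust variance), an exposure hazard-ratio table across the 14 transitions,
  and covariate-conditional probability curves at specified patterns with
  model-based (multinomial logistic) initial distributions;
* **iptw** — the logistic exposure model, inverse-probability-of-treatment
  weights and balance diagnostics, weighted Nelson-Aalen curves per exposure
  group, and the contrast curves: probability differences, ratios, and the
  ratio of weighted to unadjusted difference curves.

Every run writes tidy CSV outputs plus a JSON manifest (config hash, seeds,
versions, exclusion flow, file list, convergence summaries); identical
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .covariates import (
    DESIGN_COLUMNS,
    FAVOURABLE_PATTERN,
    UNFAVOURABLE_PATTERN,
    encode_pattern,
)
from .hazards import ConvergenceError, TransitionCoxModel, nelson_aalen
from .ipw import ExposureModel, balance_diagnostics, compute_weights
from .model import MultiStateModel
from .probabilities import (
    build_intensity_path,
    contrast_curves,
    fit_initial_state_model,
    ratio_of_differences,
    state_probabilities,
)
from .states import ALLOWED_TRANSITIONS, transition_label
from .synthetic import GeneratorConfig, generate_cohort, simulate_trajectories
from .trajectories import build_design_matrix

logger = logging.getLogger("spellmsm")

ANALYSES = ("unadjusted", "cox_conditional", "iptw")
EXPOSURE_GROUPS = ("completion", "non_completion")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "spellmsm_output"
    seed: int = 0
    generator: GeneratorConfig | None = None
    spells_path: str | None = None
    cohort_path: str | None = None
    fields: tuple[str, ...] = ("general", "vocational")
    analyses: tuple[str, ...] = ANALYSES
    patterns: dict[str, dict] = field(
        default_factory=lambda: {
            "unfavourable": dict(UNFAVOURABLE_PATTERN),
            "favourable": dict(FAVOURABLE_PATTERN),
        }
    )
    income_threshold_G: float = 2.0
    stabilized_weights: bool = False
    truncate_weight_percentiles: tuple[float, float] | None = None
    make_plots: bool = False
    bootstrap: dict | None = None

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")
        if not self.analyses:
            raise ValueError("at least one analysis must be selected")
        if self.generator is None and not (self.spells_path and self.cohort_path):
            raise ValueError("need either a generator config or input CSV paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = None if self.generator is None else self.generator.to_dict()
        d["fields"] = list(self.fields)
        d["analyses"] = list(self.analyses)
        if d.get("truncate_weight_percentiles") is not None:
            d["truncate_weight_percentiles"] = list(d["truncate_weight_percentiles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("fields", "analyses"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("truncate_weight_percentiles") is not None:
            d["truncate_weight_percentiles"] = tuple(d["truncate_weight_percentiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    versions: dict[str, str]
    flow_report: list[dict]
    files: list[str]
    convergence: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def load_or_generate(config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (cohort, spells), reading CSVs or running the generator."""
    if config.spells_path and config.cohort_path:
        cohort = pd.read_csv(config.cohort_path)
        spells = pd.read_csv(config.spells_path)
        return cohort, spells
    gen = dataclasses.replace(config.generator, seed=config.seed)
    cohort = generate_cohort(gen)
    spells = simulate_trajectories(cohort, gen)
    return cohort, spells


def _group_table(table: pd.DataFrame, ids: np.ndarray) -> pd.DataFrame:
    return table[table["person_id"].isin(ids)]


def _curve_for_group(model: MultiStateModel, ids: np.ndarray, label: str,
                     weights: pd.Series | None = None):
    sub = MultiStateModel(
        _group_table(model.transitions, ids),
        trajectories={int(p): model.trajectories[int(p)] for p in ids},
        weights=weights,
    )
    res = sub.fit()
    return res.state_probability_curve(label=label)


def fit_cox_models(
    table: pd.DataFrame,
    weights: pd.Series | None,
) -> dict[str, dict[tuple[str, str], object]]:
    """The three Cox variants for every allowed transition.

    Failed fits (no events, rank deficiency, non-convergence) are stored as
    ``None`` and flagged in the HR table.  Constant columns are dropped from
    the multivariate design per transition.
    """
    fits: dict[str, dict] = {"univariate": {}, "multivariate": {}, "weighted_univariate": {}}
    for tr in ALLOWED_TRANSITIONS:
        sub = table[(table["from_state"] == tr[0]) & (table["to_state"] == tr[1])]
        for name, covs, w, robust in (
            ("univariate", ["exposure"], None, False),
            ("multivariate", None, None, False),
            ("weighted_univariate", ["exposure"], weights, True),
        ):
            if name == "weighted_univariate" and weights is None:
                continue
            if covs is None:
                covs = [c for c in DESIGN_COLUMNS if sub[c].nunique() > 1]
            try:
                fits[name][tr] = TransitionCoxModel(table, tr, covs, weights=w).fit(
                    robust=robust
                )
            except (ValueError, ConvergenceError) as err:
                logger.warning("cox %s %s failed: %s", name, transition_label(tr), err)
                fits[name][tr] = None
    if weights is None:
        fits.pop("weighted_univariate")
    return fits


def export_hr_table(
    fits: Mapping[str, Mapping[tuple[str, str], object]],
    robust_models: frozenset[str] = frozenset({"weighted_univariate"}),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exposure hazard ratios with Wald confidence limits per model variant.

    One row per (transition, model); rows whose fit failed carry NaN
    estimates and ``flagged=True``.  Robust (sandwich) standard errors are
    used for the weighted models.
    """
    zq = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for model_name, per_transition in fits.items():
        for tr in ALLOWED_TRANSITIONS:
            fit = per_transition.get(tr)
            if fit is None:
                rows.append(
                    {
                        "transition": transition_label(tr),
                        "model": model_name,
                        "hr": np.nan,
                        "lower": np.nan,
                        "upper": np.nan,
                        "flagged": True,
                    }
                )
                continue
            beta = fit.params["exposure"]
            se_series = fit.robust_bse if model_name in robust_models else fit.bse
            se = se_series["exposure"]
            with np.errstate(over="ignore"):
                rows.append(
                    {
                        "transition": transition_label(tr),
                        "model": model_name,
                        "hr": float(np.exp(beta)),
                        "lower": float(np.exp(beta - zq * se)),
                        "upper": float(np.exp(beta + zq * se)),
                        "flagged": bool(fit.flags),
                    }
                )
    return pd.DataFrame(rows)


def conditional_curves(
    fits: Mapping[tuple[str, str], object],
    pattern: dict,
    init,
    label: str,
):
    """Covariate-conditional occupation curve from multivariate Cox fits.

    Predicted cumulative hazards ``exp(beta'z) dA0`` for every transition are
    assembled through the same product-integral code path as the
    nonparametric curves.  With sparse late risk sets a predicted intensity
    step can exceed 1; the path is then truncated just before the first
    invalid jump (logged) rather than propagating invalid probabilities.
    """
    hazards = {}
    for tr, fit in fits.items():
        if fit is None:
            continue
        hz = fit.predict_cumulative_hazard(pattern)
        if len(hz.times):
            hazards[tr] = hz
    path = build_intensity_path(hazards, on_invalid="truncate")
    if path.truncated_at is not None:
        logger.warning(
            "conditional curve '%s' truncated at t=%.4g (invalid intensity step)",
            label, path.truncated_at,
        )
    return state_probabilities(path, init, label=label)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Execute the configured analyses and write all outputs.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    failure aborts with a stage-named exception.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    convergence: dict = {}

    logger.info("stage data: loading or generating cohort and spells")
    cohort, spells = load_or_generate(config)
    logger.info("stage build: %d persons, %d spells", len(cohort), len(spells))
    model = MultiStateModel.from_spells(
        spells, cohort, income_threshold_G=config.income_threshold_G
    )
    flow = model.flow_report
    logger.info("exclusion flow:\n%s", flow)
    flow.to_frame().to_csv(out / "flow_report.csv", index=False)
    (out / "flow_report.txt").write_text(str(flow) + "\n")
    files += ["flow_report.csv", "flow_report.txt"]

    kept = model.cohort
    for field_name in config.fields:
        fcohort = kept[kept["field"] == field_name].reset_index(drop=True)
        if len(fcohort) == 0:
            raise RuntimeError(f"stage field-split: no persons in field '{field_name}'")
        ids = fcohort["person_id"].to_numpy()
        ftable = _group_table(model.transitions, ids)
        fmodel = MultiStateModel(
            ftable, trajectories={int(p): model.trajectories[int(p)] for p in ids}
        )
        group_ids = {
            g: fcohort.loc[fcohort["exposure"] == g, "person_id"].to_numpy()
            for g in EXPOSURE_GROUPS
        }
        logger.info(
            "field %s: %d persons (%d completion / %d non-completion), %d rows",
            field_name, len(fcohort), len(group_ids["completion"]),
            len(group_ids["non_completion"]), len(ftable),
        )

        unadj_curves = None
        if "unadjusted" in config.analyses or "iptw" in config.analyses:
            unadj_curves = {
                g: _curve_for_group(fmodel, group_ids[g], label=f"{field_name}/{g}/unadjusted")
                for g in EXPOSURE_GROUPS
            }
        if "unadjusted" in config.analyses:
            frame = pd.concat([c.to_frame() for c in unadj_curves.values()])
            name = f"{field_name}_unadjusted_curves.csv"
            frame.to_csv(out / name, index=False)
            files.append(name)

        weight_set = None
        if "iptw" in config.analyses or "cox_conditional" in config.analyses:
            logger.info("field %s: fitting exposure model", field_name)
            exp_fit = ExposureModel(fcohort).fit()
            weight_set = compute_weights(
                exp_fit,
                stabilized=config.stabilized_weights,
                truncate_percentiles=config.truncate_weight_percentiles,
            )
            convergence.setdefault(field_name, {})["exposure_model"] = {
                "converged": exp_fit.converged,
                "n_iter": int(exp_fit.n_iter),
            }

        if "cox_conditional" in config.analyses:
            logger.info("field %s: fitting Cox models for 14 transitions", field_name)
            fits = fit_cox_models(ftable, None if weight_set is None else weight_set.weights)
            hr = export_hr_table(fits)
            name = f"{field_name}_hr_table.csv"
            hr.to_csv(out / name, index=False)
            files.append(name)
            convergence[field_name]["cox"] = {
                model_name: {
                    transition_label(tr): (
                        None if fit is None else {"converged": fit.converged, "n_iter": fit.n_iter}
                    )
                    for tr, fit in per.items()
                }
                for model_name, per in fits.items()
            }

            design = build_design_matrix(fcohort)
            starting = pd.Series(
                [model.trajectories[int(p)].intervals[0][2] for p in ids], index=ids
            )
            try:
                init_model = fit_initial_state_model(starting, design)
            except Exception as err:  # fall back to empirical starting proportions
                logger.warning("field %s: initial-state model failed (%s)", field_name, err)
                init_model = None
            cond_frames = []
            for pattern_name, pattern in config.patterns.items():
                for g, expo in (("completion", 1), ("non_completion", 0)):
                    pat = dict(pattern, exposure=expo)
                    if init_model is not None:
                        init = init_model.predict(dict(encode_pattern(pat)))
                    else:
                        init = fmodel.fit().initial_distribution(group_ids[g])
                    curve = conditional_curves(
                        fits["multivariate"], pat, init,
                        label=f"{field_name}/{g}/{pattern_name}",
                    )
                    cond_frames.append(curve.to_frame())
            name = f"{field_name}_conditional_curves.csv"
            pd.concat(cond_frames).to_csv(out / name, index=False)
            files.append(name)

        if "iptw" in config.analyses:
            logger.info("field %s: weighted Nelson-Aalen and contrasts", field_name)
            balance = balance_diagnostics(fcohort, weight_set)
            name = f"{field_name}_balance.csv"
            balance.to_csv(out / name)
            files.append(name)
            weight_set.to_frame().to_csv(out / f"{field_name}_weights.csv", index=False)
            files.append(f"{field_name}_weights.csv")

            wcurves = {
                g: _curve_for_group(
                    fmodel, group_ids[g], label=f"{field_name}/{g}/iptw",
                    weights=weight_set.weights,
                )
                for g in EXPOSURE_GROUPS
            }
            frame = pd.concat([c.to_frame() for c in wcurves.values()])
            name = f"{field_name}_iptw_curves.csv"
            frame.to_csv(out / name, index=False)
            files.append(name)

            diff_w = contrast_curves(
                wcurves["completion"], wcurves["non_completion"],
                "difference", label=f"{field_name}/iptw",
            )
            ratio_w = contrast_curves(
                wcurves["completion"], wcurves["non_completion"],
                "ratio", label=f"{field_name}/iptw",
            )
            diff_u = contrast_curves(
                unadj_curves["completion"], unadj_curves["non_completion"],
                "difference", label=f"{field_name}/unadjusted",
            )
            meta = ratio_of_differences(diff_w, diff_u, label=f"{field_name}/iptw_vs_unadjusted")
            frame = pd.concat(
                [c.to_frame() for c in (diff_w, ratio_w, diff_u, meta)]
            )
            name = f"{field_name}_contrasts.csv"
            frame.to_csv(out / name, index=False)
            files.append(name)

        if config.make_plots:
            from .plotting import plot_state_probability_curves

            curves = unadj_curves or {}
            if curves:
                name = f"{field_name}_unadjusted_curves.svg"
                plot_state_probability_curves(list(curves.values()), out / name)
                files.append(name)

    import scipy
    import statsmodels

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        versions={
            "spellmsm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        flow_report=[
            {"step": s, "n_removed": r, "n_remaining": n} for s, r, n in flow.steps
        ],
        files=sorted(files),
        convergence=convergence,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
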