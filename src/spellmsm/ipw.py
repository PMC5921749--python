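"""Inverse probability of treatment weighting for the completion exposure.

A logistic regression of completion on the 23 encoded baseline covariates
gives each person's probability of their observed exposure; weighting by its
reciprocal creates a pseudo-population in which completion is independent of
the measured covariates, so weighted analyses that only include the exposure
estimate its marginal (population-averaged) effect.  Standardized mean
differences before and after weighting quantify how well the weights balance
each covariate column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import ENCODED_COLUMNS, encode_covariates


@dataclass
class ExposureModelResults:
    """Fitted logistic exposure (propensity) model."""

    params: pd.Series  # includes 'const'
    cov_params: pd.DataFrame
    fitted_probabilities: pd.Series  # P(completion | Z), indexed by person_id
    exposure: pd.Series  # 0/1, indexed by person_id
    converged: bool
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.bse
        return pd.DataFrame(
            {"coef": self.params, "odds_ratio": np.exp(self.params), "se": se}
        )

    def weights(self, stabilized: bool = False, truncate_percentiles=None) -> "WeightSet":
        return compute_weights(self, stabilized=stabilized, truncate_percentiles=truncate_percentiles)


class ExposureModel:
    """Logistic model of completion on the encoded baseline covariates.

    Fitted by iteratively reweighted least squares (via statsmodels GLM with
    a binomial family); deterministic.  The design is the 23-column encoded
    covariate matrix plus an intercept — the exposure itself is excluded.
    """

    def __init__(self, cohort: pd.DataFrame):
        self._cohort = cohort
        encoded = encode_covariates(cohort, include_exposure=True)
        self._y = encoded["exposure"]
        # constant columns carry no information and make the design singular
        active = [c for c in ENCODED_COLUMNS if encoded[c].nunique() > 1]
        self.dropped_columns = [c for c in ENCODED_COLUMNS if c not in active]
        self._x = encoded[active]
        self._ids = cohort["person_id"].to_numpy()
        if self._y.nunique() < 2:
            raise ValueError("both exposure levels must be present")

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> ExposureModelResults:
        x = sm.add_constant(self._x, has_constant="add")
        model = sm.GLM(self._y.to_numpy(), x.to_numpy(), family=sm.families.Binomial())
        res = model.fit(method="IRLS", tol=tol, maxiter=max_iter)
        if not res.converged:
            raise RuntimeError("exposure model IRLS did not converge")
        params = pd.Series(res.params, index=["const"] + list(self._x.columns))
        p = pd.Series(res.fittedvalues, index=self._ids, name="p_completion")
        eps = np.finfo(float).tiny
        if np.any(p <= eps) or np.any(p >= 1 - 1e-12):
            extreme = params[np.abs(params) > 15].index.tolist()
            raise ValueError(
                "separation in the exposure model: fitted probabilities at 0/1"
                + (f" (suspect columns: {extreme})" if extreme else "")
            )
        return ExposureModelResults(
            params=params,
            cov_params=pd.DataFrame(
                res.cov_params(), index=params.index, columns=params.index
            ),
            fitted_probabilities=p,
            exposure=pd.Series(self._y.to_numpy(), index=self._ids, name="exposure"),
            converged=res.converged,
            n_iter=res.fit_history["iteration"],
        )


def fit_exposure_model(cohort: pd.DataFrame) -> ExposureModelResults:
    """Convenience wrapper: fit the logistic completion model on a cohort."""
    return ExposureModel(cohort).fit()


@dataclass
class WeightSet:
    """Inverse-probability-of-treatment weights per person."""

    weights: pd.Series  # indexed by person_id
    stabilized: bool
    truncate_percentiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.weights.index,
                "weight": self.weights.to_numpy(),
                "stabilized": self.stabilized,
            }
        )


def compute_weights(
    fit: ExposureModelResults,
    stabilized: bool = False,
    truncate_percentiles: tuple[float, float] | None = None,
) -> WeightSet:
    """IPT weights: 1/p for the exposed, 1/(1-p) for the unexposed.

    Stabilized weights multiply by the marginal exposure prevalence of the
    person's own arm, making the mean weight approximately 1.  Optional
    symmetric percentile truncation clips extreme weights and is recorded.
    """
    p = fit.fitted_probabilities
    exposed = fit.exposure.astype(bool)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("positivity violation: fitted probability at 0 or 1")
    w = np.where(exposed, 1.0 / p, 1.0 / (1.0 - p))
    if stabilized:
        prev = exposed.mean()
        w = np.where(exposed, prev, 1.0 - prev) * w
    w = pd.Series(w, index=p.index, name="weight")
    if truncate_percentiles is not None:
        lo, hi = np.percentile(w, truncate_percentiles)
        w = w.clip(lo, hi)
    return WeightSet(weights=w, stabilized=stabilized, truncate_percentiles=truncate_percentiles)


def balance_diagnostics(cohort: pd.DataFrame, weights: WeightSet) -> pd.DataFrame:
    """Standardized mean differences per covariate column, raw and weighted.

    The SMD divides the between-arm mean difference by the pooled standard
    deviation of the unweighted sample; columns with zero pooled variance are
    reported as 0 and flagged.
    """
    encoded = encode_covariates(cohort, include_exposure=True)
    exposed = encoded["exposure"].to_numpy(bool)
    w = cohort["person_id"].map(weights.weights).to_numpy(float)
    rows = []
    for col in ENCODED_COLUMNS:
        x = encoded[col].to_numpy(float)
        smd_raw, degenerate = _smd(x, exposed, np.ones_like(w))
        smd_w, _ = _smd(x, exposed, w)
        rows.append(
            {
                "covariate": col,
                "smd_unweighted": smd_raw,
                "smd_weighted": smd_w,
                "zero_variance": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def _smd(x: np.ndarray, exposed: np.ndarray, w: np.ndarray) -> tuple[float, bool]:
    def wmean(v, m):
        return np.average(v[m], weights=w[m])

    m1, m0 = wmean(x, exposed), wmean(x, ~exposed)
    # pooled SD always from the unweighted sample, the conventional scaling
    v1 = x[exposed].var(ddof=1) if exposed.sum() > 1 else 0.0
    v0 = x[~exposed].var(ddof=1) if (~exposed).sum() > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled <= 1e-12 * max(1.0, abs(m1), abs(m0)):
        return 0.0, True
    return float((m1 - m0) / pooled), False
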