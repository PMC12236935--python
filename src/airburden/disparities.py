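"""Social-vulnerability disparities regression.

Tract-level attributable all-cause-mortality rate (per 100 000) is regressed
on each of 16 social-vulnerability covariates (percentages) in univariate
Gaussian-family GLMs — ordinary least squares — and covariates passing a raw
p < 0.05 screen enter a single multivariate Gaussian GLM that additionally
adjusts for the tract's total pollutant concentration increment and
population. Wald 95% intervals throughout; no multiple-testing correction
across the univariate screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import SVI_COVARIATE_NAMES


@dataclass(frozen=True)
class RegressionResult:
    covariate: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # univariate | multivariate
    scenario: str = ""

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _fit_gaussian_glm(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=sm.families.Gaussian())
    return model.fit()


def univariate_screen(
    inputs: pd.DataFrame,
    covariate_names: tuple[str, ...] = SVI_COVARIATE_NAMES,
    outcome: str = "mortality_rate_per_100k",
    scenario: str = "",
) -> list[RegressionResult]:
    """One Gaussian GLM per covariate against the mortality rate.

    Constant covariates are skipped with a warning (their slope is not
    identifiable). Requires more than 3 tracts.
    """
    if len(inputs) <= 3:
        raise ValueError("need more than 3 tracts for regression")
    y = inputs[outcome].to_numpy(dtype=float)
    results = []
    for name in covariate_names:
        x = inputs[[name]].astype(float)
        if float(x[name].std()) == 0.0:
            warnings.warn(f"covariate {name!r} is constant; univariate model skipped")
            continue
        fit = _fit_gaussian_glm(y, x)
        ci = fit.conf_int().loc[name]
        results.append(
            RegressionResult(
                covariate=name,
                beta=float(fit.params[name]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p_value=float(fit.pvalues[name]),
                model="univariate",
                scenario=scenario,
            )
        )
    return results


def multivariate_model(
    inputs: pd.DataFrame,
    screened: list[str],
    adjusters: tuple[str, ...] = ("delta_c", "population"),
    outcome: str = "mortality_rate_per_100k",
    scenario: str = "",
) -> list[RegressionResult]:
    """Joint Gaussian GLM of screened covariates plus exposure/population adjusters."""
    if not screened:
        raise ValueError("screened covariate set is empty; nothing to fit")
    cols = list(screened) + [a for a in adjusters if a in inputs.columns]
    X = inputs[cols].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        raise ValueError(f"perfect collinearity among columns {cols}")
    fit = _fit_gaussian_glm(inputs[outcome].to_numpy(dtype=float), X)
    ci = fit.conf_int()
    return [
        RegressionResult(
            covariate=name,
            beta=float(fit.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(fit.pvalues[name]),
            model="multivariate",
            scenario=scenario,
        )
        for name in cols
    ]


def screen_and_fit(
    inputs: pd.DataFrame,
    covariate_names: tuple[str, ...] = SVI_COVARIATE_NAMES,
    alpha: float = 0.05,
    scenario: str = "",
) -> pd.DataFrame:
    """Full two-stage analysis: univariate screen, then adjusted joint model.

    Returns a tidy frame (covariate, model, scenario, beta, ci_low, ci_high, p).
    If no covariate passes the screen only univariate rows are returned.
    """
    uni = univariate_screen(inputs, covariate_names, scenario=scenario)
    passed = [r.covariate for r in uni if r.p_value < alpha]
    rows = list(uni)
    if passed:
        rows += multivariate_model(inputs, passed, scenario=scenario)
    return results_to_frame(rows)


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "model": [r.model for r in results],
            "scenario": [r.scenario for r in results],
            "beta": [r.beta for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p_value for r in results],
        }
    )
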