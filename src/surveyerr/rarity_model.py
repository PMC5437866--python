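"""Logit model of false-positive status against regional occupancy.

Per-species false-positive counts are heavily zero/one-inflated, so the
response is the binary status of a species at a site — false positive (1)
versus true positive (0) — modelled with a Bernoulli GLM and logit link
against the species' regional 4 km² occupancy probability. Rarer species
(lower occupancy) being more error-prone shows up as a negative slope on
the logit scale, i.e. an odds factor below 1 per unit occupancy.

Back-transformation convention: the intercept is reported through the
inverse logit (the probability of a false positive at occupancy 0 — species
effectively absent from the region); the slope through the exponential (the
multiplicative odds factor per unit of occupancy). The occupancy covariate
is a proportion in [0, 1] by default; the scale used is recorded on the fit
because published coefficient magnitudes depend on it.

Each site is fitted separately, never pooled: sites differ in composition,
abundance and habitat and act as independent replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import DomainError
from .records_io import SiteReference, Survey

__all__ = ["LogitFit", "CentralThirdCheck", "fit_fp_vs_occupancy", "central_third_check", "fp_binary_table"]

#: Wald standard errors above this are taken as a symptom of (quasi-)complete
#: separation; coefficients are still reported but flagged
_SEPARATION_SE = 50.0


@dataclass(frozen=True)
class LogitFit:
    site_id: str
    n_obs: int
    intercept: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    intercept_bt: float
    intercept_bt_ci: tuple[float, float]
    slope_bt: float
    slope_bt_ci: tuple[float, float]
    covariate_scale: str
    separation_flag: bool

    def predict(self, occupancy) -> np.ndarray:
        """Fitted P(false positive) at the given occupancy value(s)."""
        return expit(self.intercept + self.slope * np.asarray(occupancy, dtype=float))


@dataclass(frozen=True)
class CentralThirdCheck:
    """Goodness-of-fit probe: observed FP proportion in the central third of
    the occupancy-sorted data, with binomial SE, against the model's
    prediction at that subgroup's mean occupancy."""

    n: int
    observed: float
    se: float
    mean_occupancy: float
    predicted: float
    single_class: bool


def fp_binary_table(
    surveys: Sequence[Survey], ref: SiteReference, attrs: pd.DataFrame
) -> pd.DataFrame:
    """One row per species ever recorded at the site at species rank:
    outcome 1 if the species is a false positive there (not accepted),
    0 if true positive; occupancy joined from the attribute table.

    Species missing from the attribute table are dropped (they cannot carry
    the covariate).
    """
    recorded: set[str] = set()
    for s in surveys:
        recorded |= s.species_set()
    rows = []
    for sp in sorted(recorded):
        if sp not in attrs.index:
            continue
        rows.append(
            {
                "species_name": sp,
                "outcome": int(sp not in ref.accepted_species),
                "occupancy": float(attrs.loc[sp, "occupancy"]),
            }
        )
    return pd.DataFrame(rows)


def fit_fp_vs_occupancy(
    records: pd.DataFrame,
    site_id: str = "",
    alpha: float = 0.05,
    covariate_scale: str = "proportion",
) -> LogitFit:
    """Maximum-likelihood Bernoulli fit with logit link (IRLS) plus Wald CIs.

    ``records`` needs columns ``outcome`` (0/1) and ``occupancy`` in [0, 1].
    Requires >= 20 species rows and both outcome classes. Complete
    separation is flagged rather than fatal; the Wald CIs are then
    effectively infinite and should not be interpreted.
    """
    if len(records) < 20:
        raise DomainError(f"need >= 20 species rows, got {len(records)}")
    y = np.asarray(records["outcome"], dtype=float)
    x = np.asarray(records["occupancy"], dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DomainError("both outcome classes (0 and 1) must be present")
    if x.min() < 0 or x.max() > 1:
        raise DomainError("occupancy must lie in [0, 1]")
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    (a, b) = fit.params
    ci = fit.conf_int(alpha=alpha)
    a_ci = (float(ci[0, 0]), float(ci[0, 1]))
    b_ci = (float(ci[1, 0]), float(ci[1, 1]))
    sep = bool(np.any(fit.bse > _SEPARATION_SE) or not np.all(np.isfinite(fit.bse)))
    with np.errstate(over="ignore"):  # separated fits have huge CI bounds
        slope_bt_ci = (float(np.exp(b_ci[0])), float(np.exp(b_ci[1])))
    return LogitFit(
        site_id=site_id,
        n_obs=len(records),
        intercept=float(a),
        slope=float(b),
        intercept_ci=a_ci,
        slope_ci=b_ci,
        intercept_bt=float(expit(a)),
        intercept_bt_ci=(float(expit(a_ci[0])), float(expit(a_ci[1]))),
        slope_bt=float(np.exp(b)),
        slope_bt_ci=slope_bt_ci,
        covariate_scale=covariate_scale,
        separation_flag=sep,
    )


def central_third_check(records: pd.DataFrame, fit: LogitFit) -> CentralThirdCheck:
    """Observed vs predicted FP proportion in the middle third by occupancy
    rank; a well-calibrated model keeps |observed − predicted| within a
    couple of binomial standard errors."""
    if len(records) < 9:
        raise DomainError("need >= 9 rows for a central-third check")
    df = records.sort_values("occupancy", kind="stable").reset_index(drop=True)
    n = len(df)
    lo, hi = n // 3, n - n // 3
    mid = df.iloc[lo:hi]
    y = np.asarray(mid["outcome"], dtype=float)
    p_obs = float(y.mean())
    single = p_obs in (0.0, 1.0)
    se = float(np.sqrt(p_obs * (1 - p_obs) / len(mid)))
    mean_occ = float(mid["occupancy"].mean())
    return CentralThirdCheck(
        n=len(mid),
        observed=p_obs,
        se=se,
        mean_occupancy=mean_occ,
        predicted=float(fit.predict(mean_occ)),
        single_class=single,
    )
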