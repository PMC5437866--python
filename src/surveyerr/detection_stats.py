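"""Detection probabilities, observer error rates and cross-site correlations.

A species' detection probability at a site is the number of surveys in which
it was recorded divided by the number of surveys conducted there — a raw
ratio, deliberately not a latent-state occupancy model. Species that are
false positives at the site (recorded but not accepted) get the same ratio,
flagged, which supports the two-group detection-probability histogram.

Cross-site summaries follow the replicate-sites reporting pattern: one
Pearson correlation per site, then the mean across sites with a
t-distribution confidence interval (n = number of sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedStatisticError
from .records_io import SiteReference, Survey

__all__ = [
    "DetectionEstimate",
    "CorrelationSummary",
    "detection_probabilities",
    "observer_fp_rate",
    "cross_site_correlation",
    "fp_vs_correct_pairs",
    "genus_fp_vs_size_pairs",
    "cautious_vs_size_pairs",
    "cautious_vs_fp_pairs",
]


@dataclass(frozen=True)
class DetectionEstimate:
    species_name: str
    site_id: str
    n_detections: int
    n_surveys: int
    p_detect: float
    is_false_positive_species: bool


@dataclass(frozen=True)
class CorrelationSummary:
    """Mean of per-site correlation coefficients with a t-interval."""

    per_site_r: dict
    mean_r: float
    ci_low: float
    ci_high: float
    n_sites: int
    alpha: float = 0.05


def detection_probabilities(surveys: Sequence[Survey], ref: SiteReference) -> list[DetectionEstimate]:
    """Per-species detection probability = detections / surveys at one site.

    Covers every species either accepted at the site or ever recorded there
    at species rank (cautious and mythical records never enter). Accepted
    species never seen get p = 0.
    """
    surveys = list(surveys)
    if not surveys:
        raise DomainError("need at least one survey at the site")
    sites = {s.site_id for s in surveys}
    if sites != {ref.site_id}:
        raise DomainError(f"surveys from sites {sorted(sites)} do not match reference {ref.site_id}")
    n_surveys = len(surveys)
    counts: dict[str, int] = {}
    for s in surveys:
        for sp in s.species_set():
            counts[sp] = counts.get(sp, 0) + 1
    species = set(counts) | set(ref.accepted_species)
    return [
        DetectionEstimate(
            species_name=sp,
            site_id=ref.site_id,
            n_detections=counts.get(sp, 0),
            n_surveys=n_surveys,
            p_detect=counts.get(sp, 0) / n_surveys,
            is_false_positive_species=sp not in ref.accepted_species,
        )
        for sp in sorted(species)
    ]


def detection_table(surveys: Sequence[Survey], ref: SiteReference) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in detection_probabilities(surveys, ref)])


def observer_fp_rate(survey: Survey) -> float:
    """Fraction of a survey's species-rank records that are false positives.

    Cautious and mythical records are excluded from the denominator. A
    survey with no species-rank classified records has no defined rate.
    """
    counts = survey.category_counts()
    denom = counts["true_positive"] + counts["false_positive"]
    if denom == 0:
        raise UndefinedStatisticError(
            f"survey {survey.survey_id}: no species-rank records, FP rate undefined"
        )
    return counts["false_positive"] / denom


def cross_site_correlation(
    pairs_per_site: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    method: str = "pearson",
    alpha: float = 0.05,
) -> CorrelationSummary:
    """Per-site correlation coefficients summarised across sites.

    CI = mean ± t(1−α/2, n−1) · sd/√n over the per-site coefficients. Sites
    where either variable is constant have no defined r and are excluded
    with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    if len(pairs_per_site) < 2:
        raise DomainError("need at least two sites")
    per_site: dict = {}
    for site, (x, y) in pairs_per_site.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise DomainError(f"site {site}: need >= 3 paired values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"site {site}: constant values, correlation undefined; excluded", stacklevel=2)
            continue
        if method == "pearson":
            r = stats.pearsonr(x, y).statistic
        else:
            r = stats.spearmanr(x, y).statistic
        per_site[site] = float(r)
    if len(per_site) < 2:
        raise DomainError("fewer than two sites with defined correlations")
    rs = np.array(list(per_site.values()))
    n = len(rs)
    mean = float(rs.mean())
    sd = float(rs.std(ddof=1))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return CorrelationSummary(per_site, mean, mean - half, mean + half, n, alpha)


# ---------------------------------------------------------------------------
# pair extractions feeding cross_site_correlation — one per analysis


def _by_site(surveys: Iterable[Survey]) -> dict[str, list[Survey]]:
    out: dict[str, list[Survey]] = {}
    for s in surveys:
        out.setdefault(s.site_id, []).append(s)
    return out


def fp_vs_correct_pairs(surveys: Iterable[Survey]) -> dict[str, tuple[list[float], list[float]]]:
    """Per observer (survey): number of correct observations vs number of
    false positives."""
    pairs: dict[str, tuple[list[float], list[float]]] = {}
    for site, svs in _by_site(surveys).items():
        x, y = pairs.setdefault(site, ([], []))
        for s in svs:
            c = s.category_counts()
            x.append(c["true_positive"])
            y.append(c["false_positive"])
    return pairs


def genus_fp_vs_size_pairs(
    surveys: Iterable[Survey], attrs: pd.DataFrame
) -> dict[str, tuple[list[float], list[float]]]:
    """Per genus: total false-positive observations at the site vs the
    number of congeneric species in the regional flora."""
    genus_size = dict(zip(attrs["genus"], attrs["genus_size"]))
    pairs: dict[str, tuple[list[float], list[float]]] = {}
    for site, svs in _by_site(surveys).items():
        fp_per_genus: dict[str, int] = {g: 0 for g in genus_size}
        for s in svs:
            for o in s.observations:
                if o.category == "false_positive" and o.matched_name:
                    g = o.matched_name.split()[0]
                    fp_per_genus[g] = fp_per_genus.get(g, 0) + 1
        x = [float(genus_size.get(g, 1)) for g in sorted(fp_per_genus)]
        y = [float(fp_per_genus[g]) for g in sorted(fp_per_genus)]
        pairs[site] = (x, y)
    return pairs


def cautious_vs_size_pairs(
    surveys: Iterable[Survey], attrs: pd.DataFrame
) -> dict[str, tuple[list[float], list[float]]]:
    """Per genus: total cautious (genus-only) observations vs genus size."""
    genus_size = dict(zip(attrs["genus"], attrs["genus_size"]))
    pairs: dict[str, tuple[list[float], list[float]]] = {}
    for site, svs in _by_site(surveys).items():
        caut: dict[str, int] = {g: 0 for g in genus_size}
        for s in svs:
            for o in s.observations:
                if o.category == "cautious" and o.matched_name:
                    caut[o.matched_name] = caut.get(o.matched_name, 0) + 1
        x = [float(genus_size.get(g, 1)) for g in sorted(caut)]
        y = [float(caut[g]) for g in sorted(caut)]
        pairs[site] = (x, y)
    return pairs


def cautious_vs_fp_pairs(surveys: Iterable[Survey]) -> dict[str, tuple[list[float], list[float]]]:
    """Per observer (survey): cautious record count vs false-positive count."""
    pairs: dict[str, tuple[list[float], list[float]]] = {}
    for site, svs in _by_site(surveys).items():
        x, y = pairs.setdefault(site, ([], []))
        for s in svs:
            c = s.category_counts()
            x.append(c["cautious"])
            y.append(c["false_positive"])
    return pairs


PAIR_EXTRACTIONS = {
    "fp_vs_correct": fp_vs_correct_pairs,
    "genus_fp_vs_size": genus_fp_vs_size_pairs,
    "cautious_vs_size": cautious_vs_size_pairs,
    "cautious_vs_fp": cautious_vs_fp_pairs,
}
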