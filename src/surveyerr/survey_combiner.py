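"""Bootstrap combination of repeated surveys and the confusion calculus.

Raising the acceptance threshold for a species — requiring it to appear in
all of k combined surveys, in at least m of them, or in any (union) — trades
false positives against false negatives. Because survey lists differ, the
average behaviour of a k-survey combination is estimated by bootstrap: k
distinct surveys are drawn uniformly from the site's pool, the acceptance
rule is applied to their species sets, and TP/FP/FN are averaged over many
resamples (10,000 by default).

True negatives have no natural denominator in an open flora, so the pool of
species ever recorded as false positives at the site stands in for the
plausible-but-absent species: tn = |fp_pool| − mean FP of the combination.
The absolute specificity therefore depends on this arbitrary choice, but
comparisons across thresholds do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError
from .records_io import SiteReference, Survey

__all__ = [
    "AcceptanceRule",
    "CombinationResult",
    "ConfusionSummary",
    "combine",
    "bootstrap_combination",
    "exact_combination_means",
    "confusion",
    "threshold_sweep",
]


@dataclass(frozen=True)
class AcceptanceRule:
    """Species acceptance criterion for a k-survey combination.

    ``all_of_k``: present in every combined survey (the strictest rule);
    ``at_least_m_of_k``: present in >= m of them; ``union``: present in any.
    """

    kind: str
    m: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("all_of_k", "at_least_m_of_k", "union"):
            raise DomainError(f"unknown rule kind {self.kind!r}")
        if self.kind == "at_least_m_of_k":
            if self.m is None or self.m < 1:
                raise DomainError("at_least_m_of_k requires m >= 1")
        elif self.m is not None:
            raise DomainError(f"{self.kind} takes no m")

    def min_count(self, k: int) -> int:
        """Minimum number of the k surveys a species must appear in."""
        if self.kind == "all_of_k":
            return k
        if self.kind == "union":
            return 1
        if self.m > k:
            raise DomainError(f"m={self.m} exceeds k={k}")
        return self.m

    def label(self) -> str:
        return f"atleast:{self.m}" if self.kind == "at_least_m_of_k" else self.kind.replace("_of_k", "")

    @classmethod
    def parse(cls, text: str) -> "AcceptanceRule":
        text = text.strip().lower()
        if text in ("all", "all_of_k"):
            return cls("all_of_k")
        if text == "union":
            return cls("union")
        if text.startswith("atleast:"):
            return cls("at_least_m_of_k", int(text.split(":", 1)[1]))
        raise DomainError(f"cannot parse rule {text!r}")


@dataclass(frozen=True)
class CombinationResult:
    site_id: str
    k: int
    rule: AcceptanceRule
    n_boot: int
    seed: int | None
    mean_tp: float
    mean_fp: float
    mean_fn: float


@dataclass(frozen=True)
class ConfusionSummary:
    """Sensitivity = tp/(tp+fn); specificity = tn/(tn+fp), with tn built
    from the site's cumulative false-positive pool."""

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _check_one_site(surveys: Sequence[Survey]) -> str:
    sites = {s.site_id for s in surveys}
    if len(sites) != 1:
        raise DomainError(f"surveys span multiple sites: {sorted(sites)}")
    return next(iter(sites))


def combine(selection: Sequence[Survey], rule: AcceptanceRule) -> set[str]:
    """Accepted species set for a selection of k surveys under a rule.

    Only species-rank records count; genus-level cautious records never
    contribute to agreement between surveys.
    """
    if not selection:
        raise DomainError("need at least one survey")
    _check_one_site(selection)
    k = len(selection)
    need = rule.min_count(k)
    counts: dict[str, int] = {}
    for s in selection:
        for sp in s.species_set():
            counts[sp] = counts.get(sp, 0) + 1
    return {sp for sp, c in counts.items() if c >= need}


def _membership(surveys: Sequence[Survey]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Boolean survey × species matrix over all species-rank records."""
    species = sorted({sp for s in surveys for sp in s.species_set()})
    idx = {sp: j for j, sp in enumerate(species)}
    M = np.zeros((len(surveys), len(species)), dtype=bool)
    for i, s in enumerate(surveys):
        for sp in s.species_set():
            M[i, idx[sp]] = True
    return M, np.array(species, dtype=object), species


def _tallies(M: np.ndarray, accepted_mask: np.ndarray, picks: np.ndarray, need: int, n_accept: int):
    """TP/FP/FN per resample for rows-of-picks combinations."""
    counts = M[picks].sum(axis=1)  # (n_boot, n_species)
    accepted = counts >= need
    tp = accepted[:, accepted_mask].sum(axis=1)
    fp = accepted[:, ~accepted_mask].sum(axis=1)
    fn = n_accept - tp
    return tp, fp, fn


def bootstrap_combination(
    surveys: Sequence[Survey],
    ref: SiteReference,
    k: int,
    rule: AcceptanceRule,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> CombinationResult:
    """Mean TP/FP/FN over ``n_boot`` random k-survey combinations.

    Each resample draws k *distinct* surveys uniformly without replacement
    (combining a survey with itself is meaningless for an agreement rule);
    resamples are independent across the bootstrap. mean_tp + mean_fn equals
    the size of the site's accepted list exactly. Bit-reproducible given a
    seed.
    """
    surveys = list(surveys)
    site = _check_one_site(surveys)
    if site != ref.site_id:
        raise DomainError(f"surveys are from {site}, reference is for {ref.site_id}")
    S = len(surveys)
    if not 1 <= k <= S:
        raise DomainError(f"k={k} outside [1, {S}]")
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    need = rule.min_count(k)
    M, species_arr, species = _membership(surveys)
    accepted_mask = np.array([sp in ref.accepted_species for sp in species], dtype=bool)
    rng = np.random.default_rng(seed)
    # k distinct indices per resample: first k columns of a random ranking
    picks = np.argsort(rng.random((n_boot, S)), axis=1)[:, :k]
    tp, fp, fn = _tallies(M, accepted_mask, picks, need, len(ref.accepted_species))
    return CombinationResult(
        site_id=site, k=k, rule=rule, n_boot=n_boot, seed=seed,
        mean_tp=float(tp.mean()), mean_fp=float(fp.mean()), mean_fn=float(fn.mean()),
    )


def exact_combination_means(
    surveys: Sequence[Survey], ref: SiteReference, k: int, rule: AcceptanceRule
) -> tuple[float, float, float]:
    """Exhaustive average of TP/FP/FN over all C(S, k) combinations.

    Feasible for small survey pools; the bootstrap converges to these values.
    Uses plain set operations via :func:`combine` — a separate code path
    from the vectorised bootstrap.
    """
    surveys = list(surveys)
    site = _check_one_site(surveys)
    if site != ref.site_id:
        raise DomainError(f"surveys are from {site}, reference is for {ref.site_id}")
    if not 1 <= k <= len(surveys):
        raise DomainError(f"k={k} outside [1, {len(surveys)}]")
    tps, fps, fns = [], [], []
    for combo in combinations(surveys, k):
        acc = combine(combo, rule)
        tp = len(acc & ref.accepted_species)
        tps.append(tp)
        fps.append(len(acc - ref.accepted_species))
        fns.append(len(ref.accepted_species) - tp)
    return float(np.mean(tps)), float(np.mean(fps)), float(np.mean(fns))


def confusion(result: CombinationResult, ref: SiteReference) -> ConfusionSummary:
    """Confusion summary with tn = |fp_pool| − mean_fp.

    The fp_pool comes from ALL surveys at the site regardless of which were
    resampled, so mean_fp can never exceed it; if it does, the reference and
    the surveys are inconsistent.
    """
    n_pool = len(ref.fp_pool)
    if result.mean_fp > n_pool + 1e-9:
        raise IntegrityError(
            f"mean_fp={result.mean_fp:.3f} exceeds fp_pool size {n_pool}; "
            "reference fp_pool was not built from the full record set"
        )
    return ConfusionSummary(
        tp=result.mean_tp, fp=result.mean_fp, fn=result.mean_fn,
        tn=n_pool - result.mean_fp,
    )


def threshold_sweep(
    surveys: Sequence[Survey],
    ref: SiteReference,
    k_range: Iterable[int],
    rules: Sequence[AcceptanceRule],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy long table over (k, rule): bootstrap means plus the confusion
    summary for each cell.

    A single root seed spawns an independent, reproducible stream per
    (site, k, rule) cell, so any cell can be recomputed in isolation.
    """
    rows = []
    for k in k_range:
        for ri, rule in enumerate(rules):
            if rule.kind == "at_least_m_of_k" and rule.m > k:
                continue
            cell_seed = None
            if seed is not None:
                cell_seed = int(
                    np.random.SeedSequence([seed, k, ri]).generate_state(1)[0] % (2**31)
                )
            res = bootstrap_combination(surveys, ref, k, rule, n_boot, cell_seed)
            conf = confusion(res, ref)
            rows.append(
                {
                    "site_id": res.site_id,
                    "k": k,
                    "rule": rule.label(),
                    "mean_tp": res.mean_tp,
                    "mean_fp": res.mean_fp,
                    "mean_fn": res.mean_fn,
                    "tn": conf.tn,
                    "sensitivity": conf.sensitivity,
                    "specificity": conf.specificity,
                }
            )
    return pd.DataFrame(rows)
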