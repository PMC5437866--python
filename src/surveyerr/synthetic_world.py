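"""Synthetic observer-simulation world with known ground truth.

The generator emulates the statistical structure of repeated botanical site
surveys drawn from a timed field identification test: sites of around 100
vascular plant species sampled from a regional flora with genus structure;
per-species detectability spanning 0–1 with roughly three quarters of
species below 0.5; observers of widely varying skill who also generate a
few false-positive records per survey (≈3–4% of their records under the
defaults), preferentially for regionally rare species and for species from
species-rich genera; occasional genus-only "cautious" records and invented
("mythical") name combinations.

Every pipeline estimate — detection probabilities, FP rates, occupancy
slopes, genus-size correlations, the D statistic — can be checked against
the generative parameters, because every synthetic observation is traceable
to a generative event recorded in the ground truth.

False-positive species selection is phylogeny-agnostic: errors are drawn
from the regional pool with rarity and genus-size weights but no reference
to any tree, so a D statistic computed on the resulting trait should sit
near 1. Trees for the phylogenetic analyses are simulated separately
(pure-birth, unit depth).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .errors import DomainError
from .phylo_signal import BinaryTrait, PhyloTree, _brownian_tip_values, threshold_by_prevalence
from .records_io import Observation, SiteReference, Survey

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "simulate_survey",
    "simulate_dataset",
    "simulate_tree",
    "simulate_trait",
    "expected_survey_counts",
    "write_world",
]


@dataclass(frozen=True)
class WorldConfig:
    """Generative parameters; the defaults are the study conditions.

    * ``occupancy_beta`` Beta(0.8, 2.5): right-skewed regional occupancy —
      most species regionally uncommon.
    * ``detectability_beta`` Beta(1, 0.9): calibrated so the *realized*
      per-species detection probability — detectability × mean observer
      skill × the species-rank retention (1 − cautious_rate), a factor of
      ≈0.63 under the defaults — has about 75% of its mass below 0.5 while
      spanning ~0–1.
    * ``skill_beta`` Beta(4, 2): fraction of the detected species an
      observer can actually name; widely varying (mean 2/3).
    * ``fp_lambda`` 1.2 expected false-positive records per survey, drawn
      per-observer from Gamma(1.5, λ/1.5); with ~33 correct records per
      survey under the defaults this yields ≈3–4% FP records.
    * ``rarity_bias`` γ: FP species drawn with weight ∝ (1−occupancy)^γ.
    * ``genus_bias`` δ: ... × genus_size^δ.
    """

    n_species_regional: int = 1000
    n_genera: int = 200
    genus_geometric_p: float = 0.2
    occupancy_beta: tuple[float, float] = (0.8, 2.5)
    site_size: int = 100
    n_sites: int = 6
    detectability_beta: tuple[float, float] = (1.0, 0.9)
    n_observers: int = 40
    skill_beta: tuple[float, float] = (4.0, 2.0)
    fp_lambda: float = 1.2
    fp_lambda_shape: float = 1.5
    rarity_bias: float = 1.0
    genus_bias: float = 0.5
    cautious_rate: float = 0.05
    mythical_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.site_size > self.n_species_regional:
            raise DomainError("site_size exceeds the regional species pool")
        if self.n_genera > self.n_species_regional:
            raise DomainError("more genera than species")
        for name in ("fp_lambda", "rarity_bias", "genus_bias"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("cautious_rate", "mythical_rate", "genus_geometric_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticWorld:
    """Species pool, site compositions and observer roster, plus the ground
    truth of every simulated survey (appended as surveys are simulated)."""

    config: WorldConfig
    species: pd.DataFrame  # index species_name: genus, genus_size, occupancy, detectability
    sites: dict[str, frozenset[str]]
    observers: pd.DataFrame  # index observer_id: skill, fp_lambda
    truth: dict[str, dict] = field(default_factory=dict)

    def reference(self, site_id: str, fp_pool: Sequence[str] = ()) -> SiteReference:
        """Gold-standard reference: the true site composition."""
        return SiteReference(site_id, frozenset(self.sites[site_id]), frozenset(fp_pool))

    def checklist(self) -> tuple[set[str], set[str]]:
        return set(self.species.index), set(self.species["genus"])

    def attributes(self) -> pd.DataFrame:
        return self.species[["genus", "genus_size", "occupancy"]].copy()


def _alpha_id(i: int, width: int = 3) -> str:
    s = ""
    for _ in range(width):
        s = chr(ord("a") + i % 26) + s
        i //= 26
    return s


def _genus_sizes(cfg: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """Geometric genus sizes adjusted to sum exactly to the pool size."""
    sizes = rng.geometric(cfg.genus_geometric_p, size=cfg.n_genera)
    diff = int(sizes.sum()) - cfg.n_species_regional
    while diff > 0:  # shrink the largest genera first
        j = int(np.argmax(sizes))
        take = min(diff, sizes[j] - 1)
        if take == 0:
            break
        sizes[j] -= take
        diff -= take
    while diff < 0:
        j = int(rng.integers(cfg.n_genera))
        sizes[j] += 1
        diff += 1
    return sizes


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build the regional pool, the sites and the observer roster.

    Sites are occupancy-weighted draws (without replacement) of ``site_size``
    species — regionally common species are more likely to occur at a site,
    mirroring how real site floras relate to regional frequency. Identical
    seeds give identical worlds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = _genus_sizes(config, rng)
    genera = [f"Gen{_alpha_id(i)}" for i in range(config.n_genera)]
    names, gen_col, gsize_col = [], [], []
    sp_counter = 0
    for g, size in zip(genera, sizes):
        for _ in range(size):
            names.append(f"{g} sp{_alpha_id(sp_counter)}")
            gen_col.append(g)
            gsize_col.append(int(size))
            sp_counter += 1
    a, b = config.occupancy_beta
    occ = rng.beta(a, b, size=len(names))
    a, b = config.detectability_beta
    det = rng.beta(a, b, size=len(names))
    species = pd.DataFrame(
        {"genus": gen_col, "genus_size": gsize_col, "occupancy": occ, "detectability": det},
        index=pd.Index(names, name="species_name"),
    )
    w = occ / occ.sum()
    sites = {}
    for s in range(config.n_sites):
        chosen = rng.choice(len(names), size=config.site_size, replace=False, p=w)
        sites[f"site{s + 1:02d}"] = frozenset(species.index[chosen])
    a, b = config.skill_beta
    observers = pd.DataFrame(
        {
            "skill": rng.beta(a, b, size=config.n_observers),
            "fp_lambda": rng.gamma(
                config.fp_lambda_shape,
                config.fp_lambda / config.fp_lambda_shape,
                size=config.n_observers,
            ),
        },
        index=pd.Index([f"obs{i + 1:03d}" for i in range(config.n_observers)], name="observer_id"),
    )
    return SyntheticWorld(config, species, sites, observers)


def _fp_weights(world: SyntheticWorld, pool: pd.DataFrame) -> np.ndarray:
    cfg = world.config
    w = (1.0 - pool["occupancy"].to_numpy()) ** cfg.rarity_bias
    w = w * pool["genus_size"].to_numpy() ** cfg.genus_bias
    total = w.sum()
    if total <= 0:
        w = np.ones(len(pool))
        total = float(len(pool))
    return w / total


def _corrupt_name(name: str, checklist: set[str], rng: np.random.Generator, epithets: Sequence[str]) -> str:
    """Invent a plausible but invalid combination: existing genus, existing
    epithet, nonexistent pairing."""
    genus = name.split()[0]
    for _ in range(20):
        cand = f"{genus} {epithets[rng.integers(len(epithets))]}"
        if cand not in checklist:
            return cand
    return f"{genus} imaginaria"


def simulate_survey(
    world: SyntheticWorld,
    site_id: str,
    observer_id: str,
    seed: int | None = None,
    survey_id: str | None = None,
    date: str = "2014-07-01",
) -> Survey:
    """Simulate one observer's survey of one site.

    Each present species is detected-and-named independently with
    probability detectability × skill. The false-positive count is
    Poisson(λ_observer); FP species are drawn without replacement from the
    regional pool outside the site with weight ∝ (1−occupancy)^γ ×
    genus_size^δ. Any would-be species record degrades to a genus-only
    cautious record with probability ``cautious_rate``; an FP record's name
    is corrupted to an invalid combination with probability
    ``mythical_rate``. The generative events are appended to
    ``world.truth``.
    """
    if site_id not in world.sites:
        raise DomainError(f"unknown site {site_id!r}")
    if observer_id not in world.observers.index:
        raise DomainError(f"unknown observer {observer_id!r}")
    cfg = world.config
    rng = np.random.default_rng(seed)
    skill = float(world.observers.loc[observer_id, "skill"])
    lam = float(world.observers.loc[observer_id, "fp_lambda"])
    present = sorted(world.sites[site_id])
    det_p = world.species.loc[present, "detectability"].to_numpy() * skill
    detected = [sp for sp, p in zip(present, det_p) if rng.random() < p]

    pool = world.species.drop(index=list(world.sites[site_id]))
    n_fp = int(rng.poisson(lam))
    n_fp = min(n_fp, len(pool))
    fp_species: list[str] = []
    if n_fp:
        w = _fp_weights(world, pool)
        picks = rng.choice(len(pool), size=n_fp, replace=False, p=w)
        fp_species = list(pool.index[picks])

    checklist = set(world.species.index)
    epithets = [n.split()[1] for n in world.species.index]
    sid = survey_id or f"{site_id}-{observer_id}-{seed if seed is not None else 'x'}"
    obs: list[Observation] = []
    truth = {
        "site_id": site_id, "observer_id": observer_id,
        "present": present, "detected": detected, "false_positives": fp_species,
        "cautious": [], "mythical": [],
    }
    for sp in detected:
        if rng.random() < cfg.cautious_rate:
            obs.append(Observation(sid, sp.split()[0], rank="genus"))
            truth["cautious"].append(sp)
        else:
            obs.append(Observation(sid, sp))
    for sp in fp_species:
        if rng.random() < cfg.mythical_rate:
            bad = _corrupt_name(sp, checklist, rng, epithets)
            obs.append(Observation(sid, bad))
            truth["mythical"].append(bad)
        elif rng.random() < cfg.cautious_rate:
            obs.append(Observation(sid, sp.split()[0], rank="genus"))
            truth["cautious"].append(sp)
        else:
            obs.append(Observation(sid, sp))
    world.truth[sid] = truth
    return Survey(sid, site_id, observer_id, date, obs)


def simulate_dataset(
    world: SyntheticWorld, surveys_per_site: int = 20, seed: int | None = None
) -> list[Survey]:
    """Simulate a full campaign: each site surveyed by ``surveys_per_site``
    observers drawn from the roster (with replacement only if the roster is
    smaller)."""
    rng = np.random.default_rng(seed)
    out: list[Survey] = []
    roster = list(world.observers.index)
    for site_id in sorted(world.sites):
        replace = surveys_per_site > len(roster)
        who = rng.choice(roster, size=surveys_per_site, replace=replace)
        for j, observer_id in enumerate(who):
            sv_seed = int(rng.integers(2**31))
            out.append(
                simulate_survey(
                    world, site_id, str(observer_id), seed=sv_seed,
                    survey_id=f"{site_id}-sv{j + 1:03d}",
                )
            )
    return out


def expected_survey_counts(world: SyntheticWorld, site_id: str, observer_id: str) -> tuple[float, float]:
    """Closed-form expected numbers of (true-positive, false-positive)
    species-rank records for one observer at one site, accounting for the
    cautious and mythical degradation of records."""
    cfg = world.config
    skill = float(world.observers.loc[observer_id, "skill"])
    lam = float(world.observers.loc[observer_id, "fp_lambda"])
    det = world.species.loc[sorted(world.sites[site_id]), "detectability"].to_numpy()
    e_tp = float((det * skill).sum()) * (1 - cfg.cautious_rate)
    e_fp = lam * (1 - cfg.mythical_rate) * (1 - cfg.cautious_rate)
    return e_tp, e_fp


# ---------------------------------------------------------------------------
# trees and traits for the phylogenetic-signal calibrations


def simulate_tree(n_tips: int, seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, rescaled to unit
    root-to-tip depth; tips labelled t0001, t0002, ..."""
    if n_tips < 4:
        raise DomainError("need at least 4 tips")
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_pyrandom.Random(seed),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:04d}"
    return PhyloTree(dtree).scale_height(1.0)


def species_tree(world: SyntheticWorld, seed: int | None = None) -> PhyloTree:
    """Pure-birth phylogeny whose tips are the regional species names.

    Simulated independently of the false-positive machinery, so FP status on
    its tips carries no phylogenetic structure by construction — the null
    the analysis expects to report as D ≈ 1.
    """
    tree = simulate_tree(len(world.species), seed=seed)
    for leaf, name in zip(tree._dtree.leaf_node_iter(), world.species.index):
        leaf.taxon.label = name
    return PhyloTree(tree._dtree)


def simulate_trait(
    tree: PhyloTree, model: str, prevalence: float, seed: int | None = None
) -> BinaryTrait:
    """Binary trait with exactly ``round(prevalence × n_tips)`` ones.

    ``random``: a uniform random subset of tips. ``brownian_threshold``: a
    Brownian trait evolved on the tree and dichotomised at the rank matching
    the prevalence, so the ones cluster phylogenetically.
    """
    n = tree.n_tips
    n_ones = int(round(prevalence * n))
    if not 0 < n_ones < n:
        raise DomainError(f"prevalence {prevalence} is degenerate for {n} tips")
    rng = np.random.default_rng(seed)
    if model == "random":
        states = np.zeros(n)
        states[rng.choice(n, size=n_ones, replace=False)] = 1.0
    elif model == "brownian_threshold":
        values = _brownian_tip_values(tree, 1, rng)
        states = threshold_by_prevalence(values, n_ones)[:, 0]
    else:
        raise DomainError(f"unknown trait model {model!r}")
    return BinaryTrait({t: int(s) for t, s in zip(tree.tip_labels, states)})


# ---------------------------------------------------------------------------
# emit the same delimited formats records_io reads


def write_world(world: SyntheticWorld, surveys: Sequence[Survey], out_dir) -> None:
    """Write surveys.csv, reference.csv, attributes.csv and truth.json."""
    import json
    from pathlib import Path

    from .records_io import write_surveys

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_surveys(surveys, out / "surveys.csv")
    rows = [
        {"site_id": site, "species": sp}
        for site, members in sorted(world.sites.items())
        for sp in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(out / "reference.csv", index=False)
    world.attributes().reset_index().to_csv(out / "attributes.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {"config": asdict(world.config), "surveys": world.truth},
            fh, indent=1, default=str,
        )
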