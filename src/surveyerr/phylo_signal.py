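"""Phylogenetic signal of a binary trait: the D statistic.

False-positive status (1 = species recorded as a false positive, 0 = true
positive) is a binary trait on the tips of a phylogeny. To ask whether
observers' errors cluster phylogenetically, the observed sum of sister-clade
differences d_obs is scaled between two calibration points obtained by
simulation on the same tree with the same prevalence:

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

* random calibration: the tip states are permuted uniformly (no signal),
* Brownian calibration: a continuous trait evolves by Brownian motion on the
  tree and is dichotomised at the rank matching the observed prevalence
  (strong signal).

D ≈ 1 means the trait looks phylogenetically random, D ≈ 0 Brownian-like;
values outside [0, 1] are legal (overdispersion gives D > 1) and are never
clamped. Two p-values accompany D: p_random is the fraction of permutation
d values ≤ d_obs (small when the trait is clumped, i.e. un-random), and
p_brownian the fraction of Brownian d values ≥ d_obs (small when the trait
is random-like).

d itself is computed by estimating a value at every internal node as the
branch-length-weighted average of its daughters (Felsenstein's pruning pass,
tips to root) and summing the absolute differences between sister clades at
each node; polytomies contribute the mean absolute pairwise daughter
difference.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import dendropy
import numpy as np

from .errors import DomainError

__all__ = [
    "PhyloTree",
    "BinaryTrait",
    "DResult",
    "PruneResult",
    "prune",
    "genus_trait",
    "sister_diff_sum",
    "d_statistic",
]

#: floor on branch lengths, as a fraction of tree height, so that the
#: 1/branch-length weights stay finite on trees with zero-length edges
_ZERO_BRANCH_FLOOR = 1e-8


class BinaryTrait(dict):
    """Mapping tip name -> state in {0, 1}.

    Convention: 1 = false-positive species, 0 = true-positive species.
    """

    def validate(self, tip_labels: Iterable[str]) -> None:
        labels = list(tip_labels)
        missing = [t for t in labels if t not in self]
        if missing:
            raise DomainError(f"trait missing states for tips: {missing[:5]}")
        states = {int(self[t]) for t in labels}
        if not states <= {0, 1}:
            raise DomainError("trait states must be 0 or 1")
        if len(states) < 2:
            raise DomainError("both trait states must be present on the tree")


class PruneResult(NamedTuple):
    tree: "PhyloTree"
    unmatched: list[str]


@dataclass(frozen=True)
class DResult:
    """Observed sister-clade difference sum, its two calibrations, the
    scaled D and both p-values."""

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    seed: int | None


class PhyloTree:
    """Rooted phylogeny with branch lengths, backed by dendropy for parsing
    and pruning, with flat arrays cached for fast trait computations.

    Tip labels must be unique. Missing branch lengths are treated as zero
    (and later floored, see :data:`_ZERO_BRANCH_FLOOR`).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._build_arrays()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse from a file path, file object, or Newick string."""
        if isinstance(source, str) and source.lstrip().startswith("("):
            dtree = dendropy.Tree.get(data=source, schema="newick")
        elif isinstance(source, io.IOBase):
            dtree = dendropy.Tree.get(file=source, schema="newick")
        else:
            dtree = dendropy.Tree.get(path=str(source), schema="newick")
        return cls(dtree)

    def to_newick(self, path=None) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def _build_arrays(self) -> None:
        nodes = list(self._dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.intp)
        self.branch_length = np.zeros(n)
        self.tip_index: dict[str, int] = {}
        children: list[list[int]] = [[] for _ in range(n)]
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = index[id(node.parent_node)]
                children[index[id(node.parent_node)]].append(i)
            self.branch_length[i] = node.edge.length or 0.0
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label in self.tip_index:
                    raise DomainError(f"duplicate tip label {label!r}")
                self.tip_index[label] = i
        self.children = children
        self.postorder = np.arange(n)  # nodes[] already postorder
        self.tip_labels = list(self.tip_index)
        self.tip_ids = np.array([self.tip_index[t] for t in self.tip_labels], dtype=np.intp)
        self.n_tips = len(self.tip_labels)
        self.root = n - 1
        # tree height = max root-to-tip path length
        depth = np.zeros(n)
        for i in range(n - 2, -1, -1):  # preorder via reversed postorder
            depth[i] = depth[self.parent[i]] + self.branch_length[i]
        self.height = float(depth[self.tip_ids].max()) or 1.0
        # effective branch lengths for nodal averaging: zero edges floored
        floor = _ZERO_BRANCH_FLOOR * self.height
        self._eff_bl = np.maximum(self.branch_length, floor)
        self._internal = [i for i in range(n) if children[i]]
        # extended branch lengths after Felsenstein's pruning pass; they
        # depend only on topology + branch lengths, so precompute once
        vbl = self._eff_bl.copy()
        for i in self._internal:
            inv = sum(1.0 / vbl[c] for c in children[i])
            vbl[i] = self._eff_bl[i] + 1.0 / inv
        self._pruned_bl = vbl

    # -- operations --------------------------------------------------------
    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self._dtree.phylogenetic_distance_matrix()
        ta = self._dtree.taxon_namespace.get_taxon(a)
        tb = self._dtree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    def scale_height(self, target: float = 1.0) -> "PhyloTree":
        """Return a copy with branch lengths rescaled to the given height."""
        clone = self._dtree.clone(depth=1)
        factor = target / self.height
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return PhyloTree(clone)


def prune(tree: PhyloTree, keep: Iterable[str]) -> PruneResult:
    """Induced subtree on the kept tips; unbranched internal nodes are
    collapsed with branch lengths summed, so patristic distances among kept
    tips are unchanged.

    Names absent from the tree are returned in ``unmatched`` — never
    silently dropped; the caller decides whether that is acceptable.
    """
    keep = list(dict.fromkeys(keep))
    present = [t for t in keep if t in tree.tip_index]
    unmatched = [t for t in keep if t not in tree.tip_index]
    if len(present) < 2:
        raise DomainError(f"cannot prune to {len(present)} matched tip(s)")
    clone = tree._dtree.clone(depth=1)
    clone.retain_taxa_with_labels(present)
    clone.suppress_unifurcations()
    return PruneResult(PhyloTree(clone), unmatched)


def genus_trait(
    tree: PhyloTree, cautious_genera: Iterable[str], representative: str = "all"
) -> BinaryTrait:
    """Binary trait for genus-level (cautious) recording.

    Tips whose genus (the first token of the tip label) received at least
    one cautious record are marked 1. With ``representative="all"`` every
    congeneric tip carries the state; with ``"first"`` only one tip per
    cautious genus does (the first in tip order), the rest staying 0. No
    single canonical choice exists for which tips represent a genus-level
    record, hence the switch.
    """
    if representative not in ("all", "first"):
        raise DomainError(f"unknown representative mode {representative!r}")
    cautious = set(cautious_genera)
    trait = BinaryTrait({t: 0 for t in tree.tip_labels})
    seen: set[str] = set()
    for t in tree.tip_labels:
        genus = t.split()[0]
        if genus in cautious and (representative == "all" or genus not in seen):
            trait[t] = 1
            seen.add(genus)
    return trait


def _states_vector(tree: PhyloTree, trait: Mapping[str, int]) -> np.ndarray:
    if isinstance(trait, BinaryTrait):
        trait.validate(tree.tip_labels)
    else:
        BinaryTrait(trait).validate(tree.tip_labels)
    return np.array([int(trait[t]) for t in tree.tip_labels], dtype=float)


def _d_values(tree: PhyloTree, tip_states: np.ndarray) -> np.ndarray:
    """Sister-clade difference sums for a batch of trait vectors.

    ``tip_states`` has shape (n_tips, m) ordered like ``tree.tip_labels``;
    returns shape (m,). Nodal values are branch-length-weighted daughter
    averages using the extended (pruned) branch lengths.
    """
    tip_states = np.atleast_2d(tip_states.T).T  # ensure 2-D (n_tips, m)
    m = tip_states.shape[1]
    values = np.zeros((tree.n_nodes, m))
    values[tree.tip_ids] = tip_states
    d = np.zeros(m)
    vbl = tree._pruned_bl
    for i in tree._internal:
        kids = tree.children[i]
        w = 1.0 / vbl[kids]
        values[i] = (w[:, None] * values[kids]).sum(axis=0) / w.sum()
        if len(kids) == 2:
            d += np.abs(values[kids[0]] - values[kids[1]])
        else:
            pair_sum = np.zeros(m)
            npairs = 0
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    pair_sum += np.abs(values[kids[a]] - values[kids[b]])
                    npairs += 1
            d += pair_sum / npairs
    return d


def sister_diff_sum(tree: PhyloTree, trait: Mapping[str, int]) -> float:
    """Observed d: sum over internal nodes of |left daughter − right
    daughter| of the nodal trait values (mean pairwise difference at
    polytomies)."""
    states = _states_vector(tree, trait)
    return float(_d_values(tree, states[:, None])[0])


def _brownian_tip_values(tree: PhyloTree, m: int, rng: np.random.Generator) -> np.ndarray:
    """Brownian motion on the tree: root state 0, variance proportional to
    (actual) branch length; returns tip values, shape (n_tips, m)."""
    z = rng.standard_normal((tree.n_nodes, m))
    x = np.zeros((tree.n_nodes, m))
    sd = np.sqrt(tree.branch_length)
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder
        x[i] = x[tree.parent[i]] + sd[i] * z[i]
    return x[tree.tip_ids]

def threshold_by_prevalence(values: np.ndarray, n_ones: int) -> np.ndarray:
    """Dichotomise continuous tip values column-wise at the order statistic
    matching the observed prevalence: the ``n_ones`` largest values become 1
    (ties broken by draw order)."""
    values = np.atleast_2d(values.T).T
    order = np.argsort(-values, axis=0, kind="stable")
    states = np.zeros_like(values)
    np.put_along_axis(states, order[:n_ones], 1.0, axis=0)
    return states


def d_statistic(
    tree: PhyloTree,
    trait: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | None = None,
) -> DResult:
    """D statistic with permutation and Brownian-threshold calibrations.

    ``n_perm`` random tip permutations (prevalence fixed) give the random
    calibration mean; ``n_perm`` Brownian simulations thresholded at the
    observed prevalence give the Brownian mean. Fully reproducible given
    ``seed``.
    """
    if tree.n_tips < 3:
        raise DomainError("D statistic needs at least 3 tips")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives an unstable calibration; use >= 100",
            stacklevel=2,
        )
    states = _states_vector(tree, trait)
    n_ones = int(states.sum())
    rng = np.random.default_rng(seed)
    d_obs = float(_d_values(tree, states[:, None])[0])
    perm = rng.permuted(np.tile(states, (n_perm, 1)), axis=1).T
    d_rand = _d_values(tree, perm)
    bm = _brownian_tip_values(tree, n_perm, rng)
    d_brown = _d_values(tree, threshold_by_prevalence(bm, n_ones))
    mean_r = float(d_rand.mean())
    mean_b = float(d_brown.mean())
    if np.isclose(mean_r, mean_b):
        raise DomainError("degenerate calibration: random and Brownian means coincide")
    D = (d_obs - mean_b) / (mean_r - mean_b)
    return DResult(
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=float(D),
        p_random=float((d_rand <= d_obs).mean()),
        p_brownian=float((d_brown >= d_obs).mean()),
        n_perm=n_perm,
        seed=seed,
    )
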