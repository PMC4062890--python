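"""Synthetic data with the statistical structure the analyses assume.

Each generator emulates one input of the pipeline so every stage can be
exercised and validated without external downloads:

* star-shaped mutation-count trees with Poisson branch lengths at a fixed
  clock — the substrate for validating rho dating and its Saillard error;
* haplotypes generated down a haplogroup tree (each sample carries the
  defining variants accumulated on its clade's root path; reversion motifs
  remove the reverted ancestral variant), optionally with private noise
  mutations — the substrate for classifier recovery tests;
* pedigrees with binomially occurring per-transmission mutations — the
  substrate for the pedigree rate estimator;
* multinomial regional survey rows — the substrate for the frequency
  table statistics.

All generators are pure functions of their configuration: the same seed
gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dating import MutNode, MutTree
from .haplotree import HaploTree
from .mtvar import (
    HVR1,
    RCRS_LENGTH,
    WHOLE_GENOME,
    HaplotypeProfile,
    Variant,
    VariantKind,
)
from .popstats import CATEGORIES, FrequencyTable

__all__ = [
    "SimConfig",
    "simulate_star_tree",
    "simulate_haplotypes",
    "simulate_pedigree",
    "simulate_region_table",
]


@dataclass
class SimConfig:
    """Configuration shared by the generators; the seed is mandatory."""

    seed: int
    years_per_mutation: float = 3624.0
    true_age_years: float = 10000.0
    n_tips: int = 50
    rate_per_transmission: float = 1 / 90
    #: probability that a realised noise mutation falls inside HVS-I
    hvr1_weight: float = 0.1
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")
        if self.true_age_years < 0 or self.noise_rate < 0:
            raise ValueError("ages and rates must be non-negative")
        if not 0 <= self.rate_per_transmission <= 1:
            raise ValueError("rate_per_transmission must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_star_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> MutTree:
    """Star genealogy of ``n_tips`` lineages of true age ``true_age_years``.

    Each tip branch length is an independent Poisson draw with mean
    ``true_age_years / years_per_mutation``, the event count a linear
    clock accumulates over that time.
    """
    if cfg.n_tips < 2:
        raise ValueError("a star tree needs at least 2 tips")
    rng = rng or cfg.rng()
    lam = cfg.true_age_years / cfg.years_per_mutation
    lengths = rng.poisson(lam, size=cfg.n_tips)
    root = MutNode(name="root")
    for i, l in enumerate(lengths):
        root.add(MutNode(name=f"t{i + 1}", length=int(l), multiplicity=1))
    return MutTree(root)


def _path_profile(tree: HaploTree, name: str) -> frozenset[Variant]:
    """Union of defining variants down the root path.

    A back-mutation motif removes the earlier derived variant at the same
    position (the haplotype has reverted) while the explicit ``!`` token is
    retained as the observable record of the reversion.
    """
    variants: set[Variant] = set()
    for v in tree[name].path_variants():
        if v.kind is VariantKind.BACK_MUTATION:
            variants = {u for u in variants if u.position != v.position}
        variants.add(v)
    return frozenset(variants)


def simulate_haplotypes(
    tree: HaploTree,
    node_weights: dict[str, float],
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, HaplotypeProfile]]:
    """Draw ``n`` labelled haplotypes down a haplogroup tree.

    Clades are sampled with the given weights (must sum to 1); each sample
    carries its clade's root-path variant union. With ``cfg.noise_rate > 0``
    a Poisson number of private transitions is added at positions drawn
    uniformly within HVS-I (probability ``hvr1_weight``) or the rest of the
    molecule, never colliding with path positions.
    """
    names = list(node_weights)
    weights = np.array([node_weights[k] for k in names], dtype=float)
    for name in names:
        if name not in tree:
            raise KeyError(f"unknown node name {name!r}")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("node weights must sum to 1")
    rng = rng or cfg.rng()
    paths = {name: _path_profile(tree, name) for name in names}
    out = []
    choices = rng.choice(len(names), size=n, p=weights)
    for i, ci in enumerate(choices):
        label = names[ci]
        variants = set(paths[label])
        if cfg.noise_rate > 0:
            taken = {v.position for v in variants}
            for _ in range(rng.poisson(cfg.noise_rate)):
                for _attempt in range(100):
                    if rng.random() < cfg.hvr1_weight:
                        pos = int(rng.integers(HVR1[0][0], HVR1[0][1] + 1))
                    else:
                        pos = int(rng.integers(1, RCRS_LENGTH + 1))
                    if pos not in taken:
                        taken.add(pos)
                        variants.add(Variant(pos, VariantKind.TRANSITION))
                        break
        out.append(
            (label, HaplotypeProfile(frozenset(variants), WHOLE_GENOME, f"S{i + 1}"))
        )
    return out


def simulate_pedigree(
    founders: int,
    transmissions: int,
    rate: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[int, list[int]]:
    """Simulate germline mutation events along a maternal pedigree.

    Returns ``(k, events)`` where ``k ~ Binomial(T, rate)`` and ``events``
    lists the (1-based) transmission index of each mutation, uniformly
    placed. ``founders`` only scales bookkeeping (transmissions are given
    as a total count, as pedigree studies report them).
    """
    if transmissions <= 0:
        raise ValueError("transmissions must be positive")
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if founders <= 0:
        raise ValueError("founders must be positive")
    rng = rng or cfg.rng()
    k = int(rng.binomial(transmissions, rate))
    events = sorted(int(x) for x in rng.integers(1, transmissions + 1, size=k))
    return k, events


def simulate_region_table(
    composition: Sequence[float],
    N: int,
    u6_freq: float,
    cfg: SimConfig,
    region: str = "SIM",
    rng: np.random.Generator | None = None,
) -> FrequencyTable:
    """One synthetic survey row: binomial carrier count, multinomial categories.

    ``composition`` gives per-category probabilities over the eight
    categories (shorter vectors are zero-padded on the right) and must sum
    to 1. A zero-carrier draw yields a valid row whose composition is
    flagged undefined by the table statistics.
    """
    import pandas as pd

    probs = np.zeros(len(CATEGORIES))
    if len(composition) > len(CATEGORIES):
        raise ValueError("composition longer than the category list")
    probs[: len(composition)] = composition
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a probability vector summing to 1")
    if not 0 <= u6_freq <= 1:
        raise ValueError("u6_freq must lie in [0, 1]")
    rng = rng or cfg.rng()
    u6 = int(rng.binomial(N, u6_freq))
    counts = rng.multinomial(u6, probs)
    row = {"region": region, "sample_size": N, "u6_count": u6}
    row.update({c: int(x) for c, x in zip(CATEGORIES, counts)})
    return FrequencyTable(pd.DataFrame([row]))
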