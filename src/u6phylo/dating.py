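"""Coalescence dating with the rho statistic and pedigree mutation rates.

The rho statistic is the (multiplicity-weighted) mean number of mutations
separating each sampled lineage from a chosen ancestral node. Under a
linear molecular clock of one mutation every ``years_per_mutation`` years
(default 3624 for the complete molecule), ``age = rho * years_per_mutation``.
Its standard error follows the closed form of Saillard et al.:

    sigma^2 = (1/N^2) * sum_i l_i * n_i^2

summing over the branches below the node, where ``l_i`` is the branch's
mutation count, ``n_i`` the number of sampled descendants below it, and
``N`` the total sample size under the node.

The pedigree estimator turns ``k`` observed germline substitutions in
``T`` mother-to-child transmissions into a per-transmission rate ``k/T``
with exact confidence intervals (Clopper-Pearson binomial and exact
Poisson, both reported), plus unit conversions to per-site-per-million-year
rates and the conventional halving for the male transmission bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

from scipy import stats

__all__ = [
    "MutNode",
    "MutTree",
    "ClockModel",
    "RhoEstimate",
    "PedigreeRate",
    "rho",
    "saillard_sigma",
    "age_from_rho",
    "date_node",
    "pedigree_rate",
    "convert_rate",
    "sex_bias_halve",
    "generation_length",
    "dating_table",
]

RCRS_LENGTH = 16569


@dataclass
class ClockModel:
    """Linear molecular clock: one mutation every ``years_per_mutation`` years."""

    years_per_mutation: float = 3624.0

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")


@dataclass
class MutNode:
    """Node of a mutation-count tree.

    ``length`` is the integer number of mutations on the branch above the
    node; ``multiplicity`` the number of sampled individuals collapsed on a
    tip (internal nodes normally carry 0).
    """

    name: str | None = None
    length: int = 0
    multiplicity: int = 0
    children: list["MutNode"] = field(default_factory=list)
    parent: "MutNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "MutNode") -> "MutNode":
        child.parent = self
        self.children.append(child)
        return child


class MutTree:
    """Rooted tree with branch lengths in mutation counts.

    Tips default to multiplicity 1 if none was given. Construct directly,
    from Newick (``label*count`` tip multiplicities, integer branch
    lengths), or from a child/parent/length table.
    """

    def __init__(self, root: MutNode):
        self.root = root
        for tip in self.tips():
            if tip.multiplicity == 0:
                tip.multiplicity = 1
        self._n_below: dict[int, int] = {}
        self._cache_n(root)

    def _cache_n(self, node: MutNode) -> int:
        n = node.multiplicity if node.is_tip else 0
        for c in node.children:
            n += self._cache_n(c)
        self._n_below[id(node)] = n
        return n

    def n_below(self, node: MutNode) -> int:
        """Number of sampled descendants at or below ``node``."""
        return self._n_below[id(node)]

    def walk(self, node: MutNode | None = None) -> Iterator[MutNode]:
        node = node or self.root
        yield node
        for c in node.children:
            yield from self.walk(c)

    def tips(self, node: MutNode | None = None) -> Iterator[MutNode]:
        return (n for n in self.walk(node or self.root) if n.is_tip)

    def find(self, name: str) -> MutNode:
        for n in self.walk():
            if n.name == name:
                return n
        raise KeyError(name)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "MutTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        root = cls._convert(dtree.seed_node)
        return cls(root)

    @staticmethod
    def _convert(dnode) -> MutNode:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        mult = 0
        name = label
        if label and "*" in label:
            name, mult_s = label.rsplit("*", 1)
            mult = int(mult_s)
        length = dnode.edge.length or 0
        if abs(length - round(length)) > 1e-9:
            raise ValueError(f"branch length {length} is not an integer mutation count")
        node = MutNode(name=name or None, length=int(round(length)), multiplicity=mult)
        for c in dnode.child_nodes():
            node.add(MutTree._convert(c))
        return node

    def to_newick(self) -> str:
        def fmt(node: MutNode) -> str:
            label = node.name or ""
            if node.is_tip and node.multiplicity != 1:
                label = f"{label}*{node.multiplicity}"
            inner = ""
            if node.children:
                inner = "(" + ",".join(fmt(c) for c in node.children) + ")"
            length = f":{node.length}" if node.parent is not None else ""
            return f"{inner}{label}{length}"

        return fmt(self.root) + ";"

    @classmethod
    def from_table(cls, rows) -> "MutTree":
        """Build from (child, parent, length[, multiplicity]) tuples; parent '-' roots."""
        nodes: dict[str, MutNode] = {}
        root = None
        for row in rows:
            child, parent, length = row[0], row[1], int(row[2])
            mult = int(row[3]) if len(row) > 3 else 0
            nodes.setdefault(child, MutNode(name=child))
            nodes[child].length = length
            nodes[child].multiplicity = mult
            if parent == "-":
                root = nodes[child]
            else:
                nodes.setdefault(parent, MutNode(name=parent))
                nodes[parent].add(nodes[child])
        if root is None:
            raise ValueError("no root row (parent '-') in tree table")
        return cls(root)


def _resolve(tree: MutTree, node: MutNode | str | None) -> MutNode:
    if node is None:
        return tree.root
    if isinstance(node, str):
        return tree.find(node)
    return node


def rho(tree: MutTree, node: MutNode | str | None = None) -> float:
    """Multiplicity-weighted mean mutation count from each tip up to ``node``."""
    node = _resolve(tree, node)
    total_n = tree.n_below(node)
    if total_n == 0:
        raise ValueError("node has no sampled descendants")
    total = 0
    for tip in tree.tips(node):
        dist = 0
        n = tip
        while n is not node:
            dist += n.length
            n = n.parent
        total += tip.multiplicity * dist
    return total / total_n


def saillard_sigma(tree: MutTree, node: MutNode | str | None = None) -> float:
    """Standard error of rho: sqrt(sum_i l_i * n_i^2) / N over branches below node."""
    node = _resolve(tree, node)
    total_n = tree.n_below(node)
    if total_n == 0:
        raise ValueError("node has no sampled descendants")
    acc = 0
    for n in tree.walk(node):
        if n is node:
            continue
        acc += n.length * tree.n_below(n) ** 2
    return math.sqrt(acc) / total_n


@dataclass
class RhoEstimate:
    """A rho-based age: mutations, standard error, and years under a clock."""

    rho: float
    sigma: float
    age_years: float
    age_se_years: float

    def interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.age_years - z * self.age_se_years,
                self.age_years + z * self.age_se_years)


def age_from_rho(
    rho_value: float, sigma: float, clock: ClockModel | None = None
) -> RhoEstimate:
    """Convert a rho estimate into years: both the point and its SE scale linearly."""
    clock = clock or ClockModel()
    return RhoEstimate(
        rho_value,
        sigma,
        rho_value * clock.years_per_mutation,
        sigma * clock.years_per_mutation,
    )


def date_node(
    tree: MutTree, node: MutNode | str | None = None, clock: ClockModel | None = None
) -> RhoEstimate:
    """rho + Saillard sigma + clock in one call."""
    return age_from_rho(rho(tree, node), saillard_sigma(tree, node), clock)


def dating_table(tree: MutTree, clock: ClockModel | None = None):
    """Date every named internal node; returns a DataFrame (node, rho, sigma, age, age_se)."""
    import pandas as pd

    rows = []
    for n in tree.walk():
        if n.is_tip or n.name is None:
            continue
        est = date_node(tree, n, clock)
        rows.append(
            {"node": n.name, "rho": est.rho, "sigma": est.sigma,
             "age_years": est.age_years, "age_se_years": est.age_se_years}
        )
    return pd.DataFrame(rows, columns=["node", "rho", "sigma", "age_years", "age_se_years"])


# ---------------------------------------------------------------------------
# pedigree mutation rate

@dataclass
class PedigreeRate:
    """Per-transmission germline substitution rate with exact 95% CIs.

    Both the Clopper-Pearson (exact binomial) and exact Poisson intervals
    are carried, because published pedigree intervals are not always
    attributable to a single standard method.
    """

    k: int
    T: int
    rate_per_transmission: float
    ci95_clopper_pearson: tuple[float, float]
    ci95_poisson: tuple[float, float]

    def per_site_per_my(self, L: int = RCRS_LENGTH, G: float = 25.0) -> float:
        return convert_rate(self.rate_per_transmission, L, G)


def pedigree_rate(k: int, T: int, alpha: float = 0.05) -> PedigreeRate:
    """Estimate a per-transmission mutation rate from k events in T transmissions.

    ``k = 0`` yields a one-sided interval (lower bound exactly 0).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 <= k <= T:
        raise ValueError("k must satisfy 0 <= k <= T")
    rate = k / T
    # exact binomial by beta-quantile inversion
    lo_b = stats.beta.ppf(alpha / 2, k, T - k + 1) if k > 0 else 0.0
    hi_b = stats.beta.ppf(1 - alpha / 2, k + 1, T - k) if k < T else 1.0
    if k == 0:
        hi_b = stats.beta.ppf(1 - alpha, 1, T)  # one-sided upper
    # exact Poisson via gamma quantiles on the event count
    lo_p = stats.gamma.ppf(alpha / 2, k) / T if k > 0 else 0.0
    hi_p = (stats.gamma.ppf(1 - alpha / 2, k + 1) / T
            if k > 0 else stats.gamma.ppf(1 - alpha, 1) / T)
    return PedigreeRate(k, T, rate, (float(lo_b), float(hi_b)), (float(lo_p), float(hi_p)))


def convert_rate(rate_per_transmission: float, L: int = RCRS_LENGTH, G: float = 25.0) -> float:
    """Per-transmission rate -> substitutions per site per million years.

    One transmission spans one generation of ``G`` years over ``L`` sites:
    ``rate / (L * G) * 1e6``. Report to 3 decimals.
    """
    if L <= 0 or G <= 0:
        raise ValueError("L and G must be positive")
    return rate_per_transmission / (L * G) * 1e6


def sex_bias_halve(rate: float) -> float:
    """Halve a pedigree rate for the male transmission bias (sons never transmit)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate / 2.0


def generation_length(found_year: float, ref_year: float, n_generations: int) -> float:
    """Empirical mean generation time from a dated founder to a reference year."""
    if ref_year <= found_year:
        raise ValueError("ref_year must be after found_year")
    if n_generations <= 0:
        raise ValueError("n_generations must be positive")
    return (ref_year - found_year) / n_generations
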