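"""Regional frequency tables, pi diversity, permutation tests, and PCA.

The frequency table follows the layout of regional U6 surveys: one row per
population with its sample size, the number (or percentage) of U6
carriers, and the breakdown of those carriers over the eight HVS-I
categories. Diversity within a region is summarised by pi, the mean
number of pairwise differences between haplotypes, with the Tajima (1983)
sampling variance; regions are compared by a label-shuffling permutation
test on ``|pi_A - pi_B|``. Frequency gradients are tested with Pearson
correlation, and subhaplogroup composition is ordinated by PCA on
correlation-standardised category frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotree import CATEGORIES
from .mtvar import HaplotypeProfile, profile_distance

__all__ = [
    "FrequencyTable",
    "DiversityEstimate",
    "load_table1",
    "u6_frequency",
    "composition",
    "pi_diversity",
    "diversity_compare",
    "gradient_correlation",
    "pca_scores",
    "counts_from_percentages",
]

_BASE_COLS = ["region", "sample_size", "u6_count"]


def counts_from_percentages(percentages: Sequence[float], total: int) -> list[int]:
    """Integer counts from percentages summing to ~100, hitting ``total`` exactly.

    Largest-remainder apportionment: deterministic, and re-validated so the
    per-category counts always sum to the carrier count.
    """
    if total == 0:
        return [0] * len(percentages)
    raw = [p / 100.0 * total for p in percentages]
    counts = [math.floor(x) for x in raw]
    short = total - sum(counts)
    if short < 0:
        raise ValueError("percentages exceed 100 by more than rounding")
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], raw[i]), reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


class FrequencyTable:
    """Region x subhaplogroup counts with sample sizes.

    Wraps a DataFrame with columns ``region``, ``sample_size``,
    ``u6_count`` and one integer column per category. Invariants checked
    on construction: category counts sum to the carrier count and carriers
    never exceed the sample size.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _BASE_COLS + list(CATEGORIES) if c not in df.columns]
        if missing:
            raise ValueError(f"frequency table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        cat = df[list(CATEGORIES)].to_numpy(dtype=int)
        if (cat.sum(axis=1) != df["u6_count"].to_numpy(dtype=int)).any():
            bad = df.loc[cat.sum(axis=1) != df["u6_count"], "region"].tolist()
            raise ValueError(f"category counts do not sum to u6_count for {bad}")
        if (df["u6_count"] > df["sample_size"]).any():
            raise ValueError("u6_count exceeds sample_size")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def regions(self) -> list[str]:
        return self.df["region"].tolist()

    def row(self, region: str) -> pd.Series:
        hit = self.df[self.df["region"] == region]
        if hit.empty:
            raise KeyError(region)
        return hit.iloc[0]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_percentages(cls, df: pd.DataFrame) -> "FrequencyTable":
        """Build from the printed layout: %U6 of N, category % of carriers.

        Percentages are converted to integer counts by rounding against the
        sample size (largest-remainder within categories) and re-validated.
        Missing category entries ('-' or NaN) count as zero.
        """
        rows = []
        for _, r in df.iterrows():
            n = int(r["sample_size"])
            u6 = int(round(float(r["pct_u6"]) / 100.0 * n))
            pcts = [
                0.0 if pd.isna(r[c]) or r[c] in ("-", "") else float(r[c])
                for c in CATEGORIES
            ]
            counts = counts_from_percentages(pcts, u6)
            row = {"region": r["region"], "sample_size": n, "u6_count": u6}
            row.update(dict(zip(CATEGORIES, counts)))
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_csv(cls, path) -> "FrequencyTable":
        df = pd.read_csv(path)
        if "u6_count" in df.columns:
            return cls(df)
        if "pct_u6" in df.columns:
            return cls.from_percentages(df)
        raise ValueError("CSV must carry either count columns or pct_u6 percentages")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    # -- statistics --------------------------------------------------------
    def u6_frequency(self, region: str) -> float:
        return u6_frequency(self.row(region))

    def composition(self, region: str) -> pd.Series:
        return composition(self.row(region))

    def category_matrix(self, as_percentages: bool = True) -> pd.DataFrame:
        """regions x categories matrix (percentage of carriers by default)."""
        m = self.df.set_index("region")[list(CATEGORIES)].astype(float)
        if as_percentages:
            tot = m.sum(axis=1)
            m = m.div(tot.replace(0, np.nan), axis=0) * 100.0
        return m


def u6_frequency(row: pd.Series) -> float:
    """Percentage of U6 carriers in the sample, to 2 decimals."""
    n = int(row["sample_size"])
    if n <= 0:
        raise ValueError("sample_size must be positive")
    return round(100.0 * int(row["u6_count"]) / n, 2)


def composition(row: pd.Series) -> pd.Series:
    """Per-category percentages of the U6 carriers (1 decimal); sums to ~100."""
    u6 = int(row["u6_count"])
    if u6 <= 0:
        raise ValueError("composition undefined for a row with no U6 carriers")
    return pd.Series(
        {c: round(100.0 * int(row[c]) / u6, 1) for c in CATEGORIES}, name=row["region"]
    )


def load_table1() -> FrequencyTable:
    """The shipped worldwide U6 survey table (printed percentage layout)."""
    with resources.files("u6phylo.data").joinpath("u6_survey_table.csv").open() as fh:
        return FrequencyTable.read_csv(fh)


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversityEstimate:
    """pi (mean pairwise differences) with its Tajima-type standard error."""

    pi: float
    se: float
    n: int


def pi_diversity(
    profiles: Sequence[HaplotypeProfile], **distance_kwargs
) -> DiversityEstimate:
    """Mean number of pairwise differences over all unordered pairs.

    The standard error is the square root of Tajima's (1983) variance,

        V = (n+1)/(3(n-1)) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2,

    the form implemented by the standard population-genetics packages for
    the "mean number of pairwise differences" summary.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("pi requires at least two profiles")
    total = sum(
        profile_distance(a, b, **distance_kwargs) for a, b in combinations(profiles, 2)
    )
    pi = total / (n * (n - 1) / 2)
    var = (n + 1) / (3 * (n - 1)) * pi + 2 * (n * n + n + 3) / (9 * n * (n - 1)) * pi * pi
    return DiversityEstimate(pi, math.sqrt(var), n)


def diversity_compare(
    a: Sequence[HaplotypeProfile],
    b: Sequence[HaplotypeProfile],
    n_perm: int = 999,
    seed: int | None = None,
    **distance_kwargs,
) -> float:
    """Two-sided permutation p-value for the pi difference between two groups.

    Group labels are shuffled ``n_perm`` times; p is the add-one estimate
    of how often ``|pi_A - pi_B|`` under relabelling reaches the observed
    difference. Reproducible under a fixed seed.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    na = len(a)
    pooled = list(a) + list(b)
    observed = abs(pi_diversity(a, **distance_kwargs).pi - pi_diversity(b, **distance_kwargs).pi)
    hits = 0
    idx = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(idx)
        pa = [pooled[i] for i in idx[:na]]
        pb = [pooled[i] for i in idx[na:]]
        d = abs(pi_diversity(pa, **distance_kwargs).pi - pi_diversity(pb, **distance_kwargs).pi)
        if d >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def gradient_correlation(
    freq: Sequence[float], longitude: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided t-test p) of frequency against longitude.

    Returns ``(nan, nan)`` with a warning when either vector is constant.
    """
    if len(freq) != len(longitude) or len(freq) < 3:
        raise ValueError("freq and longitude must have equal length >= 3")
    f = np.asarray(freq, dtype=float)
    x = np.asarray(longitude, dtype=float)
    if np.ptp(f) == 0 or np.ptp(x) == 0:
        warnings.warn("correlation undefined: zero variance", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(f, x)
    return float(r), float(p)


def pca_scores(freq_matrix: pd.DataFrame, n_components: int | None = None):
    """PCA of a regions x categories frequency matrix.

    Columns are correlation-standardised (z-scored); constant columns are
    dropped with a warning. The sign of each component is fixed so the
    largest-magnitude loading is positive. Returns ``(scores, loadings,
    explained_variance_ratio)`` with scores/loadings as DataFrames.
    """
    from sklearn.decomposition import PCA

    m = freq_matrix.astype(float)
    const = [c for c in m.columns if np.ptp(m[c].to_numpy()) == 0]
    if const:
        warnings.warn(f"dropping constant columns: {const}", stacklevel=2)
        m = m.drop(columns=const)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 non-constant columns")
    z = (m - m.mean()) / m.std(ddof=0)
    k = n_components or min(z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=m.index, columns=cols),
        pd.DataFrame(loadings, index=cols, columns=m.columns),
        pca.explained_variance_ratio_,
    )
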