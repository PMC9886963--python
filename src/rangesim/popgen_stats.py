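"""Diversity, divergence, differentiation and the comparison statistics.

All diversity statistics operate on haplotypes represented as sorted arrays
of mutation positions (infinite sites: identical positions are identical
alleles by descent).  With M haplotypes carrying a site in k copies, the
number of differing haplotype pairs at that site is k (M - k), which makes
pi computable from a single site-frequency pass instead of explicit pairwise
comparison; tests verify equivalence against the brute-force double loop.

Nucleotide diversity within a group uses all C(2n, 2) haplotype pairs
(including the two within-individual pairs); a ``between_individuals_only``
flag switches to cross-individual pairs, which differs at O(1/n).

F_ST follows the pi-based form 1 - 2 (pi1 + pi2) / (pi1 + 2 pi12 + pi2):
zero without structure, one for fixed differences, and possibly slightly
negative by sampling (reported as computed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "individual_heterozygosity",
    "nucleotide_diversity",
    "pairwise_divergence",
    "fst",
    "normality_check",
    "pairwise_wilcoxon",
    "trend_fit",
    "TrendFit",
    "group_heterozygosities",
]


def _hap_array(h) -> np.ndarray:
    """Accept a Haplotype or a raw sorted position array."""
    return h.muts if hasattr(h, "muts") else np.asarray(h, dtype=float)


def _group_haplotypes(group) -> list:
    """Flatten a group (sequence of haplotype pairs / Individuals) to haplotypes."""
    haps = []
    for item in group:
        pair = item.genome if hasattr(item, "genome") else item
        haps.append(_hap_array(pair[0]))
        haps.append(_hap_array(pair[1]))
    return haps


def individual_heterozygosity(individual, genome_length: float) -> float:
    """Per-site heterozygosity of one diploid.

    The count of positions carried by exactly one of its two haplotypes,
    divided by genome length.  ``individual`` may be an Individual, a
    SampleGroup entry, or a bare (hapA, hapB) pair.
    """
    pair = individual.genome if hasattr(individual, "genome") else individual
    a, b = _hap_array(pair[0]), _hap_array(pair[1])
    return float(np.setxor1d(a, b, assume_unique=True).size) / float(genome_length)


def group_heterozygosities(group, genome_length: float) -> np.ndarray:
    """Individual heterozygosity for every member of a group."""
    return np.array([individual_heterozygosity(g, genome_length) for g in group])


def _site_counts(haps: list) -> tuple:
    """Unique site positions and their copy counts across haplotypes."""
    if not haps:
        return np.empty(0), np.empty(0, dtype=np.int64)
    allpos = np.concatenate(haps) if len(haps) > 1 else haps[0]
    return np.unique(allpos, return_counts=True)


def nucleotide_diversity(group, genome_length: float,
                         between_individuals_only: bool = False) -> float:
    """Mean per-site pairwise difference among a group's haplotypes.

    Default: all C(2n, 2) haplotype pairs of the 2n haplotypes.  With
    ``between_individuals_only`` the two within-individual pairs are
    excluded (pairs from distinct diploids only).
    """
    haps = _group_haplotypes(group)
    n2 = len(haps)
    if n2 < 4:
        raise ValueError("group must contain at least 2 diploid individuals")
    pos, k = _site_counts(haps)
    diff_pairs = float(np.sum(k * (n2 - k)))
    n_pairs = n2 * (n2 - 1) / 2.0
    if between_individuals_only:
        # remove the within-individual comparisons from numerator and denominator
        within = sum(
            np.setxor1d(haps[2 * i], haps[2 * i + 1], assume_unique=True).size
            for i in range(n2 // 2)
        )
        diff_pairs -= float(within)
        n_pairs -= n2 / 2.0
    return diff_pairs / (n_pairs * float(genome_length))


def pairwise_divergence(group1, group2, genome_length: float) -> float:
    """Mean per-site difference over all cross-group haplotype pairs (pi12)."""
    h1 = _group_haplotypes(group1)
    h2 = _group_haplotypes(group2)
    if not h1 or not h2:
        raise ValueError("both groups must be non-empty")
    p1, k1 = _site_counts(h1)
    p2, k2 = _site_counts(h2)
    m1, m2 = len(h1), len(h2)
    allpos = np.unique(np.concatenate([p1, p2]))
    c1 = np.zeros(len(allpos), dtype=np.int64)
    c2 = np.zeros(len(allpos), dtype=np.int64)
    c1[np.searchsorted(allpos, p1)] = k1
    c2[np.searchsorted(allpos, p2)] = k2
    cross_diffs = float(np.sum(c1 * (m2 - c2) + c2 * (m1 - c1)))
    return cross_diffs / (m1 * m2 * float(genome_length))


def fst(pi1: float, pi2: float, pi12: float) -> float:
    """Differentiation F_ST = 1 - 2 (pi1 + pi2) / (pi1 + 2 pi12 + pi2)."""
    if min(pi1, pi2, pi12) < 0:
        raise ValueError("diversities must be non-negative")
    denom = pi1 + 2.0 * pi12 + pi2
    if denom == 0:
        raise ValueError("F_ST undefined: no variation within or between groups")
    return 1.0 - 2.0 * (pi1 + pi2) / denom


# ---------------------------------------------------------------------------
# comparison statistics


def normality_check(values) -> tuple:
    """Shapiro-Wilk test; returns (statistic, p-value).

    Used to justify the nonparametric group comparisons.  Rejects samples
    of fewer than 3 values or degenerate (constant) samples.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon(groups: dict, adjust: str = "holm",
                      kind: str = "rank-sum") -> pd.DataFrame:
    """All pairwise nonparametric group comparisons, multiplicity-adjusted.

    ``groups`` maps label -> 1-D sample of values (e.g. individual pi).
    ``kind='rank-sum'`` (default) uses the unpaired Mann-Whitney U test --
    the groups here are different individuals at different times;
    ``kind='signed-rank'`` uses the paired Wilcoxon test on equal-length
    samples.  P-values are adjusted with ``adjust`` (any statsmodels
    method; 'none' disables).  Returns a symmetric label-indexed DataFrame
    with unit diagonal.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    pairs = list(combinations(labels, 2))
    raw = []
    for la, lb in pairs:
        a, b = np.asarray(groups[la], float), np.asarray(groups[lb], float)
        if kind == "rank-sum":
            p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif kind == "signed-rank":
            if len(a) != len(b):
                raise ValueError("signed-rank comparison needs equal-length samples")
            p = 1.0 if np.all(a == b) else sps.wilcoxon(a, b).pvalue
        else:
            raise ValueError(f"unknown test kind {kind!r}")
        raw.append(float(p))
    if adjust and adjust != "none":
        adj = multipletests(raw, method=adjust)[1]
    else:
        adj = np.asarray(raw)
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (la, lb), p in zip(pairs, adj):
        mat.loc[la, lb] = mat.loc[lb, la] = float(min(p, 1.0))
    return mat


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    stderr: float


def trend_fit(t, y) -> TrendFit:
    """Ordinary least squares of a statistic on timestep.

    Returns slope, intercept, coefficient of determination and the slope's
    two-sided p-value.  Rejects fewer than 3 points or constant timesteps.
    """
    ta = np.asarray(t, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~(np.isnan(ta) | np.isnan(ya))
    ta, ya = ta[keep], ya[keep]
    if ta.size < 3:
        raise ValueError("trend fit needs at least 3 points")
    if np.ptp(ta) == 0:
        raise ValueError("timesteps are constant")
    res = sps.linregress(ta, ya)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        pvalue=float(res.pvalue),
        stderr=float(res.stderr),
    )
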