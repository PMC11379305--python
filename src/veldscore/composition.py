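"""Between-group compositional statistics: Bray-Curtis, ANOSIM, SIMPER.

These are implemented here rather than delegated, because the exact
conventions matter for reproducibility:

* Bray-Curtis dissimilarity BC(x, y) = 1 - 2 sum_i min(x_i, y_i) /
  (sum_i x_i + sum_i y_i) on raw occurrence counts.
* ANOSIM (Clarke) ranks all n(n-1)/2 pairwise dissimilarities (average ranks
  on ties) and computes R = (rbar_between - rbar_within) / (M/2) with
  M = n(n-1)/2, so R lies in [-1, 1].  Significance is by label permutation:
  exact enumeration over all distinct group assignments when that count is
  small, otherwise Monte-Carlo with the +1/+1 rule
  p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
* SIMPER (Clarke) decomposes each between-group pair's Bray-Curtis value into
  per-species terms |x_i - y_i| / (sum x + sum y), which sum exactly to the
  pair's dissimilarity, then averages over all between-group pairs.

A greedy collinearity pre-screen for environmental/soil variable tables is
included: of every pair with |Pearson r| above a threshold, the later-listed
variable is dropped.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .survey_io import AbundanceMatrix

__all__ = [
    "DissimilarityMatrix",
    "AnosimResult",
    "SimperResult",
    "bray_curtis",
    "bray_curtis_pair",
    "anosim",
    "simper",
    "collinearity_screen",
    "EXACT_ENUMERATION_LIMIT",
]

# exact permutation enumeration is used when the number of distinct label
# assignments is at most this
EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class DissimilarityMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix over sites."""

    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def mean_dissimilarity(self) -> float:
        return float(self.condensed().mean())


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    method: str  # "exact" or "montecarlo"
    seed: int | None


@dataclass
class SimperResult:
    """Species contributions to mean between-group Bray-Curtis dissimilarity.

    ``table`` rows are sorted by descending contribution and carry the mean
    contribution (on the 0-1 dissimilarity scale), the percent of the overall
    mean dissimilarity, and the running cumulative percent.
    ``overall_mean_dissimilarity`` is in percent.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame
    overall_mean_dissimilarity: float


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = x.sum() + y.sum()
    if denom == 0:
        warnings.warn(
            "both abundance vectors are all-zero; dissimilarity defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis(matrix: AbundanceMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between all sites."""
    counts = np.asarray(matrix.counts, dtype=float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least two sites")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn(
            "some sites have all-zero counts; their dissimilarity to other "
            "all-zero sites is defined as 0",
            stacklevel=2,
        )
    # sum of elementwise minima for every pair, vectorised over one axis
    values = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(counts[i], counts).sum(axis=1)
        denom = totals[i] + totals
        with np.errstate(invalid="ignore", divide="ignore"):
            row = 1.0 - 2.0 * mins / denom
        row[denom == 0] = 0.0
        values[i] = row
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return DissimilarityMatrix(site_ids=list(matrix.site_ids), values=values)


def _anosim_R(
    rank_matrix: np.ndarray, labels: np.ndarray, M: int
) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    within_mask = same[iu]
    ranks = rank_matrix[iu]
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return float((r_between - r_within) / (M / 2.0))


def _distinct_assignments(labels: np.ndarray) -> int:
    """Number of distinct ways to assign the multiset of labels to positions."""
    n = labels.size
    count = math.factorial(n)
    for _, size in zip(*np.unique(labels, return_counts=True)):
        count //= math.factorial(int(size))
    return count


def anosim(
    dm: DissimilarityMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "auto",
) -> AnosimResult:
    """Analysis of similarities: rank-based test of group separation.

    ``method`` is ``"auto"`` (exact enumeration when the number of distinct
    label assignments is at most ``EXACT_ENUMERATION_LIMIT``, Monte-Carlo
    otherwise), ``"exact"`` or ``"montecarlo"``.
    """
    groups = np.asarray(groups)
    if groups.size != dm.n:
        raise ValueError("one group label per site required")
    uniq, sizes = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("at least two groups required")
    if np.any(sizes < 2):
        singles = uniq[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than two members: {singles}")

    n = dm.n
    M = n * (n - 1) // 2
    condensed = dm.condensed()
    if np.all(condensed == condensed[0]):
        warnings.warn(
            "all dissimilarities are identical; R defined as 0", stacklevel=2
        )
        return AnosimResult(0.0, 1.0, 0, "degenerate", seed)

    # ranks of the condensed dissimilarities, spread back to a square matrix
    ranks = rankdata(condensed)  # average ranks on ties
    rank_matrix = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    rank_matrix[iu] = ranks
    rank_matrix = rank_matrix + rank_matrix.T

    observed = _anosim_R(rank_matrix, groups, M)

    total_assignments = _distinct_assignments(groups)
    if method == "auto":
        method = (
            "exact" if total_assignments <= EXACT_ENUMERATION_LIMIT else "montecarlo"
        )
    if method == "exact":
        # enumerate distinct multiset permutations of the labels
        count_ge = 0
        total = 0
        for perm in _multiset_permutations(groups):
            total += 1
            if _anosim_R(rank_matrix, perm, M) >= observed - 1e-12:
                count_ge += 1
        p = count_ge / total
        return AnosimResult(observed, p, total, "exact", seed)
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if _anosim_R(rank_matrix, perm, M) >= observed - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(observed, p, n_permutations, "montecarlo", seed)


def _multiset_permutations(labels: np.ndarray):
    """Yield each distinct arrangement of the label multiset exactly once."""
    uniq = sorted(set(labels.tolist()))
    n = labels.size
    counts = {u: int(np.sum(labels == u)) for u in uniq}

    # choose positions for each label class in turn
    def rec(positions: list[int], remaining: dict[str, int], acc):
        if not remaining:
            out = np.empty(n, dtype=labels.dtype)
            for lab, pos in acc:
                out[list(pos)] = lab
            yield out
            return
        lab = next(iter(remaining))
        k = remaining[lab]
        rest = {u: c for u, c in remaining.items() if u != lab}
        for pos in itertools.combinations(positions, k):
            left = [p for p in positions if p not in pos]
            yield from rec(left, rest, acc + [(lab, pos)])

    yield from rec(list(range(n)), counts, [])


def simper(
    matrix: AbundanceMatrix, groups: Sequence[str] | None = None
) -> list[SimperResult]:
    """Pairwise SIMPER decomposition for every pair of groups.

    Group labels default to the matrix's location labels.  For each pair of
    sites (one per group), species i contributes |x_i - y_i| / (sum x + sum y)
    to the pair's Bray-Curtis dissimilarity; contributions are averaged over
    all between-group site pairs.
    """
    if groups is None:
        if not matrix.locations:
            raise ValueError("no group labels supplied and matrix has none")
        groups = matrix.location_labels()
    groups = np.asarray(groups)
    if groups.size != len(matrix.site_ids):
        raise ValueError("one group label per site required")
    counts = np.asarray(matrix.counts, dtype=float)
    uniq = sorted(set(groups.tolist()))
    if len(uniq) < 2:
        raise ValueError("at least two groups required")

    results: list[SimperResult] = []
    for ga, gb in itertools.combinations(uniq, 2):
        idx_a = np.flatnonzero(groups == ga)
        idx_b = np.flatnonzero(groups == gb)
        contribs = np.zeros(counts.shape[1])
        n_pairs = 0
        for i in idx_a:
            for j in idx_b:
                denom = counts[i].sum() + counts[j].sum()
                if denom == 0:
                    continue
                contribs += np.abs(counts[i] - counts[j]) / denom
                n_pairs += 1
        if n_pairs == 0:
            raise ValueError(f"no comparable site pairs between {ga} and {gb}")
        contribs /= n_pairs
        overall = contribs.sum()  # mean between-group BC on the 0-1 scale
        order = np.argsort(-contribs, kind="stable")
        pct = (
            100.0 * contribs[order] / overall
            if overall > 0
            else np.zeros_like(contribs[order])
        )
        table = pd.DataFrame(
            {
                "species_name": [matrix.species_names[k] for k in order],
                "mean_contribution": contribs[order],
                "percent_contribution": pct,
                "cumulative_percent": np.cumsum(pct),
            }
        ).set_index("species_name")
        results.append(
            SimperResult(
                group_a=str(ga),
                group_b=str(gb),
                table=table,
                overall_mean_dissimilarity=100.0 * overall,
            )
        )
    return results


def collinearity_screen(
    table: pd.DataFrame, threshold: float = 0.96
) -> tuple[list[str], dict[str, str]]:
    """Greedy collinearity pre-screen on a samples x variables table.

    For every variable pair with |Pearson r| > ``threshold`` the later-listed
    variable is dropped in favour of the earlier one.  Returns the retained
    variable names (original order) and a dropped -> kept mapping.
    Zero-variance variables are excluded from the correlations with a warning
    but retained.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    variances = table.var(axis=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(
            f"zero-variance variables excluded from correlation: {constant}",
            stacklevel=2,
        )
    candidates = [c for c in table.columns if c not in constant]
    corr = table[candidates].corr(method="pearson").abs()
    dropped: dict[str, str] = {}
    for i, earlier in enumerate(candidates):
        if earlier in dropped:
            continue
        for later in candidates[i + 1 :]:
            if later in dropped:
                continue
            if corr.loc[earlier, later] > threshold:
                dropped[later] = earlier
    retained = [c for c in table.columns if c not in dropped]
    return retained, dropped
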