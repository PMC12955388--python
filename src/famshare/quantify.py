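"""Abundance normalisation, alpha diversity and pairwise dissimilarity.

Shannon uses natural log.  Spearman uses average ranks for ties; an
all-tied vector is defined as rho = 0 with p = 1.  The within/between
comparison uses the Wilcoxon rank-sum test, exact when both groups have
at most 10 members and no ties, normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DistanceMatrix, FamilyCohort, Role, validate_abundance

__all__ = [
    "DiversityResult",
    "TrendResult",
    "rpkm",
    "shannon",
    "shannon_table",
    "bray_curtis",
    "within_between_test",
    "child_parent_trend",
    "diversity_similarity_trend",
]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float


@dataclass(frozen=True)
class TrendResult:
    spearman_rho: float
    p_value: float
    n_pairs: int


def rpkm(
    read_counts: pd.DataFrame,
    genome_lengths_bp: dict[str, float] | pd.Series,
    total_mapped_reads: dict[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of genome per million mapped reads.

    ``read_counts`` is samples x taxa.  ``total_mapped_reads`` defaults to
    the per-sample row sum.  value = count / ((length/1000) * (total/1e6)).
    """
    counts = read_counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    lengths = pd.Series(genome_lengths_bp).reindex(counts.columns)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"no genome length for taxa {missing}")
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    if total_mapped_reads is None:
        totals = counts.sum(axis=1)
    else:
        totals = pd.Series(total_mapped_reads).reindex(counts.index)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"zero total mapped reads in sample(s) {list(zero.index)}"
        )
    out = counts.div(lengths / 1000.0, axis=1).div(totals / 1e6, axis=0)
    return validate_abundance(out)


def shannon(abundance_row: pd.Series | np.ndarray, sample_id: str = "") -> DiversityResult:
    """Shannon index H = -sum p ln p over the positive entries, in nats."""
    x = np.asarray(abundance_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError(f"sample {sample_id or '<row>'}: all-zero abundance row")
    p = x / x.sum()
    return DiversityResult(sample_id, float(-(p * np.log(p)).sum()))


def shannon_table(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index as a tidy frame."""
    rows = [shannon(abundance.loc[sid], str(sid)) for sid in abundance.index]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows],
         "shannon": [r.shannon for r in rows]}
    )


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between the rows of ``matrix``."""
    validate_abundance(matrix)
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    row_sums = x.sum(axis=1)
    zero_rows = np.nonzero(row_sums == 0)[0]
    if zero_rows.size >= 2:
        pair = (matrix.index[zero_rows[0]], matrix.index[zero_rows[1]])
        raise ValueError(f"distance undefined for all-zero row pair {pair}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        tot = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = diff / tot
    d = d + d.T
    return DistanceMatrix([str(l) for l in matrix.index], d)


def _ranksum_p(within: np.ndarray, between: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value."""
    if np.all(within == within[0]) and np.all(between == within[0]):
        return 1.0  # identical constant distributions
    ties = len(np.unique(np.concatenate([within, between]))) < (
        len(within) + len(between)
    )
    if len(within) <= 10 and len(between) <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        within, between, alternative="two-sided", method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


def within_between_test(
    dist: DistanceMatrix, cohort: FamilyCohort
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split pairwise distances into same-family and cross-family sets.

    Returns (within_values, between_values, two-sided rank-sum p).
    """
    fam = {s.sample_id: s.family_id for s in cohort.samples}
    for label in dist.labels:
        if label not in fam:
            raise KeyError(f"matrix label {label!r} not in cohort")
    within, between = [], []
    n = len(dist)
    for i in range(n):
        for j in range(i + 1, n):
            v = dist.values[i, j]
            if fam[dist.labels[i]] == fam[dist.labels[j]]:
                within.append(v)
            else:
                between.append(v)
    if not within:
        raise ValueError("cohort contains no within-family pair")
    within_a, between_a = np.asarray(within), np.asarray(between)
    return within_a, between_a, _ranksum_p(within_a, between_a)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with the all-tied convention rho=0, p=1."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def child_parent_trend(dist: DistanceMatrix, cohort: FamilyCohort) -> TrendResult:
    """Correlate each child's age with its mean distance to enrolled parents."""
    parents_by_family: dict[str, list[str]] = {}
    for s in cohort.samples:
        if s.role in (Role.FATHER, Role.MOTHER):
            parents_by_family.setdefault(s.family_id, []).append(s.sample_id)
    ages, dists = [], []
    label_set = set(dist.labels)
    for s in cohort.samples:
        if s.role is not Role.CHILD or s.sample_id not in label_set:
            continue
        parents = [
            p for p in parents_by_family.get(s.family_id, []) if p in label_set
        ]
        if not parents:
            continue
        ages.append(s.age)
        dists.append(np.mean([dist.get(s.sample_id, p) for p in parents]))
    if len(ages) < 3:
        raise ValueError(
            f"need >=3 (child, parent) co-family pairs, found {len(ages)}"
        )
    rho, p = _spearman(np.asarray(ages), np.asarray(dists))
    return TrendResult(rho, p, len(ages))


def diversity_similarity_trend(
    dist: DistanceMatrix,
    diversity: pd.DataFrame | list[DiversityResult],
    cohort: FamilyCohort,
) -> TrendResult:
    """Mean Shannon of each within-family pair vs their distance."""
    if isinstance(diversity, pd.DataFrame):
        hmap = dict(zip(diversity["sample_id"], diversity["shannon"]))
    else:
        hmap = {r.sample_id: r.shannon for r in diversity}
    label_set = set(dist.labels)
    xs, ys = [], []
    for a, b in cohort.within_family_pairs():
        if a not in label_set or b not in label_set:
            continue
        xs.append(0.5 * (hmap[a] + hmap[b]))
        ys.append(dist.get(a, b))
    if len(xs) < 3:
        raise ValueError(f"need >=3 within-family pairs, found {len(xs)}")
    rho, p = _spearman(np.asarray(xs), np.asarray(ys))
    return TrendResult(rho, p, len(xs))
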