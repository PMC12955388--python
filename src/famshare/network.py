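"""Spearman co-occurrence networks among taxa.

Edges require strict |rho| > rho_min and strict |rho| < 1 — the band is
applied literally, so exactly-monotone duplicates carry no edge; pass
``include_perfect=True`` to relax the upper bound to <=1 (for the
reading that only self-pairs were meant to be excluded).

Spearman p-values use exact permutation when n <= 8 and the
t-approximation otherwise.  No multiple-testing correction is applied
by default; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _iterperms

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationEdge", "correlation_network", "core_nodes"]


@dataclass(frozen=True)
class CorrelationEdge:
    taxon_a: str
    taxon_b: str
    rho: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for |rho| >= |rho_obs| over all n! orderings."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = total = 0
    for perm in _iterperms(range(n)):
        r = np.corrcoef(rx[list(perm)], ry)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if x.size <= 8:
        return rho, _spearman_exact_p(x, y, rho)
    return rho, float(p_t)


def correlation_network(
    profiles: pd.DataFrame,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    include_perfect: bool = False,
    fdr: bool = False,
) -> list[CorrelationEdge]:
    """All taxon pairs with |rho| in the configured band and p < p_max.

    ``profiles`` is taxa x samples.  Zero-variance taxa are excluded
    with a warning.  With ``fdr=True``, p-values are Benjamini-Hochberg
    adjusted before thresholding.
    """
    if profiles.shape[1] < 4:
        raise ValueError("need >=4 samples")
    x = profiles.to_numpy(dtype=float)
    keep = []
    for i, taxon in enumerate(profiles.index):
        if np.all(x[i] == x[i, 0]):
            warnings.warn(f"taxon {taxon!r} has zero variance; excluded",
                          stacklevel=2)
        else:
            keep.append(i)
    candidates: list[tuple[str, str, float, float]] = []
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1:]:
            rho, p = _spearman(x[i], x[j])
            if math.isnan(rho):
                continue
            upper_ok = abs(rho) <= 1.0 if include_perfect else abs(rho) < 1.0 - 1e-12
            if abs(rho) > rho_min and upper_ok:
                candidates.append(
                    (str(profiles.index[i]), str(profiles.index[j]), rho, p)
                )
    if fdr and candidates:
        ps = np.array([c[3] for c in candidates])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, ps[idx] * m / (rank_pos + 1))
            adj[idx] = running
        candidates = [
            (a, b, r, float(q)) for (a, b, r, _), q in zip(candidates, adj)
        ]
    return [
        CorrelationEdge(a, b, r, p)
        for a, b, r, p in candidates
        if p < p_max
    ]


def core_nodes(edges: list[CorrelationEdge]) -> list[str]:
    """Taxa attaining the maximum degree (all ties returned, sorted)."""
    if not edges:
        return []
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.taxon_a] = degree.get(e.taxon_a, 0) + 1
        degree[e.taxon_b] = degree.get(e.taxon_b, 0) + 1
    top = max(degree.values())
    return sorted(t for t, d in degree.items() if d == top)
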