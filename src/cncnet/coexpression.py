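"""Coding-noncoding co-expression (CNC) network construction.

Every (noncoding, coding) probe pair is scored by the Pearson correlation of
its expression across all samples (both groups pooled), the t-transform
p-value, and BH FDR over the full pair family.  An edge exists when
``|r| >= r_min AND p < p_max AND q < q_max``; the sign (positive/negative) is
kept so negative correlations can be rendered distinctly (dashed) on export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .diffexpr import ExpressionMatrix, bh_adjust
from .errors import DomainError


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation of two vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("vectors must be 1-D of equal length")
    if x.size < 3:
        raise DomainError("need >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    if nx == 0.0 or ny == 0.0:
        raise DomainError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / (nx * ny), -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for H0: rho = 0 via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise DomainError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise DomainError("|r| must be <= 1")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class CncEdge:
    nc_id: str
    coding_id: str
    r: float
    p: float
    q: float
    sign: str  # positive | negative


@dataclass
class CncResult:
    edges: list
    n_pairs_tested: int
    n_skipped_constant: int
    thresholds: dict


def build_cnc(matrix: ExpressionMatrix, nc_ids: Sequence[str],
              coding_ids: Sequence[str], r_min: float = 0.90,
              p_max: float = 0.01, q_max: float = 0.01,
              log_scale: bool = True) -> CncResult:
    """Evaluate all |nc_ids| x |coding_ids| pairs across the pooled samples.

    Correlation is computed on log2 intensities by default (``log_scale``),
    the microarray convention.  Constant probes are skipped (counted, not
    fatal).  BH runs over the full tested-pair family.  Edges are sorted by
    (nc_id, coding_id).
    """
    nc_ids = sorted(nc_ids)
    coding_ids = sorted(coding_ids)
    missing = (set(nc_ids) | set(coding_ids)) - set(matrix.values.index)
    if missing:
        raise DomainError(f"ids not in matrix: {sorted(missing)[:3]}")
    thresholds = {"r_min": r_min, "p_max": p_max, "q_max": q_max}
    if not nc_ids or not coding_ids:
        return CncResult([], 0, 0, thresholds)

    X = matrix.values.loc[nc_ids].to_numpy(float)
    Y = matrix.values.loc[coding_ids].to_numpy(float)
    if log_scale:
        X = np.log2(X)
        Y = np.log2(Y)
    n = X.shape[1]

    def _standardize(mat):
        c = mat - mat.mean(axis=1, keepdims=True)
        norm = np.sqrt((c * c).sum(axis=1))
        const = norm == 0.0
        norm[const] = 1.0
        return c / norm[:, None], const

    Xs, x_const = _standardize(X)
    Ys, y_const = _standardize(Y)
    n_skipped = int(x_const.sum()) * len(coding_ids) + int(y_const.sum()) * len(nc_ids) \
        - int(x_const.sum()) * int(y_const.sum())

    R = np.clip(Xs @ Ys.T, -1.0, 1.0)
    valid = ~np.outer(x_const, y_const) & ~x_const[:, None] & ~y_const[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(T), n - 2)
    P[np.abs(R) >= 1.0] = 0.0

    flat_p = P[valid]
    Q = np.full_like(P, np.nan)
    if flat_p.size:
        Q[valid] = bh_adjust(flat_p)

    passing = valid & (np.abs(R) >= r_min) & (P < p_max) & (Q < q_max)
    edges = []
    ii, jj = np.nonzero(passing)
    for i, j in zip(ii.tolist(), jj.tolist()):
        r = float(R[i, j])
        edges.append(CncEdge(nc_ids[i], coding_ids[j], r, float(P[i, j]),
                             float(Q[i, j]), "positive" if r > 0 else "negative"))
    edges.sort(key=lambda e: (e.nc_id, e.coding_id))
    return CncResult(edges, int(valid.sum()), n_skipped, thresholds)
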