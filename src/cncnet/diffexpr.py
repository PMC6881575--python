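"""Differential expression for two-group (control vs case) linear intensities.

Per probe: fold change on the linear scale, a two-tailed unpaired Student
t-test (pooled variance by default, Welch optional), Benjamini-Hochberg FDR
within each RNA-class stratum, and the joint significance rule
``fc >= fc_min AND p < p_max AND q < q_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError

GROUPS = ("control", "case")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of positive linear-scale intensities.

    ``values``: DataFrame indexed by probe_id, columns are sample ids.
    ``rna_type``: Series (probe -> mRNA/lncRNA/circRNA).
    ``groups``: Series (sample -> control/case).
    """

    values: pd.DataFrame
    rna_type: pd.Series
    groups: pd.Series

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DomainError(f"duplicated probe_id {dup!r}")
        if self.values.isna().any().any():
            raise DomainError("missing values in expression matrix")
        if (self.values.to_numpy() <= 0).any():
            raise DomainError("expression intensities must be > 0")
        if not set(self.groups.unique()) <= set(GROUPS):
            raise DomainError(f"group labels must be in {GROUPS}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise DomainError(f"need >= 2 samples in group {g!r}")
        missing = set(self.values.index) - set(self.rna_type.index)
        if missing:
            raise DomainError(f"rna_type missing for probes: {sorted(missing)[:3]}")
        self.rna_type = self.rna_type.loc[self.values.index]
        self.groups = self.groups.loc[self.values.columns]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> np.ndarray:
        return self.values[self.samples_in(group)].to_numpy(float)

    def ids_of_type(self, rna_type: str) -> list[str]:
        return list(self.rna_type.index[self.rna_type == rna_type])


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    rna_type: str
    fc: float
    direction: str  # up | down | none
    p: float
    q: float
    passes: bool


def fold_change(control_values, case_values) -> tuple[float, str]:
    """Fold-change magnitude (>= 1) and direction from linear-scale means."""
    c = np.asarray(control_values, float)
    k = np.asarray(case_values, float)
    if c.size == 0 or k.size == 0:
        raise DomainError("both groups must be non-empty")
    if (c <= 0).any() or (k <= 0).any():
        raise DomainError("intensities must be > 0")
    r = k.mean() / c.mean()
    if r > 1:
        return float(r), "up"
    if r < 1:
        return float(1.0 / r), "down"
    return 1.0, "none"


def student_t_pvalue(control_values, case_values, welch: bool = False) -> float:
    """Two-tailed unpaired t-test p-value (pooled variance unless welch).

    Zero pooled variance with equal means returns p = 1 by convention; with
    unequal means the statistic is undefined and a DegenerateInputError is
    raised.
    """
    c = np.asarray(control_values, float)
    k = np.asarray(case_values, float)
    if c.size < 2 or k.size < 2:
        raise DomainError("each group needs >= 2 values")
    pooled = ((c.size - 1) * c.var(ddof=1) + (k.size - 1) * k.var(ddof=1)) / (
        c.size + k.size - 2
    )
    if pooled == 0.0:
        if c.mean() == k.mean():
            return 1.0
        raise DegenerateInputError("zero pooled variance with unequal means")
    return float(stats.ttest_ind(k, c, equal_var=not welch).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i}(p_(j) * m / j), capped
    at 1, returned in the input order.

    Implemented directly (sorted p * m / rank, right-to-left running minimum)
    so the arithmetic matches the textbook definition term for term.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class DEAnalysis:
    """Full differential-expression output."""

    table: pd.DataFrame  # probe_id-indexed: rna_type, fc, direction, p, q, passes
    results: list[DEResult]
    partitions: dict  # (rna_type, direction) -> sorted list of passing probe ids
    thresholds: dict
    errors: list = field(default_factory=list)  # (probe_id, message)

    def passing_ids(self, rna_type: str | None = None,
                    direction: str | None = None) -> list[str]:
        t = self.table[self.table["passes"]]
        if rna_type is not None:
            t = t[t["rna_type"] == rna_type]
        if direction is not None:
            t = t[t["direction"] == direction]
        return sorted(t.index)


def run_de(matrix: ExpressionMatrix, fc_min: float = 2.0, p_max: float = 0.05,
           q_max: float = 0.05, welch: bool = False, pool_strata: bool = False,
           log2_input: bool = False, log_scale: bool = True) -> DEAnalysis:
    """Vectorized per-probe DE with BH applied within each rna_type stratum
    (the three RNA classes come from separate array designs; ``pool_strata``
    adjusts across all probes instead).

    Fold change is always a ratio of linear-scale group means.  The t-test
    runs on log2-transformed intensities by default (``log_scale``), the
    microarray convention; ``log2_input`` declares that the stored values are
    already log2 (they are exponentiated for the fold change).
    """
    if log2_input:
        linear = np.power(2.0, matrix.values.to_numpy(float))
        logged = matrix.values.to_numpy(float)
    else:
        linear = matrix.values.to_numpy(float)
        logged = np.log2(linear)
    sample_idx = {s: i for i, s in enumerate(matrix.values.columns)}
    ctrl_cols = [sample_idx[s] for s in matrix.samples_in("control")]
    case_cols = [sample_idx[s] for s in matrix.samples_in("case")]
    n1, n2 = len(ctrl_cols), len(case_cols)

    mean_c = linear[:, ctrl_cols].mean(axis=1)
    mean_k = linear[:, case_cols].mean(axis=1)
    ratio = mean_k / mean_c
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "none"))

    tmat = logged if log_scale else linear
    ctrl = tmat[:, ctrl_cols]
    case = tmat[:, case_cols]
    var_c = ctrl.var(axis=1, ddof=1)
    var_k = case.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * var_c + (n2 - 1) * var_k) / (n1 + n2 - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch).pvalue
    p = np.asarray(p, float)

    errors: list[tuple[str, str]] = []
    zero_var = pooled == 0.0
    eq_means = mean_c == mean_k
    p[zero_var & eq_means] = 1.0  # flat probe convention
    bad = zero_var & ~eq_means
    for pid in np.asarray(matrix.probe_ids)[bad]:
        errors.append((str(pid), "zero pooled variance with unequal means"))
    p[bad] = np.nan

    rna = matrix.rna_type.to_numpy()
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if pool_strata:
        strata = [valid]
    else:
        strata = [valid & (rna == t) for t in pd.unique(rna)]
    for mask in strata:
        if mask.any():
            q[mask] = bh_adjust(p[mask])

    passes = (fc >= fc_min) & (p < p_max) & (q < q_max)
    passes &= ~np.isnan(p)

    table = pd.DataFrame(
        {
            "rna_type": rna,
            "fc": fc,
            "direction": direction,
            "p": p,
            "q": q,
            "passes": passes,
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )
    results = [
        DEResult(pid, row.rna_type, float(row.fc), str(row.direction),
                 float(row.p), float(row.q), bool(row.passes))
        for pid, row in table.iterrows()
    ]
    partitions: dict = {}
    for t in pd.unique(rna):
        for d in ("up", "down"):
            ids = sorted(table.index[(table["rna_type"] == t)
                                     & (table["direction"] == d)
                                     & table["passes"]])
            partitions[(t, d)] = ids
    thresholds = {"fc_min": fc_min, "p_max": p_max, "q_max": q_max,
                  "welch": welch, "pool_strata": pool_strata}
    return DEAnalysis(table, results, partitions, thresholds, errors)
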