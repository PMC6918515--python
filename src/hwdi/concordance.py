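"""Agreement between two state rankings: Spearman rank correlation (with an
optional Bonferroni factor), tercile Cohen's kappa, and per-state
rank-difference summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _schema as S

__all__ = [
    "ConcordanceReport",
    "spearman_with_bonferroni",
    "assign_terciles",
    "cohens_kappa",
    "rank_difference_summary",
    "compare_rankings",
]


class RankValidationError(ValueError):
    """Raised when rank vectors are malformed (length mismatch, not a
    bijection onto 1..n, ...)."""


def _as_aligned_series(ranks_a, ranks_b):
    a = pd.Series(ranks_a)
    b = pd.Series(ranks_b)
    if len(a) != len(b):
        raise RankValidationError("rank vectors must have equal length")
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise RankValidationError("rank vectors must share the same labels")
    return a.astype(float), b.astype(float)


def _check_bijection(ranks: pd.Series) -> None:
    n = len(ranks)
    if sorted(ranks.astype(int)) != list(range(1, n + 1)):
        raise RankValidationError("ranks must be a bijection onto 1..n")


def spearman_with_bonferroni(
    ranks_a,
    ranks_b,
    m_comparisons: int = 1,
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rho between two rank vectors with a Bonferroni-adjusted p.

    ``method='t'`` uses the t-approximation with n-2 degrees of freedom;
    ``method='exact'`` enumerates all permutations of one vector (n <= 8)
    and reports the two-sided tail fraction.  The p-value is multiplied by
    ``m_comparisons`` and capped at 1.
    """
    a, b = _as_aligned_series(ranks_a, ranks_b)
    n = len(a)
    if n < 3:
        raise RankValidationError("Spearman p-value undefined for n < 3")
    if m_comparisons < 1:
        raise RankValidationError("m_comparisons must be >= 1")
    if method == "t":
        rho, p = stats.spearmanr(a.to_numpy(), b.to_numpy())
        rho, p = float(rho), float(p)
    elif method == "exact":
        if n > 8:
            raise RankValidationError("exact permutation method limited to n <= 8")
        rho = float(stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic)
        bv = b.to_numpy()
        hits = 0
        total = 0
        for perm in permutations(bv):
            r = float(stats.spearmanr(a.to_numpy(), np.asarray(perm)).statistic)
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = hits / total
    else:
        raise RankValidationError(f"unknown method {method!r}")
    return rho, min(1.0, p * m_comparisons)


def tercile_sizes(n: int) -> tuple[int, int, int]:
    """Bin sizes for an n-state ranking split into three ordered bins,
    largest bin first (n=49 gives 17/16/16)."""
    s1 = -(-n // 3)
    s2 = -(-(n - s1) // 2)
    return s1, s2, n - s1 - s2


def assign_terciles(ranks) -> pd.Series:
    """Place a 1..n ranking into ordered terciles (low/middle/high); the
    label is monotone in rank."""
    r = pd.Series(ranks)
    _check_bijection(r)
    s1, s2, _ = tercile_sizes(len(r))
    labels = np.where(r <= s1, S.GROUP_LOW, np.where(r <= s1 + s2, S.GROUP_MIDDLE, S.GROUP_HIGH))
    return pd.Series(labels, index=r.index, dtype=object)


def cohens_kappa(labels_a, labels_b, categories: Sequence | None = None):
    """Cohen's kappa between two categorical labelings.

    Returns ``(kappa, p, df)`` where p comes from the large-sample normal
    test of kappa = 0 (Fleiss null standard error) and df is reported as
    n - 1, a presentation convention rather than a test parameter.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise RankValidationError("label vectors must have equal length")
    n = len(a)
    if n == 0:
        raise RankValidationError("empty labelings")
    cats = list(categories) if categories is not None else sorted(set(a) | set(b))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k), dtype=float)
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if abs(1.0 - pe) < 1e-12:
        return float("nan"), float("nan"), n - 1
    kappa = (po - pe) / (1.0 - pe)
    # Null (kappa=0) SE, Fleiss/Cohen large-sample form.
    se0_num = pe + pe**2 - float(np.sum(row * col * (row + col)))
    se0 = np.sqrt(max(se0_num, 0.0)) / ((1.0 - pe) * np.sqrt(n))
    if se0 == 0:
        pval = float("nan")
    else:
        z = kappa / se0
        pval = float(2.0 * stats.norm.sf(abs(z)))
    return float(kappa), pval, n - 1


def rank_difference_summary(ranks_a, ranks_b, top_k: int = 5):
    """Per-state absolute rank differences with headline counts.

    Returns ``(diffs, counts, top)``: a per-state series of |rank_a -
    rank_b|; counts at exactly 0, 1, 2 and at >= 5; and the ``top_k``
    largest differences as (state, diff) pairs, ties alphabetical.
    """
    a, b = _as_aligned_series(ranks_a, ranks_b)
    _check_bijection(a)
    _check_bijection(b)
    diffs = (a - b).abs().astype(int)
    counts = {
        "exact_match": int((diffs == 0).sum()),
        "diff_eq_1": int((diffs == 1).sum()),
        "diff_eq_2": int((diffs == 2).sum()),
        "diff_ge_5": int((diffs >= 5).sum()),
    }
    order = sorted(diffs.index, key=lambda st: (-diffs[st], str(st)))
    top = [(st, int(diffs[st])) for st in order[:top_k]]
    return diffs, counts, top


@dataclass
class ConcordanceReport:
    """Full agreement report between two rankings of the same states."""

    n_states: int
    rho: float
    rho_p_adjusted: float
    bonferroni_m: int
    kappa: float
    kappa_p: float
    kappa_df: int
    tercile_table: np.ndarray
    diffs: pd.Series
    counts: dict = field(default_factory=dict)
    top_diffs: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"n_states: {self.n_states}",
            f"spearman_rho: {self.rho:.4f}",
            f"spearman_p_adjusted: {self.rho_p_adjusted:.4f} (bonferroni_m={self.bonferroni_m})",
            f"kappa: {self.kappa:.4f} (df={self.kappa_df})",
            f"kappa_p: {self.kappa_p:.4f}",
        ]
        lines += [f"{k}: {v}" for k, v in self.counts.items()]
        lines.append("largest_rank_differences: " + ", ".join(f"{s} ({d})" for s, d in self.top_diffs))
        return "\n".join(lines)


def compare_rankings(ranks_a, ranks_b, m_comparisons: int = 1, top_k: int = 5) -> ConcordanceReport:
    """Build the full concordance report for two 1..n rankings of the same
    states (Spearman, tercile kappa, rank-difference summary)."""
    a, b = _as_aligned_series(ranks_a, ranks_b)
    _check_bijection(a)
    _check_bijection(b)
    rho, p_adj = spearman_with_bonferroni(a, b, m_comparisons=m_comparisons)
    ta = assign_terciles(a)
    tb = assign_terciles(b)
    kappa, kp, kdf = cohens_kappa(ta, tb, categories=S.GROUPS)
    k = len(S.GROUPS)
    idx = {c: i for i, c in enumerate(S.GROUPS)}
    table = np.zeros((k, k), dtype=int)
    for x, y in zip(ta, tb):
        table[idx[x], idx[y]] += 1
    diffs, counts, top = rank_difference_summary(a, b, top_k=top_k)
    return ConcordanceReport(
        n_states=len(a),
        rho=rho,
        rho_p_adjusted=p_adj,
        bonferroni_m=m_comparisons,
        kappa=kappa,
        kappa_p=kp,
        kappa_df=kdf,
        tercile_table=table,
        diffs=diffs,
        counts=counts,
        top_diffs=top,
    )
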