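"""Tie-aware rank statistics: Mann–Whitney (normal Z form), Kruskal–Wallis,
Jonckheere–Terpstra ordered-alternative trend test, and a Spearman
correlation matrix with significance tiers.

Conventions
-----------
* Ties receive mid-ranks, with the standard tie-corrected variances.
* Normal approximations use no continuity correction.
* All p-values are two-sided.
* Two-sample sign convention: positive Z means the FIRST sample tends
  larger.  For the trend test, positive Z means values increase along the
  stated group order.

The statistics are implemented directly (the Z forms, tie corrections and
degenerate-input behaviour needed here are pinned down explicitly);
scipy serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .core_data import ValidationError

__all__ = [
    "TestKind",
    "TestResult",
    "mann_whitney_u",
    "mann_whitney_z",
    "kruskal_wallis_h",
    "jt_count",
    "jonckheere_terpstra",
    "spearman_matrix",
    "SpearmanMatrix",
]


class TestKind(str, enum.Enum):
    MANN_WHITNEY = "mann_whitney"
    KRUSKAL_WALLIS = "kruskal_wallis"
    JONCKHEERE_TERPSTRA = "jonckheere_terpstra"
    SPEARMAN = "spearman"


@dataclass(frozen=True)
class TestResult:
    """Outcome of one rank test: the reported statistic (Z, H, Z_JT or r),
    a two-sided p-value, group sizes and whether ties were present."""

    test: TestKind
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    ties_present: bool


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: sample must be non-empty")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name}: sample contains non-finite values")
    return arr


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def mann_whitney_u(x, y) -> float:
    """The U statistic for the first sample: the number of (x, y) pairs with
    x > y, counting ties as one half (equivalently, via mid-ranks)."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_z(x, y) -> TestResult:
    """Two-sample Mann–Whitney test in its normal (Z) form.

    U counts pairs won by ``x`` (plus half-ties, via mid-ranks);
    Z = (U − n₁n₂/2)/σ with the tie-corrected σ and no continuity
    correction.  When the pooled sample is constant, σ = 0 and the
    degenerate result Z = 0, p = 1 is returned.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    ties = _tie_counts(pooled)
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    ties_present = bool((ties > 1).any())
    if var <= 0:
        return TestResult(TestKind.MANN_WHITNEY, 0.0, 1.0, (n1, n2), ties_present)
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(TestKind.MANN_WHITNEY, float(z), float(min(p, 1.0)), (n1, n2), ties_present)


def kruskal_wallis_h(groups: Sequence) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1).

    A fully constant pooled sample yields H = 0, p = 1 (no evidence of any
    location difference) rather than a 0/0 failure.
    """
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis_h requires at least 2 groups")
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    sizes = tuple(len(a) for a in arrays)
    n = sum(sizes)
    if n < 3:
        raise ValidationError("kruskal_wallis_h requires total n >= 3")
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    ties_present = bool((ties > 1).any())
    if correction <= 0:  # every observation identical
        return TestResult(TestKind.KRUSKAL_WALLIS, 0.0, 1.0, sizes, ties_present)
    h /= correction
    h = max(h, 0.0)
    p = sps.chi2.sf(h, df=len(groups) - 1)
    return TestResult(TestKind.KRUSKAL_WALLIS, float(h), float(p), sizes, ties_present)


def jt_count(groups: Sequence) -> float:
    """The Jonckheere–Terpstra count: over all between-group pairs taken in
    the stated order, the number of (earlier, later) pairs with the later
    value larger, plus half the tied pairs."""
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    jt = 0.0
    for a, b in itertools.combinations(arrays, 2):
        diff = b[None, :] - a[:, None]
        jt += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(jt)


def jonckheere_terpstra(groups: Sequence) -> TestResult:
    """Jonckheere–Terpstra test against the ordered alternative implied by
    the given group order.

    JT = Σ_{i<j} [#(gᵢ < gⱼ) + ½ #(gᵢ = gⱼ)] over all between-group pairs;
    Z = (JT − μ)/σ with μ = (N² − Σnᵢ²)/4 and the tie-corrected variance.
    Positive Z: values increase along the stated order.
    """
    if len(groups) < 2:
        raise ValidationError("jonckheere_terpstra requires at least 2 ordered groups")
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    sizes = np.array([len(a) for a in arrays], dtype=float)
    n = sizes.sum()
    jt = jt_count(arrays)
    mu = (n**2 - (sizes**2).sum()) / 4.0
    pooled = np.concatenate(arrays)
    t = _tie_counts(pooled).astype(float)
    ties_present = bool((t > 1).any())
    # Tie-corrected null variance (Hollander & Wolfe form).
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - (t * (t - 1) * (2 * t + 5)).sum()
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
    ) / 72.0
    term2 = 0.0
    term3 = 0.0
    if n > 2:
        term2 = (
            (t * (t - 1) * (t - 2)).sum()
            * (sizes * (sizes - 1) * (sizes - 2)).sum()
            / (36.0 * n * (n - 1) * (n - 2))
        )
    if n > 1:
        term3 = (t * (t - 1)).sum() * (sizes * (sizes - 1)).sum() / (8.0 * n * (n - 1))
    var = term1 + term2 + term3
    if var <= 0:
        return TestResult(
            TestKind.JONCKHEERE_TERPSTRA, 0.0, 1.0, tuple(int(s) for s in sizes), ties_present
        )
    z = (jt - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        TestKind.JONCKHEERE_TERPSTRA,
        float(z),
        float(min(p, 1.0)),
        tuple(int(s) for s in sizes),
        ties_present,
    )


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanMatrix:
    """Symmetric correlation matrix with per-pair p-values and star tiers
    ('**' for p < 0.01, '*' for p < 0.05, '' otherwise, 'na' where the
    correlation is undefined)."""

    r: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame
    n: pd.DataFrame

    def starred(self) -> pd.DataFrame:
        """Human-readable matrix: coefficient with significance stars."""
        out = self.r.copy().astype(object)
        for i in self.r.index:
            for j in self.r.columns:
                r = self.r.loc[i, j]
                t = self.tier.loc[i, j]
                out.loc[i, j] = "na" if t == "na" else f"{r:.3f}{t if t in ('*', '**') else ''}"
        return out


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return np.nan, np.nan, n  # undefined for a constant margin
    rx, ry = rankdata(xs), rankdata(ys)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0)), n


def spearman_matrix(variables: Mapping[str, Sequence[float]] | pd.DataFrame) -> SpearmanMatrix:
    """Pairwise-complete Spearman correlation matrix.

    r is the Pearson correlation of mid-ranks; p uses the t approximation
    with n − 2 degrees of freedom.  Pairs with fewer than 3 complete
    observations or a constant margin are reported as not available.
    """
    df = pd.DataFrame(variables).astype(float)
    if df.shape[1] < 2:
        raise ValidationError("spearman_matrix requires at least 2 variables")
    names = list(df.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(np.isfinite(df.iloc[:, i]).sum())
        for j in range(i + 1, k):
            rij, pij, nij = _spearman_pair(df.iloc[:, i].to_numpy(), df.iloc[:, j].to_numpy())
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    # a constant column also has no self-correlation
    for i in range(k):
        col = df.iloc[:, i].to_numpy()
        finite = col[np.isfinite(col)]
        if finite.size and np.all(finite == finite[0]):
            r[i, i] = np.nan
            p[i, i] = np.nan

    def frame(m):
        return pd.DataFrame(m, index=names, columns=names)

    tier = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(k):
            if not np.isfinite(r[i, j]):
                tier[i, j] = "na"
            elif i == j:
                tier[i, j] = ""
            elif p[i, j] < 0.01:
                tier[i, j] = "**"
            elif p[i, j] < 0.05:
                tier[i, j] = "*"
    return SpearmanMatrix(r=frame(r), p=frame(p), tier=frame(tier), n=frame(n))
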