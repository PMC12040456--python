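"""One-way MANOVA: SSCP decomposition and the four classical statistics.

For a grouping factor with g levels and p responses, the total
sum-of-squares-and-cross-products (SSCP) matrix about the grand mean
splits into a hypothesis part H (between groups, df_h = g - 1) and an
error part E (within groups, df_e = n - g).  All four test statistics —
Wilks' lambda, Pillai's trace, the Hotelling-Lawley trace and Roy's
greatest root — are functions of the eigenvalues of E^-1 H, computed
here from the symmetric generalized eigenproblem H v = lambda E v for
numerical stability.  F approximations: Rao's F for Wilks, the standard
trace approximations for Pillai and Hotelling-Lawley, and the upper-
bound F for Roy (so Roy's p-value is a lower bound, i.e. an upper bound
on significance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["SSCPPair", "StatisticResult", "ManovaResult", "sscp",
           "manova_tests", "manova_table"]

STATISTIC_NAMES = ("Wilks", "Pillai", "Hotelling-Lawley", "Roy")


@dataclass(frozen=True)
class SSCPPair:
    """Hypothesis and error SSCP matrices with their degrees of freedom."""

    H: np.ndarray
    E: np.ndarray
    df_h: int
    df_e: int
    responses: tuple[str, ...] = ()


@dataclass(frozen=True)
class StatisticResult:
    name: str
    value: float
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class ManovaResult:
    eigenvalues: np.ndarray  # descending, all >= 0
    statistics: tuple[StatisticResult, ...]

    def __getitem__(self, name: str) -> StatisticResult:
        for s in self.statistics:
            if s.name == name:
                return s
        raise KeyError(name)


def sscp(table: pd.DataFrame, responses, grouping: str) -> SSCPPair:
    """Decompose the total SSCP of ``responses`` by the ``grouping`` column.

    Requires at least two groups and two observations per group.  H + E
    equals the total SSCP about the grand mean by construction.
    """
    responses = tuple(responses)
    Y = table[list(responses)].to_numpy(dtype=float)
    groups = table[grouping].to_numpy()
    labels, counts = np.unique(groups, return_counts=True)
    g, n, p = len(labels), len(Y), Y.shape[1]
    if g < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")

    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in labels:
        Yg = Y[groups == lab]
        d = Yg.mean(axis=0) - grand
        H += len(Yg) * np.outer(d, d)
        R = Yg - Yg.mean(axis=0)
        E += R.T @ R
    H = (H + H.T) / 2.0
    E = (E + E.T) / 2.0
    return SSCPPair(H, E, df_h=g - 1, df_e=n - g, responses=responses)


def _eigenvalues(pair: SSCPPair) -> np.ndarray:
    try:
        linalg.cholesky(pair.E)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "error SSCP matrix is singular; MANOVA statistics are undefined "
            "(more responses than error degrees of freedom, or linearly "
            "dependent responses)"
        ) from exc
    lam = linalg.eigh(pair.H, pair.E, eigvals_only=True)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite eigenvalues in MANOVA eigenproblem")
    lam = np.clip(lam, 0.0, None)  # roundoff can leave tiny negatives
    return np.sort(lam)[::-1]


def manova_tests(pair: SSCPPair) -> ManovaResult:
    """The four multivariate statistics with F approximations and p-values."""
    lam = _eigenvalues(pair)
    p = pair.H.shape[0]
    q = pair.df_h
    v = pair.df_e
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (v - p - 1) / 2.0

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    pillai = float(np.sum(lam / (1.0 + lam)))
    hotelling = float(np.sum(lam))
    roy = float(lam[0]) if lam.size else 0.0

    results = []

    # Wilks: Rao's F approximation (exact for p <= 2 or q <= 2)
    if p**2 + q**2 - 5 > 0:
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        t = 1.0
    w = v + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    F = ((1.0 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
    results.append(StatisticResult("Wilks", wilks, float(F), df1, float(df2),
                                   float(stats.f.sf(F, df1, df2))))

    # Pillai's trace
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * (pillai / (s - pillai)) if s > pillai else np.inf
    results.append(StatisticResult("Pillai", pillai, float(F), float(df1),
                                   float(df2), float(stats.f.sf(F, df1, df2))))

    # Hotelling-Lawley trace (classical approximation)
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * nn + 1)
    F = hotelling * df2 / (s * df1) if df1 > 0 else np.nan
    results.append(StatisticResult("Hotelling-Lawley", hotelling, float(F),
                                   float(df1), float(df2),
                                   float(stats.f.sf(F, df1, df2))))

    # Roy's greatest root: upper-bound F
    r = max(p, q)
    df1 = r
    df2 = v - r + q
    F = roy * df2 / df1
    results.append(StatisticResult("Roy", roy, float(F), float(df1),
                                   float(df2), float(stats.f.sf(F, df1, df2))))

    return ManovaResult(lam, tuple(results))


def manova_table(table: pd.DataFrame, responses, grouping: str,
                 by: str | None = None) -> pd.DataFrame:
    """Tidy MANOVA results, optionally per level of ``by`` plus pooled.

    For the screening analysis the grouping variable is the treatment-
    series label (``varied_factor``) and ``by`` is the genus; a 'pooled'
    block covers all genera together.
    """
    blocks = []

    def one(sub: pd.DataFrame, label: str):
        res = manova_tests(sscp(sub, responses, grouping))
        for st in res.statistics:
            blocks.append({"genus": label, "statistic": st.name,
                           "value": st.value, "F": st.F, "df1": st.df1,
                           "df2": st.df2, "p": st.p})

    if by is not None:
        for label in sorted(table[by].unique()):
            one(table[table[by] == label], label)
    one(table, "pooled")
    return pd.DataFrame(blocks, columns=["genus", "statistic", "value", "F",
                                         "df1", "df2", "p"])
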