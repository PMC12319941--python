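"""Group-level inference for repeated-measures ROI data.

Paired t-tests (one- and two-tailed), fully within-subject two-way
repeated-measures ANOVA with Greenhouse-Geisser sphericity correction,
post hoc 2x2 interaction contrasts, and exact noncentral-t power for the
paired design.

All routines operate on balanced within-subject tables: every subject
contributes one value per cell. Subjects with missing cells (e.g., a
missing ROI) must be dropped by the caller before the ANOVA; the
functions raise rather than silently impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "EffectResult",
    "RmAnovaResult",
    "paired_t",
    "gg_epsilon",
    "rm_anova_2way",
    "interaction_contrast_2x2",
    "power_paired_t",
]


@dataclass(frozen=True)
class TTestResult:
    """Result of a paired (or one-sample) t-test."""

    t: float
    df: int
    p: float
    tails: int
    direction: str = "greater"  # predicted side for one-tailed tests

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class EffectResult:
    """One effect from a repeated-measures ANOVA."""

    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    eps_gg: float
    df_num_gg: float
    df_den_gg: float
    p_gg: float
    ss_effect: float
    ss_error: float


@dataclass
class RmAnovaResult:
    """Effects table of a within-subject ANOVA (uncorrected and GG-corrected)."""

    effects: dict[str, EffectResult] = field(default_factory=dict)
    n_subjects: int = 0

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.name,
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "eps_gg": e.eps_gg,
                "df_num_gg": e.df_num_gg,
                "df_den_gg": e.df_den_gg,
                "p_gg": e.p_gg,
            }
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows)


def paired_t(
    x,
    y=None,
    tails: int = 2,
    direction: str = "greater",
) -> TTestResult:
    """Classical paired-samples t-test.

    Parameters
    ----------
    x, y : array-like
        Paired observations. If ``y`` is omitted, ``x`` is treated as the
        vector of paired differences and tested against zero.
    tails : {1, 2}
        Two-tailed by default. One-tailed halves the two-tailed p on the
        predicted side.
    direction : {"greater", "less"}
        Predicted sign of ``mean(x - y)`` for one-tailed tests.
    """
    x = np.asarray(x, dtype=float)
    if y is not None and len(x) != len(np.asarray(y)):
        raise ValueError("paired samples must have equal length")
    d = x if y is None else x - np.asarray(y, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() != 0:
            raise ValueError("zero variance of paired differences; t undefined")
        # identical pairs: no evidence either way
        t = 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if tails == 2:
        p = 2.0 * sps.t.sf(abs(t), df)
    elif direction == "greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return TTestResult(t=float(t), df=df, p=float(p), tails=tails, direction=direction)


def gg_epsilon(cov: np.ndarray, k: int | None = None) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject covariance.

    epsilon = tr(CSC)^2 / ((k-1) * tr((CSC)^2)) with C the centering
    matrix; equals 1 under sphericity (e.g., compound symmetry) and is
    bounded below by 1/(k-1). Two-level factors are trivially spherical.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if k is None:
        k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if k == 2:
        return 1.0
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    A = C @ S @ C
    denom = (k - 1) * np.sum(A * A)
    if denom <= 0:
        return 1.0
    return float(min(1.0, np.trace(A) ** 2 / denom))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the space orthogonal to the mean."""
    # Helmert contrasts, normalized.
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


def _epsilon_from_projection(Y: np.ndarray, M: np.ndarray) -> float:
    """GG epsilon for the effect subspace spanned by contrast matrix M.

    Y is subjects x cells; M has one orthonormal column per effect df.
    """
    q = M.shape[1]
    if q == 1:
        return 1.0
    Z = Y @ M
    S = np.cov(Z, rowvar=False)
    denom = q * np.sum(S * S)
    if denom <= 0:
        return 1.0
    return float(min(1.0, np.trace(S) ** 2 / denom))


def _as_cell_array(data, subject=None, factors=None, value=None) -> np.ndarray:
    """Coerce input to a (subjects, a, b) array.

    Accepts a 3-d array directly, or a long DataFrame with column names
    given by ``subject``, ``factors=(A, B)`` and ``value``.
    """
    if isinstance(data, pd.DataFrame):
        if subject is None or factors is None or value is None:
            raise ValueError(
                "DataFrame input requires subject=, factors=(A, B) and value= column names"
            )
        a_name, b_name = factors
        wide = data.pivot_table(
            index=subject, columns=[a_name, b_name], values=value, aggfunc="mean"
        )
        if wide.isna().any().any():
            raise ValueError(
                "missing cells in the within-subject table; drop incomplete subjects first"
            )
        a_levels = wide.columns.get_level_values(0).unique()
        b_levels = wide.columns.get_level_values(1).unique()
        arr = np.empty((wide.shape[0], len(a_levels), len(b_levels)))
        for i, al in enumerate(a_levels):
            for j, bl in enumerate(b_levels):
                arr[:, i, j] = wide[(al, bl)].to_numpy()
        return arr
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (subjects, factorA, factorB) array")
    if np.isnan(arr).any():
        raise ValueError(
            "missing cells in the within-subject table; drop incomplete subjects first"
        )
    return arr


def rm_anova_2way(
    data,
    subject: str | None = None,
    factors: tuple[str, str] | None = None,
    value: str | None = None,
    effect_names: tuple[str, str, str] | None = None,
) -> RmAnovaResult:
    """Two-way fully within-subject repeated-measures ANOVA.

    Parameters
    ----------
    data : ndarray (subjects, a, b) or long DataFrame
        Balanced within-subject table; every subject contributes one value
        per (A, B) cell.
    effect_names : optional
        Labels for (A, B, interaction); defaults to ("A", "B", "A:B").

    Returns
    -------
    RmAnovaResult
        Main effects and interaction, each with uncorrected F/df/p and
        Greenhouse-Geisser epsilon, corrected df and corrected p. Epsilon
        is computed per effect from the covariance of the data projected
        onto that effect's orthonormal contrast subspace.
    """
    y = _as_cell_array(data, subject=subject, factors=factors, value=value)
    n, a, b = y.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    names = effect_names or ("A", "B", "A:B")

    g = y.mean()
    m_s = y.mean(axis=(1, 2))  # per subject
    m_a = y.mean(axis=(0, 2))  # per A level
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - g
    )
    ss_abs = np.sum(resid**2)

    Y = y.reshape(n, a * b)  # cells ordered (A-major, B-minor)
    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    one_a = np.full((a, 1), 1.0 / np.sqrt(a))
    one_b = np.full((b, 1), 1.0 / np.sqrt(b))
    M_a = np.kron(Ca, one_b)
    M_b = np.kron(one_a, Cb)
    M_ab = np.kron(Ca, Cb)

    specs = [
        (names[0], ss_a, (a - 1), ss_as, (a - 1) * (n - 1), M_a),
        (names[1], ss_b, (b - 1), ss_bs, (b - 1) * (n - 1), M_b),
        (names[2], ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), M_ab),
    ]
    result = RmAnovaResult(n_subjects=n)
    # SS below float rounding of the total are treated as exactly zero so
    # that degenerate (noiseless) tables give F = 0 rather than 0/0 noise
    tiny = 1e-12 * max(float(np.sum((y - g) ** 2)), np.finfo(float).tiny)
    for name, ss_eff, df_eff, ss_err, df_err, M in specs:
        if ss_eff <= tiny:
            F = 0.0
        elif ss_err <= tiny:
            F = np.inf
        else:
            F = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        eps = _epsilon_from_projection(Y, M)
        df1g, df2g = eps * df_eff, eps * df_err
        p_gg = float(sps.f.sf(F, df1g, df2g)) if np.isfinite(F) else 0.0
        result.effects[name] = EffectResult(
            name=name,
            F=float(F),
            df_num=float(df_eff),
            df_den=float(df_err),
            p=p,
            eps_gg=eps,
            df_num_gg=float(df1g),
            df_den_gg=float(df2g),
            p_gg=p_gg,
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )
    return result


def interaction_contrast_2x2(data, **kwargs) -> EffectResult:
    """Post hoc 2x2 interaction contrast.

    Restricts to a 2x2 within-subject table and returns the interaction
    effect; equivalent to a paired t-test on the per-subject double
    difference, with F = t^2.
    """
    y = _as_cell_array(data, **kwargs)
    if y.shape[1] != 2 or y.shape[2] != 2:
        raise ValueError("interaction contrast requires a 2x2 table")
    res = rm_anova_2way(y, effect_names=("A", "B", "A:B"))
    return res["A:B"]


def power_paired_t(
    n: int, d: float, alpha: float = 0.05, tails: int = 2
) -> float:
    """Exact power of the paired t-test via the noncentral t distribution.

    Noncentrality d*sqrt(n) on n-1 degrees of freedom, where d is the
    standardized mean paired difference (Cohen's d_z).
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if d < 0:
        raise ValueError("effect size d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        lower = sps.nct.cdf(-tc, df, nc)
        if not np.isfinite(lower):
            lower = 0.0  # numerically negligible far tail at large nc
        return float(min(1.0, sps.nct.sf(tc, df, nc) + lower))
    tc = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))
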