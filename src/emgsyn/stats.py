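"""Statistical comparisons across fatigue epochs.

One-way repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse-Geisser correction, Bonferroni-corrected paired t-tests between
epochs, Pearson correlations between fatigue metrics, and the paired t-test
of within-cluster similarity against the shuffled null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "RmAnovaResult",
    "rm_anova",
    "bonferroni_paired_t",
    "pearson_r",
    "paired_t_vs_null",
]


@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA with sphericity handling.

    ``df_num``/``df_den`` are the (possibly Greenhouse-Geisser corrected)
    degrees of freedom actually used for ``p_value``; ``corrected`` records
    whether the correction was applied (Mauchly p < 0.05).
    """

    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    corrected: bool
    omega_squared: float

    def summary(self) -> str:
        tag = "GG-corrected" if self.corrected else "sphericity assumed"
        return (
            f"F({self.df_num:.2f}, {self.df_den:.2f}) = {self.f_stat:.3f}, "
            f"p = {self.p_value:.4f} ({tag}); "
            f"Mauchly W = {self.mauchly_w:.3f} (p = {self.mauchly_p:.4f}), "
            f"GG epsilon = {self.gg_epsilon:.3f}, "
            f"omega^2 = {self.omega_squared:.4f}"
        )


def _contrast_covariance(data: np.ndarray) -> np.ndarray:
    """Covariance of the data projected on orthonormal within-subject contrasts."""
    n, p = data.shape
    # orthonormal basis of the (p-1)-dim space orthogonal to the unit vector
    M = np.linalg.qr(np.eye(p) - 1.0 / p)[0][:, : p - 1]
    Y = data @ M
    return np.cov(Y, rowvar=False)


def rm_anova(data: np.ndarray, alpha: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    Computes the within-subject F test, Mauchly's test of sphericity (on the
    orthonormal contrast covariance), the Greenhouse-Geisser epsilon, and a
    within-subjects omega-squared effect size.  When Mauchly's p < ``alpha``
    both degrees of freedom are multiplied by epsilon.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects x levels matrix")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing or non-finite cells are not supported")
    n, p = data.shape
    if n < 3 or p < 3:
        raise ValueError("need at least 3 subjects and 3 levels")

    grand = data.mean()
    ss_total = np.sum((data - grand) ** 2)
    ss_subj = p * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_treat = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_treat
    df_t, df_e = p - 1, (n - 1) * (p - 1)
    ms_t, ms_e = ss_treat / df_t, ss_err / df_e
    ms_subj = ss_subj / (n - 1)

    S = _contrast_covariance(data)
    eigvals = np.linalg.eigvalsh(S)
    eigvals = np.clip(eigvals, 0.0, None)
    tr = eigvals.sum()
    # Greenhouse-Geisser epsilon from the contrast covariance spectrum
    gg = float(tr**2 / ((p - 1) * np.sum(eigvals**2))) if tr > 0 else 1.0

    # Mauchly's W and its chi-square approximation
    det = float(np.prod(eigvals))
    if det <= 0 or tr <= 0:
        mauchly_w, mauchly_p = np.nan, np.nan
    else:
        mauchly_w = det / (tr / (p - 1)) ** (p - 1)
        dof = p * (p - 1) // 2 - 1
        f_corr = 1.0 - (2 * (p - 1) ** 2 + (p - 1) + 2) / (6.0 * (p - 1) * (n - 1))
        chi2 = -(n - 1) * f_corr * np.log(mauchly_w)
        mauchly_p = float(sst.chi2.sf(chi2, dof))

    corrected = bool(np.isfinite(mauchly_p) and mauchly_p < alpha)
    eps = gg if corrected else 1.0
    df_num, df_den = df_t * eps, df_e * eps

    if ss_treat <= 1e-300 * max(ss_total, 1.0):
        f_stat, p_value = 0.0, 1.0
    elif ms_e <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ms_t / ms_e
        p_value = float(sst.f.sf(f_stat, df_num, df_den))

    omega = (ss_treat - df_t * ms_e) / (ss_total + ms_subj) if ss_total + ms_subj > 0 else 0.0
    return RmAnovaResult(
        f_stat=float(f_stat), df_num=float(df_num), df_den=float(df_den),
        p_value=float(p_value), mauchly_w=float(mauchly_w),
        mauchly_p=float(mauchly_p), gg_epsilon=float(gg),
        corrected=corrected, omega_squared=float(omega),
    )


def bonferroni_paired_t(
    data: np.ndarray, pairs: list[tuple[int, int]]
) -> pd.DataFrame:
    """Paired t-tests between level pairs with Bonferroni adjustment.

    ``data`` is subjects x levels; each (i, j) in ``pairs`` compares level i
    against level j.  Raw p-values are multiplied by the number of
    comparisons and capped at 1.
    """
    data = np.asarray(data, dtype=float)
    m = len(pairs)
    rows = []
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        if len(d) < 3:
            raise ValueError("each pair needs at least 3 paired observations")
        if np.std(d, ddof=1) == 0:
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                raise ValueError(f"zero-variance non-zero differences for pair {(i, j)}")
        else:
            t, p = sst.ttest_rel(data[:, i], data[:, j])
        rows.append(
            {
                "level_a": i, "level_b": j, "t": float(t),
                "df": len(d) - 1, "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = sst.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def paired_t_vs_null(
    within_similarities: np.ndarray, null_similarities: np.ndarray
) -> tuple[float, float, float]:
    """Paired t-test of within-cluster similarity against shuffled-null similarity.

    Samples are paired by resample index.  Returns (t, p, eta-squared) with
    eta^2 = t^2 / (t^2 + df).
    """
    w = np.asarray(within_similarities, dtype=float)
    s = np.asarray(null_similarities, dtype=float)
    if w.shape != s.shape:
        raise ValueError("paired samples must have equal length")
    d = w - s
    if len(d) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero-variance non-zero differences: paired t undefined")
    t, p = sst.ttest_rel(w, s)
    df = len(d) - 1
    eta2 = float(t**2 / (t**2 + df))
    return float(t), float(p), eta2
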