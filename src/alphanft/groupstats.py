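"""Trainability and independence statistics.

Trainability: one-way within-subject (repeated-measures) ANOVA of MRAA (or
baseline alpha amplitude) across the 12 sessions, with Bonferroni-corrected
paired post-hoc comparisons of each session against session 1.

Independence: per-frequency-bin paired comparison of the first- vs
last-session amplitude spectra (Bonferroni over bins), plus a two-way
within-subject session x frequency ANOVA; training counts as independent when
the significant bins are confined to the trained 8-12 Hz range.

No sphericity correction is applied by default (a Greenhouse-Geisser flag is
available): the reported integer degrees of freedom follow the classical
(k-1), (k-1)(n-1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANOVAResult",
    "rm_anova_oneway",
    "posthoc_vs_first",
    "spectra_session_comparison",
]


@dataclass
class ANOVAResult:
    F: float
    df1: float
    df2: float
    p: float
    effect: str = "session"

    def __str__(self) -> str:
        return (f"{self.effect}: F({self.df1:g},{self.df2:g}) = "
                f"{self.F:.2f}, p = {self.p:.4g}")


def _check_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not allowed (no imputation)")
    return data


def rm_anova_oneway(data, gg_correction: bool = False) -> ANOVAResult:
    """Classical one-way repeated-measures ANOVA.

    ``data`` is subjects x conditions.  The subject effect is removed from the
    error term: F = MS_condition / MS_error with df1 = k-1 and
    df2 = (k-1)(n-1).  With ``gg_correction`` both dfs are multiplied by the
    Greenhouse-Geisser epsilon before the p-value is computed.
    """
    data = _check_matrix(data)
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else np.inf
    if gg_correction:
        eps = _gg_epsilon(data)
        p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    else:
        p = float(stats.f.sf(F, df1, df2))
    return ANOVAResult(float(F), df1, df2, p)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    mean_diag = np.trace(S) / k
    num = (k * mean_diag - S.mean()) ** 2 * k ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k ** 2 * S.mean() ** 2)
    return float(num / (den * k ** 2)) if den > 0 else 1.0


def posthoc_vs_first(data, labels=None) -> pd.DataFrame:
    """Paired t-tests of each condition against the first, Bonferroni x (k-1).

    Returns a table with one row per comparison: condition, mean difference,
    raw p, corrected p, significance flag (alpha = 0.05 two-tailed).
    """
    data = _check_matrix(data)
    n, k = data.shape
    labels = list(labels) if labels is not None else list(range(1, k + 1))
    rows = []
    for j in range(1, k):
        diff = data[:, j] - data[:, 0]
        if np.allclose(diff.std(), 0.0):
            warnings.warn(f"zero-variance difference for condition {labels[j]};"
                          " p set to 1", stacklevel=2)
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(data[:, j], data[:, 0])
        p_corr = min(1.0, float(p) * (k - 1))
        rows.append({
            "condition": labels[j],
            "mean_difference": float(diff.mean()),
            "p_raw": float(p),
            "p_corrected": p_corr,
            "significant": p_corr < 0.05,
        })
    return pd.DataFrame(rows)


def _rm_anova_twoway(first: np.ndarray, last: np.ndarray,
                     pooled_error: bool = False) -> dict[str, ANOVAResult]:
    """Two-way fully within-subject ANOVA (session x frequency).

    Default error terms are per-effect (each effect tested against its
    subject x effect interaction); ``pooled_error`` instead tests every
    effect against the highest-order residual stratum
    (subject x session x frequency, df = (n-1)(b-1)), an alternative
    convention some packages report — for 46 subjects and 28 bins its
    error df is 45 x 27 = 1215.
    """
    n, b = first.shape
    Y = np.stack([first, last], axis=1)          # (n, 2, b)
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))                   # (n,)
    sess = Y.mean(axis=(0, 2))                   # (2,)
    freq = Y.mean(axis=(0, 1))                   # (b,)
    cell_sf = Y.mean(axis=0)                     # (2, b)
    subj_sess = Y.mean(axis=2)                   # (n, 2)
    subj_freq = Y.mean(axis=1)                   # (n, b)

    ss_sess = n * b * np.sum((sess - grand) ** 2)
    ss_freq = n * 2 * np.sum((freq - grand) ** 2)
    ss_inter = n * np.sum(
        (cell_sf - sess[:, None] - freq[None, :] + grand) ** 2)
    ss_subj = 2 * b * np.sum((subj - grand) ** 2)
    ss_es = b * np.sum(
        (subj_sess - subj[:, None] - sess[None, :] + grand) ** 2)
    ss_ef = 2 * np.sum(
        (subj_freq - subj[:, None] - freq[None, :] + grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_ei = ss_tot - (ss_sess + ss_freq + ss_inter + ss_subj + ss_es + ss_ef)

    df_sess, df_freq = 1, b - 1
    df_inter = df_sess * df_freq
    df_es = (n - 1) * df_sess
    df_ef = (n - 1) * df_freq
    df_ei = (n - 1) * df_inter

    tiny = 1e-12 * max(ss_tot, 1.0)  # numerically-zero sums of squares

    def _res(name, ss, df, ss_err, df_err):
        ms = 0.0 if ss < tiny else ss / df
        ms_e = 0.0 if ss_err < tiny else ss_err / df_err
        if ms_e > 0:
            F = ms / ms_e
        else:
            F = np.inf if ms > 0 else 0.0  # 0/0: no effect, no error variance
        return ANOVAResult(float(F), df, df_err,
                           float(stats.f.sf(F, df, df_err)), effect=name)

    if pooled_error:
        return {
            "session": _res("session", ss_sess, df_sess, ss_ei, df_ei),
            "frequency": _res("frequency", ss_freq, df_freq, ss_ei, df_ei),
            "interaction": _res("interaction", ss_inter, df_inter,
                                ss_ei, df_ei),
        }
    return {
        "session": _res("session", ss_sess, df_sess, ss_es, df_es),
        "frequency": _res("frequency", ss_freq, df_freq, ss_ef, df_ef),
        "interaction": _res("interaction", ss_inter, df_inter, ss_ei, df_ei),
    }


def spectra_session_comparison(
    spectra_first,
    spectra_last,
    bin_centers_hz=None,
    trained_band: tuple[int, int] = (8, 12),
    pooled_error: bool = False,
) -> dict:
    """Compare first- vs last-session amplitude spectra across subjects.

    Parameters
    ----------
    spectra_first, spectra_last
        Subjects x frequency-bin matrices of mean amplitudes (same shapes).
    bin_centers_hz
        Frequency of each column; defaults to 1..n_bins Hz.
    trained_band
        Inclusive Hz range whose exclusivity defines "independence".

    Returns a dict with ``posthoc`` (per-bin paired t table, Bonferroni over
    bins), ``anova`` (two-way within-subject session/frequency/interaction),
    ``significant_bins`` and the boolean ``independent`` verdict (all
    significant bins inside the trained band).
    """
    first = _check_matrix(spectra_first)
    last = _check_matrix(spectra_last)
    if first.shape != last.shape:
        raise ValueError("first/last spectra matrices must have equal shapes")
    n, b = first.shape
    bins = (np.asarray(bin_centers_hz) if bin_centers_hz is not None
            else np.arange(1, b + 1))
    rows = []
    for j in range(b):
        diff = last[:, j] - first[:, j]
        if np.allclose(diff.std(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(last[:, j], first[:, j])
        p_corr = min(1.0, float(p) * b)
        rows.append({
            "bin_hz": float(bins[j]),
            "mean_difference": float(diff.mean()),
            "p_raw": float(p),
            "p_corrected": p_corr,
            "significant": p_corr < 0.05,
        })
    posthoc = pd.DataFrame(rows)
    sig = posthoc.loc[posthoc["significant"], "bin_hz"].to_numpy()
    lo, hi = trained_band
    independent = bool(np.all((sig >= lo) & (sig <= hi))) if sig.size else True
    return {
        "posthoc": posthoc,
        "anova": _rm_anova_twoway(first, last, pooled_error=pooled_error),
        "significant_bins": sig,
        "independent": independent,
    }
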