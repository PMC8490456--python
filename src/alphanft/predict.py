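"""Resting-alpha responder prediction: correlations, regression, stepwise LDA, LOOCV.

The predictor relates the four eyes-closed resting-state (ECRS) band
amplitudes (delta, theta, alpha, beta) to responder labels derived from a
learning index.  Features are screened by forward-stepwise selection under
the Wilks-lambda partial-F criterion; the retained features enter a Fisher
linear discriminant

    D = a0 + sum_i a_i X_i

oriented so that responders score D < 0, with the decision boundary at D = 0
under the chosen priors.  Generalisation is assessed by leave-one-out
cross-validation and summarised as sensitivity, specificity and accuracy.

The user-facing surface is the model/results pair :class:`ResponderLDA` /
:class:`ResponderLDAResults`; the underlying operations are module functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral import BAND_ORDER

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "DiscriminantModel",
    "ConfusionCounts",
    "ValidationMetrics",
    "correlation_table",
    "simple_linear_regression",
    "fit_lda",
    "stepwise_select",
    "discriminant_score",
    "loocv_validate",
    "classification_metrics",
    "ResponderLDA",
    "ResponderLDAResults",
]


# ---------------------------------------------------------------------------
# correlation / regression screening
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    band: str
    index: str
    r: float
    p: float
    q: float  # Benjamini-Hochberg adjusted


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


def correlation_table(ecrs_wide: pd.DataFrame,
                      indices: pd.DataFrame,
                      index_names=("L1", "L2", "L3")) -> pd.DataFrame:
    """Pearson correlations of each ECRS band with each learning index.

    ``ecrs_wide``: subjects x band columns; ``indices``: subjects x index
    columns, aligned on the index.  The 4 x 3 = 12 correlations form one
    Benjamini-Hochberg FDR family.  Zero-variance variables yield undefined r
    and are flagged and excluded from the FDR family.
    """
    if len(ecrs_wide) < 3:
        raise ValueError("at least 3 subjects required")
    ecrs_wide, indices = ecrs_wide.align(indices, join="inner", axis=0)
    rows = []
    for band in [b for b in BAND_ORDER if b in ecrs_wide.columns]:
        for name in index_names:
            x = ecrs_wide[band].to_numpy(float)
            y = indices[name].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero variance for {band}/{name}; r undefined",
                              stacklevel=2)
                rows.append({"band": band, "index": name,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"band": band, "index": name,
                         "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"],
                                           method="fdr_bh")[1]
    table["significant"] = table["q"] < 0.05
    return table


def simple_linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of a learning index on one ECRS amplitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("at least 3 pairs required")
    if np.std(x) == 0:
        raise ValueError("predictor is constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# linear discriminant machinery
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Fitted linear discriminant D = a0 + sum a_i X_i (responder <=> D < 0)."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    priors: str = "equal"

    def score(self, x) -> float | np.ndarray:
        return discriminant_score(self, x)

    def predict_responder(self, x) -> bool | np.ndarray:
        return np.asarray(self.score(x)) < 0


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ValidationMetrics:
    """Percent metrics; an undefined denominator yields NaN (not zero)."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float

    def rounded(self) -> "ValidationMetrics":
        r = lambda v: float(np.round(v, 1)) if np.isfinite(v) else v
        return ValidationMetrics(r(self.sensitivity_pct),
                                 r(self.specificity_pct),
                                 r(self.accuracy_pct))


def _split(features: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels, dtype=bool)
    pos, neg = features[labels], features[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects in each class")
    return pos, neg, labels


def fit_lda(features, labels, priors: str = "equal",
            feature_names=None) -> DiscriminantModel:
    """Fisher LDA with pooled within-class covariance.

    The direction is oriented so responders (label True) have mean training
    score below nonresponders; the boundary sits at D = 0 — at the class
    midpoint under equal priors, shifted by ln(pi_N / pi_R) under
    proportional priors (which matters for imbalanced cohorts).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    pos, neg, labels = _split(X, labels)
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    n_p, n_n = len(pos), len(neg)
    sp = np.cov(pos, rowvar=False, ddof=1) if n_p > 1 else 0.0
    sn = np.cov(neg, rowvar=False, ddof=1) if n_n > 1 else 0.0
    S = ((n_p - 1) * np.atleast_2d(sp) + (n_n - 1) * np.atleast_2d(sn)) \
        / (n_p + n_n - 2)
    if np.linalg.cond(S) > 1e10:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular for features "
            f"{tuple(feature_names)}")
    w = np.linalg.solve(S, mu_p - mu_n)   # responders score higher under w
    if priors == "equal":
        shift = 0.0
    elif priors == "proportional":
        shift = np.log(n_n / n_p)
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    # responder <=> w.x - w.(mu_p+mu_n)/2 > shift  <=>  D < 0 with:
    coef = -w
    intercept = float(w @ (mu_p + mu_n) / 2.0 + shift)
    return DiscriminantModel(tuple(feature_names), coef, intercept,
                             priors=priors)


def discriminant_score(model: DiscriminantModel, x) -> float | np.ndarray:
    """Evaluate D = a0 + sum a_i x_i; accepts a vector or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1 and x.shape[0] != len(model.coefficients):
        raise ValueError("feature vector length mismatch")
    if x.ndim == 2 and x.shape[1] != len(model.coefficients):
        raise ValueError("feature matrix width mismatch")
    d = x @ model.coefficients + model.intercept
    return float(d) if np.ndim(d) == 0 else d


# ---------------------------------------------------------------------------
# stepwise Wilks-lambda selection
# ---------------------------------------------------------------------------

def _wilks_lambda(X: np.ndarray, labels: np.ndarray, cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) over the given feature columns."""
    if not cols:
        return 1.0
    sub = X[:, cols]
    grand = sub.mean(axis=0)
    T = (sub - grand).T @ (sub - grand)
    W = np.zeros_like(T)
    for cls in (True, False):
        grp = sub[labels == cls]
        cen = grp - grp.mean(axis=0)
        W += cen.T @ cen
    detT = np.linalg.det(T)
    if detT <= 0:
        return np.nan
    return float(np.linalg.det(W) / detT)


def _partial_f_p(lam_small: float, lam_big: float, n: int, p_after: int):
    """Partial F (and p) for the feature whose addition changes the model
    from ``lam_small`` (p_after-1 features) to ``lam_big`` (p_after features),
    two groups: F = (n - 2 - (p_after-1)) * (lam_small/lam_big - 1),
    df = (1, n - 1 - p_after)."""
    df2 = n - 1 - p_after
    if df2 <= 0 or not np.isfinite(lam_big) or lam_big <= 0:
        return np.nan, np.nan
    F = df2 * (lam_small / lam_big - 1.0)
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, 1, df2))


def stepwise_select(features, labels, enter_p: float = 0.05,
                    remove_p: float = 0.10,
                    feature_names=None) -> list[str]:
    """Forward-stepwise feature selection by Wilks-lambda partial F.

    At each step the candidate with the smallest partial-F p-value enters if
    it is below ``enter_p`` (ties broken by the canonical band order, i.e.
    column order); after every entry, any included feature whose removal
    p-value exceeds ``remove_p`` is dropped (worst first).  Iterates to a
    fixed point.  An empty selection is returned (not an error) when no
    feature passes entry.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)
    n = X.shape[0]
    if min(labels.sum(), (~labels).sum()) < 2:
        raise ValueError("need at least 2 subjects in each class")
    included: list[int] = []
    for _ in range(4 * X.shape[1]):  # fixed-point iteration cap
        changed = False
        lam_cur = _wilks_lambda(X, labels, included)
        # entry step: smallest p first, first-column tie-break via argmin
        best_j, best_p = None, np.inf
        for j in range(X.shape[1]):
            if j in included:
                continue
            lam_new = _wilks_lambda(X, labels, included + [j])
            _, p = _partial_f_p(lam_cur, lam_new, n, len(included) + 1)
            if np.isfinite(p) and p < best_p - 1e-15:
                best_j, best_p = j, p
        if best_j is not None and best_p < enter_p:
            included.append(best_j)
            changed = True
        # removal step: drop worst feature while its p exceeds remove_p
        while len(included) > 0:
            lam_full = _wilks_lambda(X, labels, included)
            worst_j, worst_p = None, -np.inf
            for j in included:
                rest = [c for c in included if c != j]
                lam_rest = _wilks_lambda(X, labels, rest)
                _, p = _partial_f_p(lam_rest, lam_full, n, len(included))
                if np.isfinite(p) and p > worst_p:
                    worst_j, worst_p = j, p
            if worst_j is not None and worst_p > remove_p:
                included.remove(worst_j)
                changed = True
            else:
                break
        if not changed:
            break
    return [feature_names[j] for j in sorted(included)]


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loocv_validate(features: pd.DataFrame, labels,
                   selection_policy: str = "fixed_features",
                   priors: str = "equal",
                   enter_p: float = 0.05, remove_p: float = 0.10,
                   fixed_feature_names=None,
                   ) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Leave-one-out validation of the (stepwise-)LDA responder predictor.

    ``fixed_features`` (default): the feature set is selected once on the full
    data (or supplied via ``fixed_feature_names``) and only the LDA
    coefficients are refit per fold — the validation the study design
    prescribes.  ``nested_stepwise`` reselects features inside every fold
    (honest validation of the whole procedure).

    The held-out subject is classified responder iff its discriminant score
    is negative.  A fold whose training set loses one class entirely falls
    back to the training majority class and is flagged.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [f"x{i}" for i in range(X.shape[1])])
    subjects = (list(features.index) if isinstance(features, pd.DataFrame)
                else list(range(X.shape[0])))
    y = np.asarray(labels, dtype=bool)
    n = len(y)
    if n < 3 or y.all() or not y.any():
        raise ValueError("need n >= 3 with both classes present")

    if selection_policy == "fixed_features":
        sel = (list(fixed_feature_names) if fixed_feature_names is not None
               else stepwise_select(X, y, enter_p, remove_p, names))
        if not sel:
            raise ValueError("empty feature selection; no model to validate")
    elif selection_policy != "nested_stepwise":
        raise ValueError("selection_policy must be 'fixed_features' or "
                         "'nested_stepwise'")

    rows = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, ytr = X[keep], y[keep]
        flagged = False
        if selection_policy == "nested_stepwise":
            sel_i = stepwise_select(Xtr, ytr, enter_p, remove_p, names)
        else:
            sel_i = sel
        if ytr.all() or not ytr.any() or not sel_i:
            pred = bool(ytr.mean() >= 0.5)   # training majority / prior
            score = np.nan
            flagged = True
        else:
            cols = [names.index(f) for f in sel_i]
            try:
                model = fit_lda(Xtr[:, cols], ytr, priors=priors,
                                feature_names=sel_i)
                score = float(discriminant_score(model, X[i, cols]))
                pred = score < 0
            except np.linalg.LinAlgError:
                pred = bool(ytr.mean() >= 0.5)
                score = np.nan
                flagged = True
        rows.append({"subject": subjects[i], "actual": bool(y[i]),
                     "predicted": bool(pred), "score": score,
                     "flagged": flagged,
                     "features": ",".join(sel_i)})
    table = pd.DataFrame(rows)
    tp = int(((table.actual) & (table.predicted)).sum())
    tn = int((~table.actual & ~table.predicted).sum())
    fp = int((~table.actual & table.predicted).sum())
    fn = int((table.actual & ~table.predicted).sum())
    return ConfusionCounts(tp, tn, fp, fn), table


def classification_metrics(counts: ConfusionCounts) -> ValidationMetrics:
    """Sensitivity, specificity and accuracy in percent.

    A metric whose denominator is zero is undefined and reported as NaN.
    """
    sens = (100.0 * counts.TP / (counts.TP + counts.FN)
            if counts.TP + counts.FN > 0 else float("nan"))
    spec = (100.0 * counts.TN / (counts.TN + counts.FP)
            if counts.TN + counts.FP > 0 else float("nan"))
    acc = (100.0 * (counts.TP + counts.TN) / counts.n
           if counts.n > 0 else float("nan"))
    return ValidationMetrics(sens, spec, acc)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class ResponderLDA:
    """Stepwise-LDA responder predictor built from per-subject data.

    Parameters
    ----------
    features
        DataFrame of ECRS band amplitudes, subjects x bands.
    labels
        Boolean responder labels aligned with ``features``.
    priors
        ``"equal"`` (midpoint boundary) or ``"proportional"``.

    Examples
    --------
    >>> model = ResponderLDA(ecrs_wide, indices["responder_L2"])
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, features: pd.DataFrame, labels, priors: str = "equal"):
        self.features = features.astype(float)
        self.labels = pd.Series(np.asarray(labels, dtype=bool),
                                index=features.index)
        self.priors = priors

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str,
                       feature_cols=None, priors: str = "equal"):
        cols = list(feature_cols) if feature_cols is not None else \
            [b for b in BAND_ORDER if b in df.columns]
        return cls(df[cols], df[label_col], priors=priors)

    def fit(self, stepwise: bool = True, enter_p: float = 0.05,
            remove_p: float = 0.10) -> "ResponderLDAResults":
        names = list(self.features.columns)
        y = self.labels.to_numpy()
        if stepwise:
            selected = stepwise_select(self.features.to_numpy(), y,
                                       enter_p, remove_p, names)
        else:
            selected = names
        status = "ok"
        model = None
        if not selected:
            status = "empty-selection"
        else:
            model = fit_lda(self.features[selected].to_numpy(), y,
                            priors=self.priors, feature_names=selected)
        return ResponderLDAResults(self, model, selected, status,
                                   enter_p=enter_p, remove_p=remove_p)


@dataclass
class ResponderLDAResults:
    """Fitted responder predictor with its validation methods."""

    parent: ResponderLDA
    model: DiscriminantModel | None
    selected_features: list[str]
    status: str
    enter_p: float = 0.05
    remove_p: float = 0.10

    @property
    def coefficients(self) -> pd.Series:
        self._require_model()
        return pd.Series(self.model.coefficients,
                         index=list(self.model.feature_names), name="a_i")

    @property
    def intercept(self) -> float:
        self._require_model()
        return self.model.intercept

    def _require_model(self):
        if self.model is None:
            raise ValueError("no features passed stepwise entry; "
                             "model building aborted (status="
                             f"{self.status!r})")

    def scores(self) -> pd.Series:
        """Training discriminant scores (responders negative by construction)."""
        self._require_model()
        X = self.parent.features[self.selected_features].to_numpy()
        return pd.Series(discriminant_score(self.model, X),
                         index=self.parent.features.index, name="D")

    def loocv(self, selection_policy: str = "fixed_features"
              ) -> tuple[ConfusionCounts, ValidationMetrics, pd.DataFrame]:
        if selection_policy == "fixed_features":
            self._require_model()
        counts, table = loocv_validate(
            self.parent.features, self.parent.labels.to_numpy(),
            selection_policy=selection_policy, priors=self.parent.priors,
            enter_p=self.enter_p, remove_p=self.remove_p,
            fixed_feature_names=(self.selected_features
                                 if selection_policy == "fixed_features"
                                 else None),
        )
        return counts, classification_metrics(counts), table

    def summary(self) -> str:
        lines = ["Stepwise LDA responder predictor",
                 "=" * 40,
                 f"priors:            {self.parent.priors}",
                 f"n subjects:        {len(self.parent.labels)} "
                 f"({int(self.parent.labels.sum())} responders)",
                 f"selected features: {', '.join(self.selected_features) or '(none)'}"]
        if self.model is not None:
            lines.append(f"intercept a0:      {self.intercept:+.4f}")
            for name, a in self.coefficients.items():
                lines.append(f"coef {name:>10s}:    {a:+.4f}")
            counts, metrics, _ = self.loocv()
            m = metrics.rounded()
            lines += [
                "LOOCV (fixed features):",
                f"  confusion TP/TN/FP/FN: {counts.TP}/{counts.TN}/"
                f"{counts.FP}/{counts.FN}",
                f"  sensitivity: {m.sensitivity_pct:.1f}%",
                f"  specificity: {m.specificity_pct:.1f}%",
                f"  accuracy:    {m.accuracy_pct:.1f}%",
            ]
        else:
            lines.append(f"status: {self.status}")
        return "\n".join(lines)
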