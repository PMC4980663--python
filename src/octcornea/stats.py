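"""Group statistics: ANOVA, Wilks'-lambda stepwise LDA, ROC/AUC.

The screening question is whether thickness indices separate normal,
sub-clinical keratoconus and manifest keratoconus eyes.  The machinery:

* one-way fixed-effects ANOVA per index (with Dunnett-style post-hoc
  contrasts of each patient group against normal),
* forward stepwise linear discriminant analysis: at each step the
  candidate index minimising Wilks' lambda of the selected set enters if
  its partial F-to-enter exceeds a threshold (default 3.84, the 0.05
  chi-square/F criterion); no removal step,
* a linear discriminant function on the selected indices, oriented so
  diseased eyes score higher than normal ones and scaled to unit pooled
  within-group variance,
* empirical ROC curves with trapezoidal AUC and the Youden-J cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def anova_groups(values: pd.DataFrame | np.ndarray, labels) -> pd.DataFrame:
    """One-way ANOVA F/p and descriptives per variable.

    ``values``: one column per variable (a Series/1-D array is treated as
    a single variable), ``labels``: group label per row.  Returns a tidy
    frame with one row per (variable, group) carrying the group mean, SD,
    95% CI and the variable's F and p.
    """
    df = pd.DataFrame(values)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    rows = []
    for var in df.columns:
        x = df[var].to_numpy(dtype=float)
        per_group = [x[labels == g] for g in groups]
        per_group_clean = [v[np.isfinite(v)] for v in per_group]
        F, p = sps.f_oneway(*per_group_clean)
        for g, v in zip(groups, per_group_clean):
            mean = v.mean()
            sd = v.std(ddof=1)
            half = sps.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size)
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "n": v.size,
                    "mean": mean,
                    "sd": sd,
                    "ci95_low": mean - half,
                    "ci95_high": mean + half,
                    "F": float(F),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def dunnett_vs_control(values, labels, control: str) -> dict:
    """Dunnett-style many-to-one comparisons against the control group.

    Returns {group: p-value} for each non-control group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    others = [g for g in pd.unique(labels) if g != control]
    res = sps.dunnett(
        *[values[labels == g] for g in others], control=values[labels == control]
    )
    return {g: float(p) for g, p in zip(others, res.pvalue)}


# ---------------------------------------------------------------------------
# stepwise LDA
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantModel:
    """A (possibly empty) stepwise linear discriminant function."""

    features: list[str]
    coefficients: np.ndarray
    intercept: float
    wilks_trajectory: list[float]
    entry_f: list[float]
    f_enter: float
    control_label: str
    empty: bool = False

    def to_json(self) -> str:
        d = {
            "features": self.features,
            "coefficients": np.asarray(self.coefficients, dtype=float).tolist(),
            "intercept": float(self.intercept),
            "wilks_trajectory": [float(v) for v in self.wilks_trajectory],
            "entry_f": [float(v) for v in self.entry_f],
            "f_enter": float(self.f_enter),
            "control_label": self.control_label,
            "empty": bool(self.empty),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        d["coefficients"] = np.asarray(d["coefficients"], dtype=float)
        return cls(**d)


def _scatter(X: np.ndarray, labels: np.ndarray):
    """Within-group (W) and total (T) scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(labels):
        sel = X[labels == g]
        d = sel - sel.mean(axis=0)
        W += d.T @ d
    return W, T


def _wilks(X: np.ndarray, labels: np.ndarray) -> float:
    W, T = _scatter(X, labels)
    if X.shape[1] == 0:
        return 1.0
    detT = np.linalg.det(T)
    if detT <= 0:
        raise ValueError("singular total scatter matrix")
    return float(np.linalg.det(W) / detT)


def stepwise_lda(
    features: pd.DataFrame,
    labels,
    f_enter: float = 3.84,
    control_label: str = "normal",
) -> DiscriminantModel:
    """Forward Wilks'-lambda stepwise selection + linear discriminant fit.

    At each step the candidate minimising the Wilks' lambda of the
    selected set enters (ties broken lexicographically by name) if its
    partial F-to-enter exceeds ``f_enter``; selection stops otherwise.
    With no feature passing at step 1 an empty, flagged model is returned.
    The discriminant direction is Fisher's for two groups, the leading
    canonical variate for three or more; scores are scaled to unit pooled
    within-group variance and oriented so the non-control (diseased)
    groups score above the control group.
    """
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    labels = np.asarray(labels)
    n, n_feat = X.shape
    groups = np.unique(labels)
    g = groups.size
    if n_feat < 2:
        raise ValueError("need at least 2 candidate features")
    if g < 2 or any((labels == gr).sum() < 2 for gr in groups):
        raise ValueError("groups degenerate: need >= 2 groups with >= 2 eyes each")

    selected: list[int] = []
    lam_traj: list[float] = []
    entry_f: list[float] = []
    lam_old = 1.0
    while True:
        best = None  # (lambda, name, index)
        p = len(selected)
        if n - g - p <= 0:  # no residual degrees of freedom left
            break
        for j in range(n_feat):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                lam = _wilks(X[:, cols], labels)
            except ValueError:
                continue
            key = (lam, names[j])
            if best is None or key < best[0]:
                best = (key, j)
        if best is None:
            break
        (lam_new, _), j = best
        if lam_new <= 1e-12:  # candidate set (numerically) singular
            break
        F = (n - g - p) / (g - 1) * (lam_old / lam_new - 1.0)
        if F <= f_enter:
            break
        selected.append(j)
        lam_traj.append(lam_new)
        entry_f.append(float(F))
        lam_old = lam_new
        if len(selected) == n_feat:
            break

    if not selected:
        return DiscriminantModel(
            features=[],
            coefficients=np.zeros(0),
            intercept=0.0,
            wilks_trajectory=[],
            entry_f=[],
            f_enter=f_enter,
            control_label=control_label,
            empty=True,
        )

    Xs = X[:, selected]
    W, T = _scatter(Xs, labels)
    B = T - W
    S_pooled = W / (n - g)
    try:
        if g == 2:
            mus = [Xs[labels == gr].mean(axis=0) for gr in groups]
            w = np.linalg.solve(S_pooled, mus[1] - mus[0])
        else:
            evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
            w = np.real(evecs[:, np.argmax(np.real(evals))])
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled covariance") from err
    scale = float(np.sqrt(w @ S_pooled @ w))
    if scale <= 0:
        raise ValueError("degenerate discriminant direction")
    w = w / scale
    # orient: diseased (non-control) mean score above control mean score
    scores = Xs @ w
    ctrl = scores[labels == control_label]
    dis = scores[labels != control_label]
    if ctrl.size and dis.size and dis.mean() < ctrl.mean():
        w = -w
        scores = -scores
    intercept = -float((Xs @ w).mean())
    return DiscriminantModel(
        features=[names[j] for j in selected],
        coefficients=w,
        intercept=intercept,
        wilks_trajectory=lam_traj,
        entry_f=entry_f,
        f_enter=f_enter,
        control_label=control_label,
    )


def fit_discriminant(
    features: pd.DataFrame, labels, feature_names: list[str], control_label: str = "normal"
) -> DiscriminantModel:
    """Linear discriminant on a fixed feature set (no selection step)."""
    sub = features[feature_names]
    X = sub.to_numpy(dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n, g = X.shape[0], groups.size
    W, T = _scatter(X, labels)
    B = T - W
    S_pooled = W / (n - g)
    if g == 2:
        mus = [X[labels == gr].mean(axis=0) for gr in groups]
        w = np.linalg.solve(S_pooled, mus[1] - mus[0])
    else:
        evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
        w = np.real(evecs[:, np.argmax(np.real(evals))])
    w = w / float(np.sqrt(w @ S_pooled @ w))
    scores = X @ w
    if scores[labels != control_label].mean() < scores[labels == control_label].mean():
        w = -w
        scores = -scores
    return DiscriminantModel(
        features=list(feature_names),
        coefficients=w,
        intercept=-float(scores.mean()),
        wilks_trajectory=[_wilks(X, labels)],
        entry_f=[],
        f_enter=np.nan,
        control_label=control_label,
    )


def discriminant_score(model: DiscriminantModel, rows: pd.DataFrame) -> np.ndarray:
    """score = intercept + sum(coefficient * feature) per eye."""
    if model.empty or not model.features:
        raise ValueError("empty discriminant model")
    missing = [f for f in model.features if f not in rows.columns]
    if missing:
        raise ValueError(f"missing feature value(s): {missing}")
    X = rows[model.features].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("missing feature value in scoring rows")
    return X @ np.asarray(model.coefficients) + model.intercept


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    positive_direction: str


def roc_analysis(scores, labels, positive_direction: str = "higher") -> ROCResult:
    """Empirical ROC of a score against binary labels.

    ``labels`` are truthy for diseased eyes.  ``positive_direction`` says
    whether diseased eyes score ``"higher"`` or ``"lower"``.  AUC is the
    trapezoidal area (equivalently the concordance probability with ties
    counted 1/2); the reported cutoff maximises Youden's J with ties
    broken toward higher sensitivity.
    """
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC analysis")
    flip = positive_direction == "lower"
    sf = -s if flip else s
    fpr, tpr, thr = roc_curve(y.astype(int), sf, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    J = tpr - fpr
    best = np.flatnonzero(J == J.max())
    k = best[np.argmax(tpr[best])]
    cutoff = float(thr[k])
    if not np.isfinite(cutoff):  # sklearn's sentinel first threshold
        cutoff = float(sf.max())
    if flip:
        cutoff = -cutoff
    return ROCResult(
        thresholds=(-thr if flip else thr),
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        cutoff=cutoff,
        sensitivity_at_cutoff=float(tpr[k]),
        specificity_at_cutoff=float(1.0 - fpr[k]),
        positive_direction=positive_direction,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

#: indices where disease lowers the value (ectasia ratios); the variation
#: and pattern-deviation indices rise with disease
LOWER_IN_DISEASE = ("EEI", "EEI_MAX", "BEI", "BEI_MAX", "SEI", "SEI_MAX")


def index_direction(name: str) -> str:
    return "lower" if name in LOWER_IN_DISEASE else "higher"


def table_report(
    cohort: pd.DataFrame,
    index_names,
    control_label: str,
    case_labels,
    group_col: str = "group",
) -> pd.DataFrame:
    """Diagnostic-table-shaped report: one row per (index, case group) with
    group means +/- SD, Dunnett-style p vs control, AUC, Youden cutoff and
    the sensitivity/specificity there."""
    rows = []
    for name in index_names:
        base = cohort[cohort[group_col] == control_label][name].dropna()
        for case in case_labels:
            vals = cohort[cohort[group_col] == case][name].dropna()
            scores = np.concatenate([base, vals])
            y = np.concatenate([np.zeros(base.size), np.ones(vals.size)])
            roc = roc_analysis(scores, y, positive_direction=index_direction(name))
            sub = cohort[cohort[group_col].isin([control_label, case])]
            p = dunnett_vs_control(sub[name].to_numpy(), sub[group_col].to_numpy(), control_label)[case]
            rows.append(
                {
                    "index": name,
                    "comparison": f"{case}_vs_{control_label}",
                    "control_mean": round(float(base.mean()), 2),
                    "control_sd": round(float(base.std(ddof=1)), 2),
                    "case_mean": round(float(vals.mean()), 2),
                    "case_sd": round(float(vals.std(ddof=1)), 2),
                    "p": round(p, 4),
                    "auc": round(roc.auc, 3),
                    "cutoff": round(roc.cutoff, 2),
                    "sensitivity_pct": round(100 * roc.sensitivity_at_cutoff),
                    "specificity_pct": round(100 * roc.specificity_at_cutoff),
                }
            )
    return pd.DataFrame(rows)
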