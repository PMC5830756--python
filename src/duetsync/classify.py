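"""Two-stage bout classification and evaluation.

Stage one screens each predictor alone with a cross-validated univariate
logistic regression, flagging predictors that cannot beat the majority-class
baseline. Stage two fits multi-predictor models — an additive logistic
regression and a random forest (500 trees, sqrt(p) variables per split) — on
a random 80% training split and reports the area under the ROC curve on the
held-out 20%, with a DeLong 95% confidence interval. Model comparisons use
DeLong's paired test for correlated ROC curves. The decision threshold for
downstream excerpt selection is fixed by the Youden index
(max sensitivity + specificity - 1).

The random forest is there for a specific reason: interaction bouts are
signalled by *combinations* of band energies (e.g. high narrow-band energy at
matched frequencies with moderate overall motion), which an additive logistic
model cannot express without explicit interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from .predictors import FEATURE_COLUMNS
from .timeseries import TimeSeries

__all__ = [
    "ClassificationReport",
    "ImportanceReport",
    "ExcerptSpec",
    "split_train_eval",
    "screen_predictors",
    "fit_predict",
    "delong_auc_ci",
    "delong_compare",
    "variable_importance",
    "youden_cutoff",
    "select_excerpts",
]


@dataclass
class ClassificationReport:
    model_kind: str
    predictor_set: list[str]
    auc: float
    ci95: tuple[float, float]
    cv_scheme: tuple[int, int] | None
    cv_auc_mean: float | None
    cv_auc_sd: float | None
    cutoff: float
    fp_rate: float  # false positives / annotated non-interactions
    fn_rate: float  # false negatives / annotated interactions
    seed: int
    n_train: int
    n_eval: int
    eval_scores: np.ndarray = field(repr=False, default=None)
    eval_labels: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)


@dataclass
class ImportanceReport:
    """Per-predictor importance, normalized so the top predictor is 1."""

    importance: dict[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importance.items(), key=lambda kv: -kv[1])


@dataclass(frozen=True)
class ExcerptSpec:
    recording_id: str
    start_s: float
    duration_s: float
    cell: str  # TP | TN | FP | FN
    qom_class: str  # high | low


def split_train_eval(
    table: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-level random split into disjoint, exhaustive train/eval sets.

    This mirrors frame-level splitting: temporally adjacent (autocorrelated)
    frames land on both sides, which flatters held-out performance relative
    to a recording-level split. For an honest generalization estimate, split
    by ``recording_id`` yourself before building the table.
    """
    if not 0.0 < train_frac <= 1.0:
        raise ValueError("train_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = int(round(train_frac * n))
    if stratify:
        train_idx = []
        for _, grp in table.groupby("label"):
            k = int(round(train_frac * len(grp)))
            train_idx.append(rng.permutation(grp.index.to_numpy())[:k])
        train_idx = np.concatenate(train_idx)
    else:
        train_idx = rng.permutation(table.index.to_numpy())[:n_train]
    mask = table.index.isin(train_idx)
    return table.loc[mask], table.loc[~mask]


def _features_in(table: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_COLUMNS if c in table.columns]


def screen_predictors(
    train: pd.DataFrame,
    predictors: list[str] | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariate logistic screening of each predictor under CV.

    Returns a DataFrame (one row per predictor, sorted by mean CV AUC) with
    ``auc_mean``, ``auc_sd`` and ``eliminate`` — True when the predictor's
    CV-AUC lower bound (mean - 1.64 sd) does not clear the chance level of
    the majority-class baseline (AUC 0.5).
    """
    predictors = predictors or _features_in(train)
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("screening requires both classes in the training data")
    cv = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
    )
    rows = []
    for p in predictors:
        X = train[[p]].to_numpy()
        scores = cross_val_score(
            LogisticRegression(max_iter=1000), X, y, cv=cv, scoring="roc_auc"
        )
        mu, sd = float(scores.mean()), float(scores.std())
        rows.append(
            {"predictor": p, "auc_mean": mu, "auc_sd": sd, "eliminate": mu - 1.64 * sd <= 0.5}
        )
    return (
        pd.DataFrame(rows).sort_values("auc_mean", ascending=False).reset_index(drop=True)
    )


def _make_model(model_kind: str, ntree: int, mtry, seed: int):
    if model_kind == "logistic":
        return LogisticRegression(max_iter=2000)
    if model_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=ntree,
            max_features=mtry,
            random_state=seed,
            n_jobs=1,
            oob_score=False,
        )
    raise ValueError(f"unknown model_kind {model_kind!r}")


def fit_predict(
    train: pd.DataFrame,
    eval_set: pd.DataFrame,
    model_kind: str = "logistic",
    predictor_set: list[str] | None = None,
    ntree: int = 500,
    mtry="sqrt",
    cv: tuple[int, int] | None = (10, 10),
    interactions: bool = False,
    seed: int = 0,
) -> ClassificationReport:
    """Fit on the training split, report held-out AUC with a DeLong CI95.

    ``cv=(folds, repeats)`` additionally runs repeated stratified k-fold CV
    inside the training split as a stability check (the models have no tuned
    hyperparameters, so CV informs, but the reported AUC is always the
    held-out one); pass ``cv=None`` to skip it. ``interactions=True``
    augments a logistic model with all pairwise product terms.
    """
    predictor_set = predictor_set or _features_in(train)
    y_tr = train["label"].to_numpy()
    y_ev = eval_set["label"].to_numpy()
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    X_tr = train[predictor_set].to_numpy()
    X_ev = eval_set[predictor_set].to_numpy()
    if interactions and model_kind == "logistic":
        X_tr = _with_products(X_tr)
        X_ev = _with_products(X_ev)

    model = _make_model(model_kind, ntree, mtry, seed)
    cv_mu = cv_sd = None
    if cv is not None:
        folds, repeats = cv
        splitter = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed
        )
        scores = cross_val_score(model, X_tr, y_tr, cv=splitter, scoring="roc_auc")
        cv_mu, cv_sd = float(scores.mean()), float(scores.std())
    model.fit(X_tr, y_tr)
    scores_ev = model.predict_proba(X_ev)[:, 1]
    auc, (lo, hi) = delong_auc_ci(scores_ev, y_ev)
    cutoff = youden_cutoff(scores_ev, y_ev)
    pred = scores_ev >= cutoff
    pos, neg = y_ev == 1, y_ev == 0
    fn_rate = float((~pred[pos]).mean()) if pos.any() else float("nan")
    fp_rate = float(pred[neg].mean()) if neg.any() else float("nan")
    return ClassificationReport(
        model_kind=model_kind,
        predictor_set=list(predictor_set),
        auc=float(auc),
        ci95=(float(lo), float(hi)),
        cv_scheme=cv,
        cv_auc_mean=cv_mu,
        cv_auc_sd=cv_sd,
        cutoff=float(cutoff),
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        seed=seed,
        n_train=len(train),
        n_eval=len(eval_set),
        eval_scores=scores_ev,
        eval_labels=y_ev,
        model=model,
    )


def _with_products(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    prods = [X[:, i] * X[:, j] for i in range(p) for j in range(i + 1, p)]
    return np.column_stack([X] + prods) if prods else X


# ---------------------------------------------------------------- DeLong ----

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    mid = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = mid
    return out


def _delong_structures(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10, V01 and the AUC for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes present")
    allv = np.concatenate([pos, neg])
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(allv)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC and its DeLong asymptotic confidence interval."""
    auc, v10, v01 = _delong_structures(np.asarray(scores), np.asarray(labels))
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def delong_compare(
    predictions_a: np.ndarray, predictions_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided p-value of DeLong's paired test for two correlated AUCs."""
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    labels = np.asarray(labels)
    auc_a, v10_a, v01_a = _delong_structures(a, labels)
    auc_b, v10_b, v01_b = _delong_structures(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------- importance ----

def variable_importance(
    report: ClassificationReport,
    eval_set: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance (accuracy decrease) normalized to max 1.

    Each predictor column of the held-out data is shuffled in turn and the
    drop in classification accuracy recorded; negative values are floored at
    0 before normalization.
    """
    X = eval_set[report.predictor_set].to_numpy()
    y = eval_set["label"].to_numpy()
    res = permutation_importance(
        report.model, X, y, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    imp = np.clip(res.importances_mean, 0.0, None)
    top = imp.max()
    imp = imp / top if top > 0 else imp
    return ImportanceReport(dict(zip(report.predictor_set, map(float, imp))))


# ---------------------------------------------------------------- Youden ----

def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    (plus outer sentinels); ties on J resolve to the lowest threshold. For a
    perfectly separating score this returns the midpoint of the gap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    npos, nneg = int(pos.sum()), int((~pos).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("youden_cutoff requires both classes")
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_j, best_t = -np.inf, cands[0]
    for t in cands:
        pred = scores >= t
        sens = (pred & pos).sum() / npos
        spec = (~pred & ~pos).sum() / nneg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


# ------------------------------------------------------------- excerpts ----

def select_excerpts(
    predictions: np.ndarray,
    labels: np.ndarray,
    qom: TimeSeries,
    cutoff: float,
    rate_hz: float,
    recording_id: str = "",
    n_per_cell: int = 12,
    dur_s: float = 7.5,
    majority_s: float = 4.0,
    hop_s: float = 0.5,
) -> list[ExcerptSpec]:
    """Candidate excerpt windows for the four model-prediction cells.

    Slides a ``dur_s`` window over the frame stream; a window belongs to cell
    (label L, prediction P) if frames where both the annotation equals L and
    the thresholded prediction equals P total at least ``majority_s``
    seconds. Window quantity of motion (summed QoM) is median-split into
    high/low over the candidate pool, and up to ``n_per_cell`` temporally
    non-overlapping windows per cell are returned, balanced on the QoM class.
    If a cell lacks candidates a warning is issued and fewer are returned —
    the criteria are never relaxed.
    """
    import warnings as _warnings

    pred = (np.asarray(predictions, dtype=float) >= cutoff).astype(int)
    lab = np.asarray(labels).astype(int)
    if pred.size != lab.size:
        raise ValueError("predictions and labels must be the same length")
    q = qom.values
    if q.size != lab.size:
        raise ValueError("qom must be on the same frame grid as the labels")

    win = int(round(dur_s * rate_hz))
    hop = max(1, int(round(hop_s * rate_hz)))
    need = majority_s * rate_hz
    cells = {"TP": (1, 1), "FN": (1, 0), "FP": (0, 1), "TN": (0, 0)}
    starts = np.arange(0, pred.size - win + 1, hop)
    cand: list[tuple[str, int, float]] = []
    for s0 in starts:
        sl = slice(s0, s0 + win)
        counts = {
            name: int(((lab[sl] == L) & (pred[sl] == P)).sum())
            for name, (L, P) in cells.items()
        }
        name, cnt = max(counts.items(), key=lambda kv: kv[1])
        if cnt >= need:
            cand.append((name, int(s0), float(q[sl].sum())))
    if not cand:
        _warnings.warn("no candidate windows satisfy the majority criterion")
        return []

    med = float(np.median([c[2] for c in cand]))
    out: list[ExcerptSpec] = []
    for cell in cells:
        rows = [c for c in cand if c[0] == cell]
        chosen: list[tuple[int, float]] = []
        for qcls in ("high", "low"):
            pool = [
                r for r in rows if (r[2] > med) == (qcls == "high")
            ]
            pool.sort(key=lambda r: -abs(r[2] - med))  # extreme QoM first
            taken = 0
            for _, s0, qv in pool:
                if taken >= n_per_cell // 2:
                    break
                if any(abs(s0 - s1) < win for s1, _ in chosen):
                    continue
                chosen.append((s0, qv))
                out.append(
                    ExcerptSpec(recording_id, s0 / rate_hz, dur_s, cell, qcls)
                )
                taken += 1
            if taken < n_per_cell // 2:
                _warnings.warn(
                    f"cell {cell}/{qcls}: only {taken} of {n_per_cell // 2} "
                    f"non-overlapping excerpts available"
                )
    return out
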