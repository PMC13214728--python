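"""Subject-independent cognitive-state classification from metric series.

Pipeline: linear-interpolation alignment of per-session metric series to a
common length, sliding-window construction inside each session (label =
state of the window's final step), per-channel standardization fitted on
training windows only, leave-one-subject-out (LOSO) cross-validation of an
LSTM sequence classifier, random-forest and gradient-boosted-tree baselines
on flattened windows, and per-fold / per-class metric reporting.

The subject-aware contract: windows never span two sessions, every fold's
test set is exactly one participant, and scaler statistics come from the
training participants alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, log_loss, roc_auc_score

from gazestate.lstm import LSTMClassifier
from gazestate.synthetic import SessionRecord

FEATURE_CHANNELS = (
    "fixation_duration",
    "fixation_count",
    "saccade_duration",
    "saccade_count",
)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Hyperparams:
    """Training configuration for the LSTM classifier."""

    window_length: int = 10
    hidden_units: int = 50
    dropout: float = 0.2
    batch_norm: bool = True
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1  # fraction of training participants held out
    include_time: bool = False  # opt-in 5th channel (timestamps)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.hidden_units < 1:
            raise ValueError("window_length and hidden_units must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class FoldReport:
    """Evaluation of one held-out participant."""

    participant_id: str
    accuracy: float  # percent
    f1_macro: float
    recall_macro: float
    precision_macro: float
    auc_macro: float
    loss: float
    per_class: pd.DataFrame  # precision/recall/f1 per class, percent
    confusion: np.ndarray  # 3x3, rows = true class


def interpolate_align(series: list[np.ndarray]) -> list[np.ndarray]:
    """Linearly resample every series onto the index grid of the longest.

    Each (L_i, F) series is stretched to length L_max by per-channel linear
    interpolation over a normalized index; endpoints are preserved.
    """
    if any(len(s) < 2 for s in series):
        raise AlignmentError("every series needs at least 2 points")
    L = max(len(s) for s in series)
    out = []
    for s in series:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if s.shape[0] == 1:
            s = s.T
        if len(s) == L:
            out.append(s)
            continue
        xi = np.linspace(0.0, 1.0, len(s))
        xo = np.linspace(0.0, 1.0, L)
        out.append(np.column_stack([np.interp(xo, xi, s[:, j]) for j in range(s.shape[1])]))
    return out


def session_features(rec: SessionRecord, include_time: bool = False) -> np.ndarray:
    cols = (("t_s",) if include_time else ()) + FEATURE_CHANNELS
    return rec.metrics[list(cols)].to_numpy(dtype=float)


def build_windows(
    features: np.ndarray, label: int, participant_id: str, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding windows of stride 1 within one session.

    A session of L steps yields L - T + 1 windows; every window carries the
    session's state label (the label of its final time step) and
    participant id.  Sessions shorter than T yield no windows.
    """
    L = len(features)
    if L < T:
        return (
            np.empty((0, T, features.shape[1])),
            np.empty(0, dtype=int),
            np.empty(0, dtype=object),
        )
    idx = np.arange(L - T + 1)[:, None] + np.arange(T)[None, :]
    X = features[idx]
    y = np.full(len(X), label, dtype=int)
    groups = np.full(len(X), participant_id, dtype=object)
    return X, y, groups


def build_dataset(
    records: list[SessionRecord], T: int = 10, include_time: bool = False, align: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed dataset (X, y, participant groups) from session records.

    Sessions are first aligned to the longest series length, then windowed
    independently so no window crosses a session boundary.
    """
    feats = [session_features(r, include_time) for r in records]
    if align:
        feats = interpolate_align(feats)
    Xs, ys, gs = [], [], []
    for f, rec in zip(feats, records):
        X, y, g = build_windows(f, rec.state_label, rec.participant_id, T)
        if len(X):
            Xs.append(X)
            ys.append(y)
            gs.append(g)
    if not Xs:
        raise AlignmentError(f"no session is at least {T} steps long")
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(gs)


def standardize(
    train: np.ndarray, *others: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Per-channel z-scoring with statistics fitted on the training windows.

    Mean/SD are computed over all training windows and time steps per
    channel; zero-variance channels are centered with a unit divisor.
    """
    if train.size == 0:
        raise ValueError("training set must be non-empty")
    mu = train.mean(axis=(0, 1))
    sd = train.std(axis=(0, 1))
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((a - mu) / sd for a in (train,) + others)


def loso_folds(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """One fold per participant: (train indices, test indices, held-out id).

    Folds partition the window set; no participant appears on both sides.
    """
    groups = np.asarray(groups)
    pids = sorted(set(groups))
    if len(pids) < 2:
        raise ValueError("LOSO needs at least 2 participants")
    folds = []
    for pid in pids:
        test = np.flatnonzero(groups == pid)
        train = np.flatnonzero(groups != pid)
        folds.append((train, test, pid))
    return folds


def _val_split(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, frac: float, rng: np.random.Generator
):
    """Hold out a fraction of training participants (not windows) for early
    stopping, preserving the subject-aware principle."""
    pids = sorted(set(groups))
    n_val = max(1, int(round(frac * len(pids))))
    val_pids = set(rng.choice(pids, size=n_val, replace=False))
    val_mask = np.isin(groups, list(val_pids))
    if val_mask.all() or not val_mask.any():
        return X, y, None, None
    return X[~val_mask], y[~val_mask], X[val_mask], y[val_mask]


def train_lstm(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, hp: Hyperparams
) -> LSTMClassifier:
    """Fit the LSTM on training windows with a grouped validation split."""
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("training set must contain all three states")
    rng = np.random.default_rng(hp.seed)
    Xtr, ytr, Xval, yval = _val_split(X, y, groups, hp.val_fraction, rng)
    model = LSTMClassifier(
        n_features=X.shape[2],
        n_classes=3,
        hidden=hp.hidden_units,
        dropout=hp.dropout,
        batch_norm=hp.batch_norm,
        lr=hp.learning_rate,
        batch_size=hp.batch_size,
        max_epochs=hp.max_epochs,
        patience=hp.patience,
        seed=hp.seed,
    )
    return model.fit(Xtr, ytr, Xval, yval)


def evaluate(model, X: np.ndarray, y: np.ndarray, participant_id: str = "") -> FoldReport:
    """Fold metrics from softmax scores: accuracy, macro P/R/F1, one-vs-rest
    macro-AUC, mean cross-entropy, and the 3x3 confusion matrix.

    If the test set lacks a class, AUC averages over the present classes.
    All rates are percentages.
    """
    if len(X) == 0:
        raise ValueError("test set must be non-empty")
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    labels = [0, 1, 2]
    cm = confusion_matrix(y, pred, labels=labels)
    support = cm.sum(axis=1)
    tp = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(cm.sum(axis=0) > 0, tp / cm.sum(axis=0), 0.0)
        rec = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    present = support > 0
    accuracy = tp.sum() / cm.sum()
    aucs = []
    for c in labels:
        yc = (np.asarray(y) == c).astype(int)
        if 0 < yc.sum() < len(yc):
            aucs.append(roc_auc_score(yc, probs[:, c]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    loss = log_loss(y, probs, labels=labels)
    per_class = pd.DataFrame(
        {
            "state": labels,
            "precision": 100 * prec,
            "recall": 100 * rec,
            "f1": 100 * f1,
            "support": support,
        }
    )
    return FoldReport(
        participant_id=participant_id,
        accuracy=100 * float(accuracy),
        f1_macro=100 * float(f1[present].mean()),
        recall_macro=100 * float(rec[present].mean()),
        precision_macro=100 * float(prec[present].mean()),
        auc_macro=100 * auc,
        loss=float(loss),
        per_class=per_class,
        confusion=cm,
    )


def _make_baseline(name: str, seed: int):
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if name == "gbt":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            objective="multi:softprob",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown baseline {name!r}")


class _FlatModel:
    """Adapter giving tree ensembles the windowed predict_proba interface."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(X.reshape(len(X), -1), y)
        return self

    def predict_proba(self, X):
        return self.est.predict_proba(X.reshape(len(X), -1))


def run_loso(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    hp: Hyperparams | None = None,
    model: str = "lstm",
    folds: list | None = None,
) -> list[FoldReport]:
    """LOSO cross-validation of the LSTM or a tree baseline.

    All models consume the identical fold index lists and standardized
    windows, so comparisons share the exact split.
    """
    hp = hp or Hyperparams()
    folds = folds if folds is not None else loso_folds(groups)
    reports = []
    for train_idx, test_idx, pid in folds:
        Xtr, Xte = standardize(X[train_idx], X[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        if model == "lstm":
            clf = train_lstm(Xtr, ytr, groups[train_idx], hp)
        else:
            clf = _FlatModel(_make_baseline(model, hp.seed)).fit(Xtr, ytr)
        reports.append(evaluate(clf, Xte, yte, participant_id=pid))
    return reports


def summarize_runs(reports: list[FoldReport]) -> dict:
    """Mean +/- sample SD of each metric over folds, per-subject accuracy,
    and class-wise mean precision/recall/F1 across folds."""
    if not reports:
        raise ValueError("need at least one fold report")
    scalars = ["accuracy", "f1_macro", "recall_macro", "precision_macro", "auc_macro", "loss"]
    summary = {}
    for name in scalars:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        summary[name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    per_subject = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "accuracy": [r.accuracy for r in reports],
        }
    )
    classwise = (
        pd.concat([r.per_class[r.per_class["support"] > 0] for r in reports])
        .groupby("state")[["precision", "recall", "f1"]]
        .mean()
        .reset_index()
    )
    return {"summary": summary, "per_subject": per_subject, "classwise": classwise}
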