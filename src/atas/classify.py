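"""Group classifiers on fluency metrics and on event sequences.

Two families, matching how the metrics are meant to be used clinically:

* feature-based — a decision tree on all 13 metrics, or a random forest on
  the 7 metrics that separate the groups (speech rate, total pause time,
  pause count, mean pause duration, vocal duration variability, mean short
  pause duration, long pause count), validated by repeated stratified 80/20
  resampling and stratified 3-fold cross-validation;
* sequence-based — non-overlapping windows of 20 consecutive events, each
  event described by 9 features (the 7 recording-level metrics plus an event
  type code and the event duration), split at the *recording* level, z-scored
  with training-set statistics only, augmented by circular rotation of the
  event order, classified per window and aggregated to a per-recording
  prediction by majority vote (ties resolved toward AWS, the clinically
  conservative direction).

All randomness is governed by explicit seeds; fixed seeds give bit-identical
splits and accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .detection import LONG, PAUSE, SHORT, EventSequence
from .metrics import METRIC_COLUMNS

ALL13 = list(METRIC_COLUMNS)
SELECTED7 = [
    "speech_rate_wpm",
    "total_pause_time_s",
    "pause_count",
    "mean_pause_ms",
    "vocal_cv",
    "mean_short_pause_ms",
    "long_pause_count",
]

POSITIVE_LABEL = "AWS"

#: numeric event-type code: sign separates vocal from pause, magnitude
#: separates the pause subtypes
DEFAULT_TYPE_CODES = {"vocal": 1.0, SHORT: -0.5, LONG: -1.0}


def build_feature_matrix(cohort: pd.DataFrame, feature_set: str = "all13"
                         ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Feature matrix and labels; rows with missing features are dropped.

    Returns (X, y, n_dropped).
    """
    cols = ALL13 if feature_set == "all13" else SELECTED7
    if feature_set not in ("all13", "selected7"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    X = cohort[cols].apply(pd.to_numeric, errors="coerce")
    ok = X.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with missing features")
    X, y = X[ok], cohort.loc[ok, "group"].astype(str)
    if len(X) == 0:
        raise ValueError("no complete rows left")
    return X, y, n_dropped


def _make_learner(learner: str, seed: int):
    if learner == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if learner == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown learner {learner!r}")


@dataclass
class FeatureClassifierReport:
    learner: str
    repeat_accuracies: np.ndarray  # stratified 80/20 resampling
    cv_accuracies: np.ndarray  # stratified k-fold
    confusion: np.ndarray  # held-out confusion matrix for the first repeat
    classes: list[str]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.repeat_accuracies.mean())

    @property
    def mean_cv_accuracy(self) -> float:
        return float(self.cv_accuracies.mean())


def evaluate_feature_classifier(X: pd.DataFrame, y: pd.Series,
                                learner: str = "random_forest",
                                n_repeats: int = 10, test_size: float = 0.2,
                                cv_folds: int = 3, seed: int = 0
                                ) -> FeatureClassifierReport:
    """Repeated stratified 80/20 resampling plus stratified k-fold CV."""
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    base = _make_learner(learner, seed)
    classes = sorted(np.unique(yv))

    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_size,
                                 random_state=seed)
    accs, conf = [], None
    for k, (tr, te) in enumerate(sss.split(Xv, yv)):
        model = clone(base).fit(Xv[tr], yv[tr])
        pred = model.predict(Xv[te])
        accs.append(accuracy_score(yv[te], pred))
        if k == 0:
            conf = confusion_matrix(yv[te], pred, labels=classes)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_accs = [
        accuracy_score(yv[te], clone(base).fit(Xv[tr], yv[tr]).predict(Xv[te]))
        for tr, te in skf.split(Xv, yv)
    ]
    return FeatureClassifierReport(
        learner=learner, repeat_accuracies=np.array(accs),
        cv_accuracies=np.array(cv_accs), confusion=conf,
        classes=list(classes), seed=seed)


# ---------------------------------------------------------------------------
# sequence windows
# ---------------------------------------------------------------------------

def event_features(seq: EventSequence, recording_metrics: pd.Series,
                   type_codes: dict[str, float] | None = None) -> np.ndarray:
    """Per-event 9-feature rows: 7 recording metrics + type code + duration."""
    codes = type_codes or DEFAULT_TYPE_CODES
    base = recording_metrics[SELECTED7].to_numpy(dtype=float)
    rows = []
    for ev in seq:
        code = codes[ev.pause_subtype] if ev.kind == PAUSE else codes["vocal"]
        rows.append(np.concatenate([base, [code, ev.duration_ms]]))
    return np.asarray(rows)


@dataclass
class EventWindowTensor:
    X: np.ndarray  # (n_windows, window, 9), z-scored with train stats
    y: np.ndarray  # group label per window
    recording_id: np.ndarray
    role: np.ndarray  # train | test | val per window
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    window: int


def build_event_windows(sequences: dict[str, EventSequence],
                        cohort: pd.DataFrame,
                        roles: dict[str, str], window: int = 20,
                        type_codes: dict[str, float] | None = None
                        ) -> EventWindowTensor:
    """Cut each recording into non-overlapping ``window``-event segments.

    ``roles`` assigns each recording to train/test/val *before* windowing.
    The trailing remainder of fewer than ``window`` events is discarded;
    recordings with fewer than ``window`` events are excluded with a warning.
    Normalization statistics come from training windows only.
    """
    meta = cohort.set_index("participant_id")
    xs, ys, ids, rs = [], [], [], []
    for pid, seq in sequences.items():
        feats = event_features(seq, meta.loc[pid], type_codes)
        n_win = len(feats) // window
        if n_win == 0:
            warnings.warn(f"{pid}: fewer than {window} events, excluded")
            continue
        for w in range(n_win):
            xs.append(feats[w * window: (w + 1) * window])
            ys.append(meta.loc[pid, "group"])
            ids.append(pid)
            rs.append(roles[pid])
    if not xs:
        raise ValueError("no recording yielded a full window")
    X = np.asarray(xs)
    y = np.asarray(ys)
    ids = np.asarray(ids)
    rs = np.asarray(rs)
    train = rs == "train"
    if not train.any():
        raise ValueError("no training windows")
    mean = X[train].reshape(-1, X.shape[-1]).mean(axis=0)
    sd = X[train].reshape(-1, X.shape[-1]).std(axis=0)
    sd[sd == 0] = 1.0
    return EventWindowTensor(X=(X - mean) / sd, y=y, recording_id=ids,
                             role=rs, feature_mean=mean, feature_sd=sd,
                             window=window)


def augment_rotation(X: np.ndarray, y: np.ndarray,
                     shifts: tuple[int, ...] = (5, 10, 15),
                     ids: np.ndarray | None = None):
    """Augment training windows by circularly shifting the event order."""
    outs_x, outs_y, outs_i = [X], [y], [ids]
    for k in shifts:
        outs_x.append(np.roll(X, k, axis=1))
        outs_y.append(y)
        outs_i.append(ids)
    Xa = np.concatenate(outs_x)
    ya = np.concatenate(outs_y)
    if ids is None:
        return Xa, ya
    return Xa, ya, np.concatenate(outs_i)


@dataclass
class SequenceClassifierReport:
    split_accuracies: np.ndarray  # per-split recording-level accuracy
    split_f1: np.ndarray  # per-split recording-level F1 (AWS positive)
    seeds: list[int]

    @property
    def mean_accuracy(self) -> float:
        return float(self.split_accuracies.mean())

    @property
    def mean_f1(self) -> float:
        return float(np.nanmean(self.split_f1))


def _assign_roles(ids: np.ndarray, groups: np.ndarray, sizes: tuple[int, int, int],
                  rng: np.random.Generator) -> dict[str, str]:
    """Stratified recording-level train/test/val assignment."""
    n_train, n_test, n_val = sizes
    total = n_train + n_test + n_val
    roles: dict[str, str] = {}
    for g in np.unique(groups):
        g_ids = ids[groups == g].copy()
        rng.shuffle(g_ids)
        n = len(g_ids)
        k_test = max(1, int(round(n * n_test / total)))
        k_val = max(1, int(round(n * n_val / total)))
        for pid in g_ids[:k_test]:
            roles[pid] = "test"
        for pid in g_ids[k_test:k_test + k_val]:
            roles[pid] = "val"
        for pid in g_ids[k_test + k_val:]:
            roles[pid] = "train"
    return roles


def evaluate_sequence_classifier(sequences: dict[str, EventSequence],
                                 cohort: pd.DataFrame, n_splits: int = 5,
                                 window: int = 20,
                                 split_sizes: tuple[int, int, int] = (29, 4, 2),
                                 shifts: tuple[int, ...] = (5, 10, 15),
                                 seed: int = 0) -> SequenceClassifierReport:
    """Train the sequence classifier over ``n_splits`` recording-level splits.

    Windows are classified by a multilayer perceptron on the flattened
    (window x 9) feature block; window predictions are aggregated to a
    recording prediction by majority vote with ties toward AWS. Accuracy and
    F1 are reported at the recording level on the held-out test recordings.
    """
    meta = cohort.set_index("participant_id")
    ids = np.array([pid for pid in sequences])
    groups = meta.loc[ids, "group"].to_numpy()
    accs, f1s, seeds = [], [], []
    for s in range(n_splits):
        split_seed = seed + 1000 * s
        rng = np.random.default_rng(split_seed)
        roles = _assign_roles(ids, groups, split_sizes, rng)
        tensor = build_event_windows(sequences, cohort, roles, window=window)
        tr = tensor.role == "train"
        te = tensor.role == "test"
        Xtr, ytr = augment_rotation(tensor.X[tr], tensor.y[tr], shifts)
        n, w, f = Xtr.shape
        model = MLPClassifier(hidden_layer_sizes=(64,), max_iter=400,
                              random_state=split_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr.reshape(n, w * f), ytr)
        pred_win = model.predict(tensor.X[te].reshape(te.sum(), w * f))
        # majority vote per recording, ties toward AWS
        y_true, y_pred = [], []
        for pid in np.unique(tensor.recording_id[te]):
            sel = tensor.recording_id[te] == pid
            votes = pred_win[sel]
            n_aws = int((votes == POSITIVE_LABEL).sum())
            y_pred.append(POSITIVE_LABEL if n_aws * 2 >= votes.size else "AWNS")
            y_true.append(meta.loc[pid, "group"])
        accs.append(accuracy_score(y_true, y_pred))
        f1s.append(f1_score(y_true, y_pred, pos_label=POSITIVE_LABEL,
                            zero_division=0))
        seeds.append(split_seed)
    return SequenceClassifierReport(split_accuracies=np.array(accs),
                                    split_f1=np.array(f1s), seeds=seeds)
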