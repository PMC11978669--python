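"""Evaluation harness: confusion metrics, cross-validation, baselines and the
end-to-end detection pipeline.

The positive class is a real HFO (ripple or fast ripple); spikes, artifacts
and background crossings are negatives.  Supervised baselines (KNN, SVM with
three kernels) are scored with stratified five-fold cross-validation;
unsupervised clusterers are scored on the whole candidate set, since they
never see the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import cluster as cl
from . import cvae as cv
from . import ste as st
from . import tfm as tf
from .config import PipelineConfig
from .preprocess import IEEGRecording, downsample

POSITIVE_KINDS = ("ripple", "fast_ripple")
BACKGROUND = "background"


@dataclass
class ConfusionMetrics:
    """Counts plus Accuracy / Sensitivity / Specificity as percentages.

    Ratios with a zero denominator are reported as None (missing), never 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """Binary confusion counts; positive = real HFO."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    return ConfusionMetrics(tp=int(np.sum(pred & truth)),
                            tn=int(np.sum(~pred & ~truth)),
                            fp=int(np.sum(pred & ~truth)),
                            fn=int(np.sum(~pred & truth)))


@dataclass
class CVMetrics:
    """Fold-averaged metrics of a cross-validated classifier."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    folds: list[ConfusionMetrics] = field(default_factory=list)


def _mean_or_none(vals: list[float | None]) -> float | None:
    ok = [v for v in vals if v is not None]
    return float(np.mean(ok)) if ok else None


def five_fold_cv(X: np.ndarray, y: np.ndarray, make_estimator, seed: int = 0,
                 n_folds: int = 5) -> CVMetrics:
    """Stratified K-fold evaluation of a supervised binary classifier."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < n_folds:
        raise ValueError("each class needs at least one sample per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        est = make_estimator()
        est.fit(X[tr], y[tr])
        folds.append(confusion(est.predict(X[te]) == 1, y[te] == 1))
    return CVMetrics(accuracy=_mean_or_none([f.accuracy for f in folds]),
                     sensitivity=_mean_or_none([f.sensitivity for f in folds]),
                     specificity=_mean_or_none([f.specificity for f in folds]),
                     folds=folds)


SUPERVISED_MODELS = ("knn", "svm_linear", "svm_poly", "svm_rbf")
UNSUPERVISED_MODELS = ("meanshift", "kmeans", "gmm", "fcm")


def _make_supervised(model: str, seed: int = 0):
    if model == "knn":
        return lambda: KNeighborsClassifier(n_neighbors=5)
    kernels = {"svm_linear": "linear", "svm_poly": "poly", "svm_rbf": "rbf"}
    if model in kernels:
        return lambda: SVC(kernel=kernels[model], C=1.0, random_state=seed)
    raise ValueError(f"unknown supervised model {model!r}")


def supervised_baseline(X: np.ndarray, y: np.ndarray, model: str = "knn",
                        seed: int = 0) -> CVMetrics:
    """KNN (k=5) or SVM (named kernel) scored by stratified five-fold CV."""
    return five_fold_cv(X, y, _make_supervised(model, seed), seed=seed)


def _cluster_with(X: np.ndarray, method: str, K: int, seed: int,
                  fcm_m: float = 2.0) -> cl.ClusterResult:
    if method == "kmeans":
        return cl.kmeans_cluster(X, K=K, seed=seed)
    if method == "fcm":
        return cl.fcm_cluster(X, K=K, m=fcm_m, seed=seed)
    if method == "gmm":
        return cl.gmm_cluster(X, K=K, seed=seed)
    if method == "meanshift":
        return cl.meanshift_cluster(X, seed=seed, reduce_to=K)
    raise ValueError(f"unknown clustering method {method!r}")


def evaluate_unsupervised(X: np.ndarray, events: list[st.CandidateEvent],
                          truth_positive: np.ndarray, method: str = "fcm",
                          K: int = 4, seed: int = 0,
                          fcm_m: float = 2.0) -> tuple[ConfusionMetrics, cl.ClusterResult]:
    """Cluster the whole candidate set, assign classes by SC, score binary flags."""
    result = _cluster_with(np.asarray(X, dtype=float), method, K, seed, fcm_m)
    result = cl.assign_classes(result, events)
    return confusion(result.is_hfo(), truth_positive), result


# ---------------------------------------------------------------------------
# candidate/annotation matching

def match_candidates(candidates: list[st.CandidateEvent], annotations: pd.DataFrame,
                     fs: float, tol_s: float = 0.075) -> np.ndarray:
    """Label each candidate with the nearest annotation kind (or background).

    Also sets ``true_kind`` in place.  Returns the per-candidate truth kinds.
    """
    tol = int(round(tol_s * fs))
    kinds = []
    for c in candidates:
        sub = annotations[annotations["channel"] == c.channel]
        kind = BACKGROUND
        if len(sub):
            d = (sub["center_sample"] - c.center_sample).abs()
            i = d.idxmin()
            if d.loc[i] <= tol:
                kind = str(sub.loc[i, "kind"])
        c.true_kind = kind
        kinds.append(kind)
    return np.asarray(kinds)


def detector_recall(candidates: list[st.CandidateEvent], annotations: pd.DataFrame,
                    fs: float, kinds: tuple[str, ...] = POSITIVE_KINDS,
                    tol_s: float = 0.075) -> float | None:
    """Fraction of annotated events (of the given kinds) hit by a candidate."""
    tol = int(round(tol_s * fs))
    sub = annotations[annotations["kind"].isin(kinds)]
    if not len(sub):
        return None
    centers: dict[int, np.ndarray] = {}
    for ch in set(int(c.channel) for c in candidates):
        centers[ch] = np.asarray([c.center_sample for c in candidates
                                  if c.channel == ch])
    hit = 0
    for _, row in sub.iterrows():
        cs = centers.get(int(row["channel"]), np.asarray([]))
        if cs.size and np.min(np.abs(cs - row["center_sample"])) <= tol:
            hit += 1
    return hit / len(sub)


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class DetectionReport:
    """Per-candidate table plus (when ground truth exists) binary metrics."""

    events: pd.DataFrame
    metrics: ConfusionMetrics | None = None
    ste_recall: float | None = None

    @property
    def n_candidates(self) -> int:
        return len(self.events)


@dataclass
class PipelineResult:
    candidates: list[st.CandidateEvent]
    rtfms: np.ndarray | None
    tfm64s: np.ndarray | None
    reconstructed: np.ndarray | None
    cluster: cl.ClusterResult | None
    model: cv.CVAE | None
    loss_history: np.ndarray | None
    report: DetectionReport


def _empty_report() -> DetectionReport:
    cols = ["channel", "center_sample", "cluster_id", "class", "SC_hz", "is_hfo",
            "true_kind"]
    return DetectionReport(events=pd.DataFrame(columns=cols))


def run_pipeline(rec: IEEGRecording, config: PipelineConfig | None = None,
                 annotations: pd.DataFrame | None = None) -> PipelineResult:
    """Full detector: preprocess -> STE -> R-TFM -> CVAE -> cluster -> assign.

    Returns every intermediate product so ablations can reuse them.  With
    annotations given, binary confusion metrics over the candidates and the
    detector's event-level recall are included in the report.
    """
    config = config or PipelineConfig()
    if rec.fs_hz != config.target_fs:
        rec = downsample(rec, config.target_fs)
    candidates = st.detect_recording(rec, k=config.ste_k, frame_ms=config.ste_frame_ms,
                                     min_consecutive=config.ste_min_consecutive,
                                     trim_fraction=config.ste_trim_fraction,
                                     filter_mode=config.filter_mode)
    if not candidates:
        return PipelineResult(candidates=[], rtfms=None, tfm64s=None,
                              reconstructed=None, cluster=None, model=None,
                              loss_history=None, report=_empty_report())
    truth_kind = None
    if annotations is not None:
        truth_kind = match_candidates(candidates, annotations, rec.fs_hz,
                                      config.match_tol_s)
    rtfms, tfm64s = tf.imaging_features([c.raw_window for c in candidates],
                                        rec.fs_hz, gamma=config.tfm_gamma,
                                        beta=config.tfm_beta, voices=config.tfm_voices,
                                        freq_range=config.tfm_freq_range)
    n = len(candidates)
    cvae_cfg = replace(config.cvae,
                       batch_size=min(config.cvae.batch_size, max(1, n // 2)))
    model, history = cv.train(rtfms, cvae_cfg)
    recon = cv.reconstruct(rtfms, model)
    result = _cluster_with(cl.vectorize_stack(recon), config.cluster_method,
                           config.cluster_k, config.cluster_seed, config.fcm_m)
    result = cl.assign_classes(result, candidates)
    sc = np.asarray([cl.spectral_centroid(c.filtered_window, c.fs_hz)
                     for c in candidates])
    events = pd.DataFrame({
        "channel": [c.channel for c in candidates],
        "center_sample": [c.center_sample for c in candidates],
        "cluster_id": result.labels,
        "class": result.classes(),
        "SC_hz": sc,
        "is_hfo": result.is_hfo(),
        "true_kind": truth_kind if truth_kind is not None else [None] * n,
    })
    metrics = recall = None
    if annotations is not None:
        truth_pos = np.isin(truth_kind, POSITIVE_KINDS)
        metrics = confusion(result.is_hfo(), truth_pos)
        recall = detector_recall(candidates, annotations, rec.fs_hz,
                                 tol_s=config.match_tol_s)
    report = DetectionReport(events=events, metrics=metrics, ste_recall=recall)
    return PipelineResult(candidates=candidates, rtfms=rtfms, tfm64s=tfm64s,
                          reconstructed=recon, cluster=result, model=model,
                          loss_history=history, report=report)


def save_report(report: DetectionReport, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.events.to_csv(out / "events.csv", index=False)
    payload = {"n_candidates": report.n_candidates, "ste_recall": report.ste_recall}
    if report.metrics is not None:
        payload.update(report.metrics.as_dict())
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# experiment grid (structure of the comparison tables)

def run_experiment_grid(representations: dict[str, np.ndarray],
                        events: list[st.CandidateEvent], truth_kind: np.ndarray,
                        supervised: tuple[str, ...] = SUPERVISED_MODELS,
                        unsupervised: tuple[str, ...] = UNSUPERVISED_MODELS,
                        seed: int = 0, K: int = 4) -> pd.DataFrame:
    """Score every (representation, model) cell.

    ``representations`` maps a name (e.g. TFM / RTFM / reconstructed_RTFM) to
    an (n, d) feature matrix aligned with ``events``.  Supervised models see
    binary labels (HFO=1) under five-fold CV; unsupervised models cluster the
    features and are scored after SC class assignment.
    """
    truth_pos = np.isin(truth_kind, POSITIVE_KINDS)
    rows = []
    for rep, X in representations.items():
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) != len(events):
            raise ValueError(f"representation {rep!r} must be (n_events, d)")
        for model in supervised:
            m = supervised_baseline(X, truth_pos.astype(int), model, seed=seed)
            rows.append({"representation": rep, "model": model,
                         "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                         "specificity": m.specificity})
        for model in unsupervised:
            m, _ = evaluate_unsupervised(X, events, truth_pos, method=model,
                                         K=K, seed=seed)
            rows.append({"representation": rep, "model": model,
                         "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                         "specificity": m.specificity})
    return pd.DataFrame(rows)


def latent_epoch_sweep(rtfms: np.ndarray, events: list[st.CandidateEvent],
                       truth_kind: np.ndarray,
                       latent_dims: tuple[int, ...] = (10, 20, 30, 40, 50),
                       epoch_grid: tuple[int, ...] = (100, 150, 200),
                       base_config: cv.CVAEConfig | None = None,
                       method: str = "fcm", seed: int = 0) -> pd.DataFrame:
    """FCM accuracy as a function of latent size and training epochs.

    For each latent size one model is trained up to max(epoch_grid) epochs
    and snapshot-evaluated at each grid epoch (identical to training that
    long, since the update sequence is seed-deterministic).
    """
    truth_pos = np.isin(truth_kind, POSITIVE_KINDS)
    base = base_config or cv.CVAEConfig()
    rows = []
    for l in latent_dims:
        cfg = replace(base, latent_dim=l, epochs=max(epoch_grid))

        def snapshot(epoch, model, l=l):
            if epoch not in epoch_grid:
                return
            recon = cv.reconstruct(rtfms, model)
            m, _ = evaluate_unsupervised(cl.vectorize_stack(recon), events,
                                         truth_pos, method=method, seed=seed)
            rows.append({"latent_dim": l, "epochs": epoch, "accuracy": m.accuracy,
                         "sensitivity": m.sensitivity, "specificity": m.specificity})

        cv.train(rtfms, cfg, on_epoch=snapshot)
    return pd.DataFrame(rows).sort_values(["latent_dim", "epochs"]).reset_index(drop=True)
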