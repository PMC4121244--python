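"""Candidate pairing, swallowing-parameter extraction and classification.

An EMG burst coinciding with a conforming bioimpedance valley is a *potential*
swallow — many other movements (chewing, neck tensing during a head movement)
also produce that coincidence. The second stage is therefore a trained
max-margin discriminator over swallowing-related parameters:

* ``max_laryngeal_elevation``  = BI_min - BI_start (ohm, negative),
* ``speed_laryngeal_elevation`` = (BI_min - BI_start) / (t(BI_min) - t(BI_start)),
* ``duration_preparation``      = t(EMG_start) - t(BI_start) (s, negative when
  the muscle burst leads the impedance drop, as it does in a swallow),
* ``extent_laryngeal_closure``  = t(BI_end) - t(BI_start) (s),

plus auxiliary shape features of the burst and the valley.

The public surface follows the scikit-learn estimator protocol:
:class:`SwallowClassifier` is a fit/predict classifier over feature matrices,
:class:`SwallowDetector` wraps the full recording -> events pipeline. The
module-level functions are thin wrappers over these estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .bi import BIValley, ValleyConditions, detect_bi_valleys, pla_approximate
from .emg import DoubleThresholdParams, EMGActivitySegment, detect_emg_activity
from .io import EMBIRecording, EventAnnotation, PipelineConfig, ValidationError
from .preprocessing import FilterSpec, apply_filter, emg_envelope, smooth_bi

__all__ = [
    "SwallowCandidate",
    "SwallowParameters",
    "DetectedEvent",
    "SwallowClassifier",
    "SwallowDetector",
    "pair_candidates",
    "extract_features",
    "feature_matrix",
    "train_classifier",
    "classify",
    "detect_swallows",
    "save_model",
    "load_model",
]

LABEL_SWALLOW = "swallow"
LABEL_NONSWALLOW = "nonswallow"


@dataclass(frozen=True)
class SwallowCandidate:
    """A paired EMG burst and bioimpedance valley from one recording."""

    emg: EMGActivitySegment
    valley: BIValley
    recording_ref: str = ""


@dataclass(frozen=True)
class SwallowParameters:
    """Feature vector of one candidate; field order defines the model arity."""

    max_laryngeal_elevation: float  # ohm, negative
    speed_laryngeal_elevation: float  # ohm/s, negative
    duration_preparation: float  # s, negative when EMG leads
    extent_laryngeal_closure: float  # s
    emg_duration_s: float
    emg_peak_mv: float
    emg_rms_mv: float
    descent_duration_s: float
    ascent_duration_s: float
    ascent_slope_ohm_s: float
    emg_to_valley_latency_s: float  # t_bi_start - t_emg_start

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(SwallowParameters))


@dataclass(frozen=True)
class DetectedEvent:
    """A classified candidate: ``decision`` is consistent with ``score``."""

    candidate: SwallowCandidate
    params: SwallowParameters
    decision: str
    score: float


def pair_candidates(
    segments: list[EMGActivitySegment],
    valleys: list[BIValley],
    grace_s: float = 0.5,
) -> list[SwallowCandidate]:
    """Pair EMG bursts with valleys under the physiological precedence rule.

    A pair qualifies iff the burst starts no later than the impedance drop
    (EMG activity always precedes the drop in a swallow) and the drop starts
    no later than ``grace_s`` after the burst ends. Each burst contributes at
    most one candidate — the deepest qualifying valley — and each valley is
    used at most once; bursts are served in temporal order.
    """
    used: set[int] = set()
    out: list[SwallowCandidate] = []
    for seg in segments:
        best: int | None = None
        for vi, v in enumerate(valleys):
            if vi in used:
                continue
            if seg.t_start <= v.t_start <= seg.t_end + grace_s:
                if best is None or v.depth < valleys[best].depth:
                    best = vi
        if best is not None:
            used.add(best)
            out.append(SwallowCandidate(emg=seg, valley=valleys[best]))
    return out


def extract_features(cand: SwallowCandidate) -> SwallowParameters:
    v, e = cand.valley, cand.emg
    descent = v.t_min - v.t_start
    if descent <= 0:
        raise ValidationError("candidate valley has non-positive descent duration")
    return SwallowParameters(
        max_laryngeal_elevation=v.depth,
        speed_laryngeal_elevation=v.depth / descent,
        duration_preparation=e.t_start - v.t_start,
        extent_laryngeal_closure=v.t_end - v.t_start,
        emg_duration_s=e.t_end - e.t_start,
        emg_peak_mv=e.peak_mv,
        emg_rms_mv=e.rms_mv,
        descent_duration_s=descent,
        ascent_duration_s=v.t_end - v.t_min,
        ascent_slope_ohm_s=v.ascent_slope,
        emg_to_valley_latency_s=v.t_start - e.t_start,
    )


def feature_matrix(params: list[SwallowParameters]) -> np.ndarray:
    if not params:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([p.to_vector() for p in params])


class SwallowClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin RBF support-vector discriminator with stored normalization.

    Features are z-scored with statistics fitted on the training set; the RBF
    width defaults to the median heuristic (``gamma = 1 / (2 m^2)`` with ``m``
    the median pairwise distance between standardized training points). The
    decision is ``swallow`` iff the signed margin exceeds ``threshold``.

    Fitted attributes: ``scaler_``, ``svc_``, ``gamma_``, ``classes_``,
    ``n_pos_``, ``n_neg_``, ``n_features_in_``.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: float | str = "median",
        threshold: float = 0.0,
        random_state: int | None = None,
    ):
        self.C = C
        self.gamma = gamma
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValidationError("X must be 2-D with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValidationError(
                f"need exactly two classes, got {list(classes)}"
            )
        if counts.min() < 2:
            raise ValidationError("need at least 2 examples per class")
        # np.unique sorts, so the positive class is classes_[1]:
        # 'swallow' > 'nonswallow', 1 > 0
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.gamma_ = self._resolve_gamma(Xs)
        self.svc_ = SVC(
            C=self.C, kernel="rbf", gamma=self.gamma_, random_state=self.random_state
        ).fit(Xs, y)
        pos = y == classes[1]
        self.n_pos_ = int(pos.sum())
        self.n_neg_ = int((~pos).sum())
        return self

    def _resolve_gamma(self, Xs: np.ndarray) -> float:
        if self.gamma != "median":
            return float(self.gamma)
        rng = np.random.default_rng(self.random_state)
        sub = Xs
        if len(Xs) > 512:
            sub = Xs[rng.choice(len(Xs), 512, replace=False)]
        d = pairwise_distances(sub)
        m = float(np.median(d[np.triu_indices_from(d, k=1)]))
        if m <= 0:
            return 1.0 / Xs.shape[1]
        return 1.0 / (2.0 * m * m)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.svc_.decision_function(self.scaler_.transform(X))

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score > self.threshold, self.classes_[1], self.classes_[0])


class SwallowDetector(BaseEstimator):
    """End-to-end two-stage detector over :class:`EMBIRecording` objects.

    ``fit`` runs the stage-1 coincidence filter on annotated training
    recordings, labels each candidate by whether its valley minimum falls in
    an annotated swallow interval, and trains the classifier. ``predict``
    returns one :class:`DetectedEvent` per stage-1 candidate, sorted by the
    valley-minimum landmark.
    """

    def __init__(
        self,
        config: PipelineConfig | None = None,
        random_state: int | None = None,
    ):
        self.config = config
        self.random_state = random_state

    @property
    def _cfg(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    # -- stage 1 -----------------------------------------------------------
    def preprocess(self, rec: EMBIRecording) -> tuple[np.ndarray, np.ndarray]:
        """Return (EMG envelope, smoothed bioimpedance)."""
        cfg = self._cfg
        emg_f = apply_filter(
            rec.emg,
            rec.fs,
            FilterSpec(
                "highpass",
                cfg.emg_highpass_hz,
                cfg.emg_highpass_order,
                cfg.zero_phase,
            ),
        )
        env = emg_envelope(
            emg_f,
            rec.fs,
            cfg.envelope_lowpass_hz,
            cfg.envelope_lowpass_order,
            cfg.zero_phase,
        )
        bi_s = smooth_bi(
            rec.bi, rec.fs, cfg.bi_lowpass_hz, cfg.bi_lowpass_order, cfg.zero_phase
        )
        return env, bi_s

    def stage1_candidates(self, rec: EMBIRecording) -> list[SwallowCandidate]:
        """EMG-burst / BI-valley coincidence filter, before classification."""
        cfg = self._cfg
        env, bi_s = self.preprocess(rec)
        t0 = float(rec.t[0])
        segments = detect_emg_activity(
            env,
            rec.fs,
            DoubleThresholdParams(
                baseline_window_s=cfg.baseline_window_s,
                k_on=cfg.k_on,
                k_off=cfg.k_off,
                min_above_s=cfg.min_above_s,
                min_below_s=cfg.min_below_s,
                min_duration_s=cfg.min_duration_s,
                max_gap_merge_s=cfg.max_gap_merge_s,
            ),
            t0=t0,
        )
        pla = pla_approximate(bi_s, rec.fs, cfg.pla_epsilon_ohm, cfg.pla_piece_s)
        valleys = detect_bi_valleys(
            pla,
            bi_s,
            rec.fs,
            ValleyConditions(
                min_depth_ohm=cfg.min_depth_ohm,
                min_total_s=cfg.min_total_s,
                max_total_s=cfg.max_total_s,
                min_descent_s=cfg.min_descent_s,
                max_descent_slope_ohm_s=cfg.max_descent_slope_ohm_s,
            ),
            flat_slope_ohm_s=cfg.flat_slope_ohm_s,
            max_flat_bottom_s=cfg.max_flat_bottom_s,
            t0=t0,
        )
        cands = pair_candidates(segments, valleys, cfg.grace_s)
        return [
            SwallowCandidate(c.emg, c.valley, recording_ref=rec.subject_id)
            for c in cands
        ]

    # -- stage 2 -----------------------------------------------------------
    def fit(
        self,
        recordings: list[EMBIRecording],
        annotations: list[list[EventAnnotation]],
    ):
        if len(recordings) != len(annotations):
            raise ValidationError("one annotation list per recording required")
        X_rows: list[np.ndarray] = []
        y: list[str] = []
        for rec, events in zip(recordings, annotations):
            swallow_ivals = [e for e in events if e.label == LABEL_SWALLOW]
            for cand in self.stage1_candidates(rec):
                X_rows.append(extract_features(cand).to_vector())
                inside = any(iv.contains(cand.valley.t_min) for iv in swallow_ivals)
                y.append(LABEL_SWALLOW if inside else LABEL_NONSWALLOW)
        if not X_rows:
            raise ValidationError("no stage-1 candidates found in training data")
        cfg = self._cfg
        self.classifier_ = SwallowClassifier(
            C=cfg.svm_c,
            gamma=cfg.svm_gamma,
            threshold=cfg.decision_threshold,
            random_state=self.random_state,
        ).fit(np.vstack(X_rows), np.array(y))
        return self

    def predict(self, rec: EMBIRecording) -> list[DetectedEvent]:
        check_is_fitted(self, "classifier_")
        cands = sorted(self.stage1_candidates(rec), key=lambda c: c.valley.t_min)
        if not cands:
            return []
        params = [extract_features(c) for c in cands]
        scores = self.classifier_.decision_function(feature_matrix(params))
        thr = self.classifier_.threshold
        return [
            DetectedEvent(
                candidate=c,
                params=p,
                decision=LABEL_SWALLOW if s > thr else LABEL_NONSWALLOW,
                score=float(s),
            )
            for c, p, s in zip(cands, params, scores)
        ]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_classifier(
    features: list[SwallowParameters],
    labels: list[str],
    hyper: dict | None = None,
    seed: int | None = 0,
) -> SwallowClassifier:
    """Train the stage-2 discriminator on extracted parameter vectors."""
    hyper = dict(hyper or {})
    clf = SwallowClassifier(
        C=hyper.get("C", 1.0),
        gamma=hyper.get("gamma", "median"),
        threshold=hyper.get("threshold", 0.0),
        random_state=seed,
    )
    return clf.fit(feature_matrix(features), np.array(labels))


def classify(
    model: SwallowClassifier, features: SwallowParameters
) -> tuple[str, float]:
    """Score one candidate; returns ``(decision, signed margin)``."""
    score = float(model.decision_function(features.to_vector()[None, :])[0])
    decision = LABEL_SWALLOW if score > model.threshold else LABEL_NONSWALLOW
    return decision, score


def detect_swallows(
    rec: EMBIRecording,
    model: SwallowClassifier,
    cfg: PipelineConfig | None = None,
) -> list[DetectedEvent]:
    """Run the full two-stage pipeline on one recording with a trained model."""
    det = SwallowDetector(config=cfg)
    det.classifier_ = model
    return det.predict(rec)


# ---------------------------------------------------------------------------
# model persistence (versioned, self-describing key-value container)
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(detector: SwallowDetector, path) -> None:
    check_is_fitted(detector, "classifier_")
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "feature_names": list(FEATURE_NAMES),
            "config": detector._cfg,
            "classifier": detector.classifier_,
        },
        path,
    )


def load_model(path) -> SwallowDetector:
    blob = joblib.load(path)
    if blob.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format {blob.get('format_version')!r}"
        )
    if list(blob["feature_names"]) != list(FEATURE_NAMES):
        raise ValidationError("model was trained with a different feature list")
    det = SwallowDetector(config=blob["config"])
    det.classifier_ = blob["classifier"]
    return det
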