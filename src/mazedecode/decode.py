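"""Per-variable binary decoding with calibrated probability outputs.

Each of the 73 variables, in each ROI, is decoded by a linear max-margin
classifier (SVM, regularization C = 1) trained on voxel patterns under
leave-one-trial-out cross-validation.  The classifier's signed distance
from the separating hyperplane (the decision value, DV) is mapped to a
predicted probability of the positive class by a 4-parameter sigmoid

    y = c + (1 - c - d) / (1 + exp((x - a) / b))

fitted to binned (mean DV, mean label probability) pairs from the training
folds.  Classification accuracy is reported bias-corrected through signal
detection theory: d' = z(H) - z(F) and P = Phi(d'/2), so that a classifier
exploiting only class imbalance scores exactly 50%.

Binarization rules per information source (thresholds always derived from
the training trials of the current fold and re-used on the held-out trial):

* quadrant     — pairwise labels; time points in neither quadrant excluded;
* visibility   — visible (> 0) vs not, "no" time points subsampled to keep
                 the no:yes ratio at most 3:1;
* motion       — lower third of values (turning right) vs upper third
                 (turning left); middle third excluded from training;
* reward       — cue vs no cue, with the same 3:1 cap;
* scene_rms / scene_temp — below vs above the median of all training
                 values of that scene square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import norm

from mazedecode.features import VariableSeries
from mazedecode.signal_prep import AlignedTrial

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0
CAP_RATIO = 3.0
CALIBRATION_BIN = 20
CALIBRATION_MIN_PARTIAL = 10


class SkipVariable(Exception):
    """Raised when a variable cannot be binarized (e.g. a degenerate split)."""


@dataclass
class BinaryLabeling:
    """Binary labels (+1/-1) with a training-eligibility mask."""

    labels: np.ndarray
    include: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.include = np.asarray(self.include, dtype=bool)
        if set(np.unique(self.labels[self.include])) - {-1, 1}:
            raise ValueError("labels must be +1/-1 on included time points")


class Binarizer:
    """Fold-local binarization: fit thresholds on training trials, apply to any
    trial.  The 3:1 majority cap is applied only when producing *training*
    labelings and subsamples the "no" class uniformly at random."""

    def __init__(self, source: str, rng: np.random.Generator | None = None,
                 cap_ratio: float = CAP_RATIO):
        self.source = source
        self.rng = rng or np.random.default_rng(0)
        self.cap_ratio = cap_ratio
        self._median: float | None = None
        self._tertiles: tuple[float, float] | None = None

    def fit(self, train_series: Sequence[VariableSeries]) -> "Binarizer":
        vals = np.concatenate([s.values for s in train_series])
        if self.source == "motion":
            # lower third = negative values (turning right), upper third =
            # positive (turning left); with many straight-ahead zeros the
            # tertile boundaries collapse onto 0, leaving the sign split
            lo, hi = np.quantile(vals, [1 / 3, 2 / 3])
            self._tertiles = (float(min(lo, 0.0)), float(max(hi, 0.0)))
        elif self.source in ("scene_rms", "scene_temp"):
            med = float(np.median(vals))
            if np.all(vals == med):
                raise SkipVariable(f"constant {self.source} square; median split degenerate")
            self._median = med
        return self

    def transform(self, series: VariableSeries, training: bool = False) -> BinaryLabeling:
        v = series.values
        if self.source == "quadrant":
            labels = np.where(v == 1.0, 1, -1)
            include = series.valid & ((v == 1.0) | (v == 0.0))
            rule = "quadrant-pair"
        elif self.source == "visibility":
            labels = np.where(v > 0, 1, -1)
            include = np.ones(len(v), dtype=bool)
            rule = "visible-vs-not, 3:1 cap"
        elif self.source == "reward":
            labels = np.where(v >= 0.5, 1, -1)
            include = np.ones(len(v), dtype=bool)
            rule = "cue-vs-no-cue, 3:1 cap"
        elif self.source == "motion":
            if self._tertiles is None:
                raise RuntimeError("motion binarizer must be fitted first")
            lo, hi = self._tertiles
            labels = np.zeros(len(v), dtype=int)
            labels[(v <= lo) & (v < 0)] = -1
            labels[(v >= hi) & (v > 0)] = 1
            include = labels != 0
            labels = np.where(labels == 0, -1, labels)
            rule = "tertile left-vs-right"
        elif self.source in ("scene_rms", "scene_temp"):
            if self._median is None:
                raise RuntimeError(f"{self.source} binarizer must be fitted first")
            labels = np.where(v >= self._median, 1, -1)
            include = np.ones(len(v), dtype=bool)
            rule = "training-median split"
        else:
            raise ValueError(f"unknown source {self.source!r}")

        if training and self.source in ("visibility", "reward"):
            include = self._cap_majority(labels, include)
        return BinaryLabeling(labels, include, rule)

    def _cap_majority(self, labels: np.ndarray, include: np.ndarray) -> np.ndarray:
        pos = include & (labels == 1)
        neg = include & (labels == -1)
        limit = int(self.cap_ratio * pos.sum())
        if neg.sum() > limit:
            idx = np.flatnonzero(neg)
            keep = self.rng.choice(idx, size=limit, replace=False) if limit else idx[:0]
            include = include.copy()
            include[idx] = False
            include[keep] = True
        return include


# ---------------------------------------------------------------------------
# calibration sigmoid


@dataclass
class CalibrationSigmoid:
    """The 4-parameter DV-to-probability curve
    y = c + (1 - c - d) / (1 + exp((x - a) / b)); outputs clipped to [0, 1].

    Note that with b > 0 the curve decreases with x; positive decision
    values mapping to the positive class corresponds to b < 0.

    ``x_lo``/``x_hi`` bound the DV domain the curve was fitted on; outside
    it the boundary value is extrapolated as a constant (the fit carries no
    information beyond the observed calibration bins).
    """

    a: float
    b: float
    c: float
    d: float
    x_lo: float = -np.inf
    x_hi: float = np.inf

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("scale parameter b must be nonzero")

    def __call__(self, dv: np.ndarray | float) -> np.ndarray:
        x = np.clip(np.asarray(dv, dtype=float), self.x_lo, self.x_hi)
        with np.errstate(over="ignore"):
            y = self.c + (1.0 - self.c - self.d) / (1.0 + np.exp((x - self.a) / self.b))
        return np.clip(y, 0.0, 1.0)


@dataclass
class _LinearCalibration:
    """Fallback DV map: clipped line through the two extreme calibration bins."""

    slope: float
    intercept: float

    def __call__(self, dv: np.ndarray | float) -> np.ndarray:
        return np.clip(self.slope * np.asarray(dv, dtype=float) + self.intercept, 0.0, 1.0)


def _sigmoid(x, a, b, c, d):
    return c + (1.0 - c - d) / (1.0 + np.exp(np.clip((x - a) / b, -500, 500)))


def calibration_bins(dvs: np.ndarray, labels: np.ndarray,
                     bin_size: int = CALIBRATION_BIN,
                     min_partial: int = CALIBRATION_MIN_PARTIAL) -> tuple[np.ndarray, np.ndarray]:
    """Bin training points by sorted DV: consecutive bins of ``bin_size``
    time points; a final partial bin is kept only if it holds at least
    ``min_partial`` points.  Returns (mean DV, mean positive-probability)
    per bin."""
    order = np.argsort(dvs, kind="stable")
    dv_s = dvs[order]
    p_s = (labels[order] == 1).astype(float)
    xs, ys = [], []
    for start in range(0, len(dv_s), bin_size):
        chunk = slice(start, start + bin_size)
        n = len(dv_s[chunk])
        if n < bin_size and n < min_partial:
            break
        xs.append(dv_s[chunk].mean())
        ys.append(p_s[chunk].mean())
    return np.asarray(xs), np.asarray(ys)


def calibrate(dvs: np.ndarray, labels: np.ndarray,
              bin_size: int = CALIBRATION_BIN,
              min_partial: int = CALIBRATION_MIN_PARTIAL):
    """Fit the DV-to-probability sigmoid from training decision values.

    Least-squares fit of the 4-parameter sigmoid to the binned calibration
    curve, seeded at a = median DV, |b| = DV range / 10 (sign from the
    DV/probability trend), c = d = 0.05, with c, d bounded in [0, 1].
    Falls back to a clipped linear map through the two extreme bins when
    the fit fails.
    """
    dvs = np.asarray(dvs, dtype=float)
    labels = np.asarray(labels)
    x, y = calibration_bins(dvs, labels, bin_size, min_partial)
    if len(x) < 2:
        raise ValueError(f"only {len(x)} calibration bins; need at least 2")
    span = max(x.max() - x.min(), 1e-6)
    trend = np.polyfit(x, y, 1)[0]
    b0 = -span / 10 if trend >= 0 else span / 10
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", (OptimizeWarning, RuntimeWarning))
            popt, _ = curve_fit(
                _sigmoid, x, y,
                p0=[float(np.median(dvs)), b0, 0.05, 0.05],
                bounds=([-np.inf, -np.inf, 0.0, 0.0], [np.inf, np.inf, 1.0, 1.0]),
                maxfev=5000,
            )
        if abs(popt[1]) < 1e-12:
            raise RuntimeError("degenerate scale")
        # parsimony guard: when the DV carries no information, least squares
        # happily fits a step through one extreme noise bin; keep the sigmoid
        # only if it clearly beats the flat base-rate model
        sse_fit = float(((y - _sigmoid(x, *popt)) ** 2).sum())
        sse_flat = float(((y - y.mean()) ** 2).sum())
        if sse_flat > 0 and sse_fit > 0.8 * sse_flat:
            return _LinearCalibration(0.0, float(y.mean()))
        return CalibrationSigmoid(*[float(p) for p in popt],
                                  x_lo=float(x.min()), x_hi=float(x.max()))
    except (RuntimeError, ValueError):
        if x[-1] == x[0]:
            return _LinearCalibration(0.0, float(y.mean()))
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        return _LinearCalibration(float(slope), float(y[0] - slope * x[0]))


# ---------------------------------------------------------------------------
# classifier


@dataclass
class VariableDecoder:
    """A trained linear margin classifier plus its calibration curve."""

    w: np.ndarray
    b: float
    variable_id: str = ""
    roi: str = ""
    calibration: CalibrationSigmoid | _LinearCalibration | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.w):
            raise ValueError(f"{X.shape[1]} voxels vs decoder trained on {len(self.w)}")
        return X @ self.w + self.b

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) >= 0, 1, -1)


@dataclass
class PredictionSeries:
    """Calibrated per-TR predictions for one held-out trial."""

    trial_index: int
    values: np.ndarray  # in [0, 1]
    dvs: np.ndarray


def decoder_to_json(decoder: "VariableDecoder", path: str | Path | None = None) -> str:
    """Serialize a trained decoder (weights, bias, calibration) to JSON."""
    import json

    cal = decoder.calibration
    if isinstance(cal, CalibrationSigmoid):
        cal_payload = {"kind": "sigmoid", "a": cal.a, "b": cal.b, "c": cal.c,
                       "d": cal.d, "x_lo": cal.x_lo, "x_hi": cal.x_hi}
    elif isinstance(cal, _LinearCalibration):
        cal_payload = {"kind": "linear", "slope": cal.slope, "intercept": cal.intercept}
    else:
        cal_payload = None
    payload = {"w": decoder.w.tolist(), "b": decoder.b,
               "variable_id": decoder.variable_id, "roi": decoder.roi,
               "calibration": cal_payload}
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def decoder_from_json(source: str | Path) -> "VariableDecoder":
    import json

    p = Path(str(source))
    raw = json.loads(p.read_text() if p.exists() else str(source))
    cal = raw.get("calibration")
    calibration = None
    if cal is not None:
        if cal["kind"] == "sigmoid":
            calibration = CalibrationSigmoid(cal["a"], cal["b"], cal["c"], cal["d"],
                                             cal["x_lo"], cal["x_hi"])
        else:
            calibration = _LinearCalibration(cal["slope"], cal["intercept"])
    return VariableDecoder(np.asarray(raw["w"], dtype=float), float(raw["b"]),
                           raw["variable_id"], raw["roi"], calibration)


def predictions_to_tsv(results: dict[str, "LotoResult"], path: str | Path) -> None:
    """Export per-fold predictions as TSV (trial, variable, tr, dv, predicted)."""
    with open(path, "w") as fh:
        fh.write("trial\tvariable\ttr\tdv\tpredicted\n")
        for vid, res in results.items():
            for pred in res.predictions:
                for t, (dv, v) in enumerate(zip(pred.dvs, pred.values)):
                    fh.write(f"{pred.trial_index}\t{vid}\t{t}\t{dv:.6g}\t{v:.6g}\n")


def _default_classifier():
    from sklearn.svm import SVC

    # iteration cap bounds non-separable (noise) fits, which otherwise grind
    # toward a solution no more informative than the capped one
    return SVC(kernel="linear", C=DEFAULT_C, max_iter=10_000)


def train_decoder(
    X: np.ndarray,
    labeling: BinaryLabeling,
    variable_id: str = "",
    roi: str = "",
    classifier_factory: Callable | None = None,
) -> VariableDecoder:
    """Fit the linear max-margin classifier on the included time points.

    The classifier is injectable (any sklearn-style estimator exposing
    ``coef_`` and ``intercept_`` after ``fit``); default is a linear SVM
    with C = 1.  The optimization problem is convex, so the result is
    deterministic given the data.
    """
    Xt = np.asarray(X, dtype=float)[labeling.include]
    yt = labeling.labels[labeling.include]
    classes, counts = np.unique(yt, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 time points per class")
    clf = (classifier_factory or _default_classifier)()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Solver terminated early")
        clf.fit(Xt, yt)
    w = np.asarray(clf.coef_, dtype=float).ravel()
    b = float(np.asarray(clf.intercept_).ravel()[0])
    # sklearn orders classes [-1, +1]; coef_ already points toward +1
    return VariableDecoder(w=w, b=b, variable_id=variable_id, roi=roi)


def predict_series(decoder: VariableDecoder, heldout_X: np.ndarray,
                   trial_index: int = 0) -> PredictionSeries:
    """Map the held-out trial's decision values through the calibration."""
    if decoder.calibration is None:
        raise ValueError("decoder has no calibration; run calibrate() first")
    dvs = decoder.decision_values(heldout_X)
    return PredictionSeries(trial_index, np.asarray(decoder.calibration(dvs)), dvs)


# ---------------------------------------------------------------------------
# accuracy


@dataclass
class AccuracyStats:
    """Hit/false-alarm proportions with d' and corrected proportion correct."""

    H: float
    F: float
    dprime: float
    P: float
    n_pos: int = 0
    n_neg: int = 0


def corrected_accuracy(H: float, F: float, n: int | None = None,
                       n_pos: int = 0, n_neg: int = 0) -> AccuracyStats:
    """Signal-detection corrected accuracy: d' = z(H) - z(F), P = Phi(d'/2).

    Proportions of exactly 0 or 1 are clipped to 1/(2n) resp. 1 - 1/(2n)
    before the z-transform, with a single n (the number of scored time
    points) shared by H and F so that H = F stays H = F after clipping —
    an always-majority classifier at any prevalence then scores exactly
    P = 0.5.
    """
    if not (0 <= H <= 1 and 0 <= F <= 1):
        raise ValueError("H and F must be proportions in [0, 1]")
    Hc, Fc = H, F
    if H in (0.0, 1.0) or F in (0.0, 1.0):
        if n is None:
            n = max(n_pos + n_neg, 2)
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        Hc = min(max(H, lo), hi)
        Fc = min(max(F, lo), hi)
    dprime = float(norm.ppf(Hc) - norm.ppf(Fc))
    P = float(norm.cdf(dprime / 2.0))
    return AccuracyStats(H=H, F=F, dprime=dprime, P=P, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class LotoResult:
    """Leave-one-trial-out decoding of one variable in one ROI."""

    source: str
    variable_id: str
    roi: str
    predictions: list[PredictionSeries]
    accuracy: AccuracyStats | None
    skipped_folds: list[int] = field(default_factory=list)


def leave_one_trial_out(
    trials: Sequence[AlignedTrial],
    source: str,
    variable_id: str,
    roi: str = "",
    seed: int = 0,
    classifier_factory: Callable | None = None,
) -> LotoResult:
    """Cross-validate one variable: train on all trials minus one, predict
    the individual time points of the remaining trial; repeat over trials.

    Binarization thresholds (medians, tertiles), the 3:1 subsampling and the
    calibration sigmoid are all re-derived inside each fold from the
    training trials only.  Folds whose training set degenerates to a single
    class are skipped (and logged).  Hits and false alarms are pooled over
    folds before the d' correction.
    """
    if len(trials) < 2:
        raise ValueError("leave-one-trial-out needs at least 2 trials")
    predictions: list[PredictionSeries] = []
    skipped: list[int] = []
    hits = fas = n_pos = n_neg = 0

    for i, test in enumerate(trials):
        train = [t for j, t in enumerate(trials) if j != i]
        rng = np.random.default_rng([seed, i])
        try:
            binz = Binarizer(source, rng=rng).fit(
                [t.vars.get(source, variable_id) for t in train]
            )
            lab_blocks = [binz.transform(t.vars.get(source, variable_id), training=True)
                          for t in train]
            X_train = np.concatenate([t.X for t in train], axis=0)
            labeling = BinaryLabeling(
                np.concatenate([lb.labels for lb in lab_blocks]),
                np.concatenate([lb.include for lb in lab_blocks]),
                lab_blocks[0].rule,
            )
            decoder = train_decoder(X_train, labeling, variable_id, roi, classifier_factory)
            dv_train = decoder.decision_values(X_train[labeling.include])
            decoder.calibration = calibrate(dv_train, labeling.labels[labeling.include])
        except (SkipVariable, ValueError) as exc:
            logger.debug("fold %d of %s/%s in %s skipped: %s", i, source, variable_id, roi, exc)
            last_skip_reason = str(exc)
            skipped.append(i)
            predictions.append(PredictionSeries(
                test.trial_index, np.full(test.n_trs, 0.5), np.zeros(test.n_trs)))
            continue

        pred = predict_series(decoder, test.X, trial_index=test.trial_index)
        predictions.append(pred)

        test_lab = binz.transform(test.vars.get(source, variable_id), training=False)
        guess = np.where(pred.dvs >= 0, 1, -1)
        pos = test_lab.include & (test_lab.labels == 1)
        neg = test_lab.include & (test_lab.labels == -1)
        hits += int((guess[pos] == 1).sum())
        fas += int((guess[neg] == 1).sum())
        n_pos += int(pos.sum())
        n_neg += int(neg.sum())

    if skipped:
        logger.info("%s/%s in %s: %d of %d folds skipped (e.g. %s)",
                    source, variable_id, roi, len(skipped), len(trials), last_skip_reason)
    accuracy = None
    if n_pos and n_neg:
        accuracy = corrected_accuracy(hits / n_pos, fas / n_neg,
                                      n=n_pos + n_neg, n_pos=n_pos, n_neg=n_neg)
    return LotoResult(source, variable_id, roi, predictions, accuracy, skipped)


def decode_source(
    trials: Sequence[AlignedTrial],
    source: str,
    roi: str = "",
    seed: int = 0,
    classifier_factory: Callable | None = None,
) -> dict[str, LotoResult]:
    """Leave-one-trial-out decoding of every variable of one source."""
    out: dict[str, LotoResult] = {}
    for s in trials[0].vars.by_source(source):
        out[s.variable_id] = leave_one_trial_out(
            trials, source, s.variable_id, roi=roi, seed=seed,
            classifier_factory=classifier_factory)
    return out
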