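"""Scoring sorters against ground truth and spike-train statistics.

Accuracy of an unsupervised sorter is the fraction of spikes agreeing
with ground truth after the optimal one-to-one cluster↔neuron assignment
(Hungarian matching on the confusion matrix).  The benchmark harness
runs detection → preprocessing → every sorter on each simulated set and
reports per-set accuracies and relative improvements over the
autoencoder-ensemble reference, 100·(acc/acc_ref − 1) %.

Spike-train statistics: mean rate, and synchrony as the plug-in mutual
information (bits) between binarized event trains on a common time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import detect_and_preprocess
from .simulate import GroundTruth, RawRecording

__all__ = [
    "EventPairing",
    "AccuracyReport",
    "SpikeTrain",
    "BenchmarkResult",
    "match_events",
    "match_accuracy",
    "relative_improvement",
    "run_benchmark",
    "spike_rate",
    "mutual_information",
]


@dataclass
class EventPairing:
    """Greedy one-to-one pairing of detections with true spikes."""

    pairs: np.ndarray  # (m, 2) columns: detection index, truth index
    false_positive_idx: np.ndarray  # unpaired detections
    miss_idx: np.ndarray  # unpaired truths

    @property
    def recall(self) -> float:
        total = len(self.pairs) + len(self.miss_idx)
        return len(self.pairs) / total if total else 0.0

    @property
    def precision(self) -> float:
        total = len(self.pairs) + len(self.false_positive_idx)
        return len(self.pairs) / total if total else 0.0


@dataclass
class AccuracyReport:
    accuracy: float
    assignment: dict[int, int]  # predicted cluster -> true neuron
    confusion: np.ndarray  # (K_pred, K_true) counts
    scope: str = "matched_only"


@dataclass
class SpikeTrain:
    """Event times (s) on one electrode or neuron."""

    times: np.ndarray
    duration: float
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))


@dataclass
class BenchmarkResult:
    """Per-set accuracies and improvements plus per-model summaries."""

    table: pd.DataFrame  # columns: set_id, model, accuracy, improvement_pct
    summary: pd.DataFrame  # index model; mean/sd of accuracy and improvement
    reference: str = "ae_ensemble"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def match_events(
    pred_events: np.ndarray, truth: GroundTruth | np.ndarray, window: int
) -> EventPairing:
    """Pair detected event times with true spike times within ±window samples.

    Greedy nearest-neighbour one-to-one matching: candidate pairs are
    considered in order of increasing |Δt| and accepted while both sides
    are unused.  Unpaired detections are false positives; unpaired truths
    are misses.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    pred = np.asarray(pred_events, dtype=np.int64)
    true_times = truth.spike_times if isinstance(truth, GroundTruth) else np.asarray(truth)
    true_times = np.asarray(true_times, dtype=np.int64)
    if len(pred) == 0 or len(true_times) == 0:
        return EventPairing(
            pairs=np.empty((0, 2), dtype=np.int64),
            false_positive_idx=np.arange(len(pred)),
            miss_idx=np.arange(len(true_times)),
        )
    order = np.argsort(true_times, kind="stable")
    sorted_truth = true_times[order]
    # each detection's two bracketing truths are its only nearest candidates
    pos = np.searchsorted(sorted_truth, pred)
    cand: list[tuple[int, int, int]] = []
    for pi, p in enumerate(pred):
        for j in (pos[pi] - 1, pos[pi]):
            if 0 <= j < len(sorted_truth):
                dt = abs(int(p) - int(sorted_truth[j]))
                if dt <= window:
                    cand.append((dt, pi, int(order[j])))
    cand.sort()
    used_p = np.zeros(len(pred), dtype=bool)
    used_t = np.zeros(len(true_times), dtype=bool)
    pairs = []
    for _, pi, ti in cand:
        if not used_p[pi] and not used_t[ti]:
            used_p[pi] = used_t[ti] = True
            pairs.append((pi, ti))
    pairs_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return EventPairing(
        pairs=pairs_arr,
        false_positive_idx=np.flatnonzero(~used_p),
        miss_idx=np.flatnonzero(~used_t),
    )


def match_accuracy(
    pred_labels: np.ndarray, true_labels: np.ndarray, scope: str = "matched_only"
) -> AccuracyReport:
    """Hungarian-matched classification accuracy of a clustering.

    Builds the (K_pred × K_true) confusion matrix and maximizes the
    number of agreeing spikes over one-to-one cluster↔neuron
    assignments; accuracy is that maximum divided by the number of
    scored spikes.
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if len(pred) == 0 or len(pred) != len(true):
        raise ValueError("label vectors must be non-empty and equal-length")
    pred_ids = np.unique(pred)
    true_ids = np.unique(true)
    confusion = np.zeros((len(pred_ids), len(true_ids)), dtype=np.int64)
    pi = np.searchsorted(pred_ids, pred)
    ti = np.searchsorted(true_ids, true)
    np.add.at(confusion, (pi, ti), 1)
    rows, cols = linear_sum_assignment(-confusion)
    correct = int(confusion[rows, cols].sum())
    assignment = {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}
    return AccuracyReport(
        accuracy=correct / len(pred),
        assignment=assignment,
        confusion=confusion,
        scope=scope,
    )


def relative_improvement(acc_model: float, acc_reference: float) -> float:
    """Accuracy change of a model relative to a reference, in percent."""
    if acc_reference <= 0:
        raise ValueError("reference accuracy must be > 0")
    return 100.0 * (acc_model - acc_reference) / acc_reference


def run_benchmark(
    suite: list[tuple[RawRecording, GroundTruth]],
    sorters: dict,
    reference: str = "ae_ensemble",
    match_window: int = 30,
    scope: str = "matched_only",
    seed: int = 0,
    size_class: str = "",
) -> BenchmarkResult:
    """Detect, preprocess and sort every set; score and normalize.

    ``sorters`` maps model name to ``f(features, K, seed) -> labels``
    (see :func:`measort.pipeline.default_sorters`); it must contain the
    ``reference`` model.  Per-set sorter seeds derive from ``seed``.
    With scope ``"matched_only"`` each sorter is scored on the detected
    spikes paired to ground truth; ``"all_truth"`` additionally counts
    every missed true spike as an error, penalizing the shared detector.
    """
    if not suite:
        raise ValueError("suite must be non-empty")
    if reference not in sorters:
        raise ValueError(f"sorters must include the reference {reference!r}")
    seeds = np.random.SeedSequence(seed).generate_state(len(suite)).astype(np.int64) % (2**31)
    rows = []
    for set_id, (rec, truth) in enumerate(suite):
        features, events = detect_and_preprocess(rec)
        trough_idx = np.asarray([ev.trough_index for ev in events])
        pairing = match_events(trough_idx, truth, window=match_window)
        det_idx = pairing.pairs[:, 0]
        true_lab = truth.neuron_labels[pairing.pairs[:, 1]]
        feats = features[det_idx]
        n_truth = len(truth)
        for name, fn in sorters.items():
            try:
                labels = fn(feats, truth.n_neurons, int(seeds[set_id]))
                report = match_accuracy(labels, true_lab, scope=scope)
                acc = report.accuracy
                if scope == "all_truth":
                    acc = acc * len(true_lab) / n_truth if n_truth else 0.0
            except Exception as exc:  # noqa: BLE001 - one failed set must not kill the run
                warnings.warn(f"sorter {name!r} failed on set {set_id}: {exc}")
                acc = np.nan
            rows.append({"set_id": set_id, "size_class": size_class,
                         "model": name, "accuracy": acc})
    table = pd.DataFrame(rows)
    ref_acc = table[table.model == reference].set_index("set_id").accuracy
    table["improvement_pct"] = [
        relative_improvement(r.accuracy, ref_acc[r.set_id])
        if np.isfinite(r.accuracy) and ref_acc[r.set_id] > 0 else np.nan
        for r in table.itertuples()
    ]
    summary = table.groupby("model").agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        improvement_mean=("improvement_pct", "mean"),
        improvement_sd=("improvement_pct", "std"),
    )
    return BenchmarkResult(table=table, summary=summary, reference=reference)


def spike_rate(train: SpikeTrain) -> float:
    """Mean firing rate: event count divided by the recording duration."""
    if train.duration <= 0:
        raise ValueError("duration must be > 0")
    return len(train.times) / train.duration


def _binarize(train: SpikeTrain, bin_width: float, duration: float) -> np.ndarray:
    n_bins = int(np.floor(duration / bin_width))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    counts, _ = np.histogram(train.times, bins=n_bins, range=(0.0, n_bins * bin_width))
    return counts > 0


def mutual_information(
    train_a: SpikeTrain, train_b: SpikeTrain, bin_width: float = 0.02
) -> float:
    """Plug-in mutual information (bits) between two binarized spike trains.

    Both trains are binned on a common grid (1 if the bin holds ≥1
    event) over their shared duration; MI is computed from the joint
    2×2 histogram with base-2 logarithms.  Nonnegative by construction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    duration = min(train_a.duration, train_b.duration)
    a = _binarize(train_a, bin_width, duration)
    b = _binarize(train_b, bin_width, duration)
    n = len(a)
    joint = np.zeros((2, 2))
    for va in (0, 1):
        for vb in (0, 1):
            joint[va, vb] = np.sum((a == va) & (b == vb))
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mi = 0.0
    for va in (0, 1):
        for vb in (0, 1):
            if joint[va, vb] > 0:
                mi += joint[va, vb] * np.log2(joint[va, vb] / (pa[va] * pb[vb]))
    return max(mi, 0.0)
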