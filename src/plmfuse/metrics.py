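"""Per-residue and per-segment evaluation measures, with random baselines.

Conventions: accuracies (Q3, Q10, Q_ok), precision, recall and F1 are
reported in percent. Per-chain aggregation uses the population standard
deviation over chains and reports the standard error SD / sqrt(n - 1).
Undefined values (constant vectors, degenerate contingency tables, empty
denominators) come back as NaN with a warning — never a silent zero — with
one documented exception: F1 is 0 when precision + recall is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .types import LabelTrack

logger = logging.getLogger(__name__)


def _as_labels(track) -> str:
    if isinstance(track, LabelTrack):
        return track.labels
    return track


def _as_scores(track) -> np.ndarray:
    if isinstance(track, LabelTrack):
        return track.scores
    return np.asarray(track, dtype=float)


# ---------------------------------------------------------------------------
# Per-residue / per-protein accuracies


def q3(pred, obs) -> float:
    """Three-state per-residue accuracy: 100 * #correct / #total."""
    p, o = _as_labels(pred), _as_labels(obs)
    if len(p) != len(o):
        raise ValueError(f"length mismatch: {len(p)} vs {len(o)}")
    if len(o) == 0:
        raise ValueError("empty tracks")
    correct = sum(a == b for a, b in zip(p, o))
    return 100.0 * correct / len(o)


def q10(pred_classes, obs_classes) -> float:
    """Per-protein accuracy over a 10-class alphabet: 100 * #correct / #total."""
    pred_classes = list(pred_classes)
    obs_classes = list(obs_classes)
    if len(pred_classes) != len(obs_classes):
        raise ValueError("length mismatch")
    if not obs_classes:
        raise ValueError("no proteins")
    correct = sum(a == b for a, b in zip(pred_classes, obs_classes))
    return 100.0 * correct / len(obs_classes)


@dataclass
class MetricReport:
    """Per-chain metric values with their mean, spread and standard error."""

    values: np.ndarray
    mean: float
    sd: float | None
    se: float | None

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def ci95_halfwidth(self) -> float | None:
        return None if self.se is None else 1.96 * self.se


def aggregate_per_chain(values) -> MetricReport:
    """Mean, population SD over chains, and SE = SD / sqrt(n - 1)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no chain values")
    mean = float(values.mean())
    if values.size < 2:
        logger.warning("single chain: SD and SE undefined")
        return MetricReport(values, mean, None, None)
    sd = float(values.std())  # population SD over the chain distribution
    se = sd / math.sqrt(values.size - 1)
    return MetricReport(values, mean, sd, se)


# ---------------------------------------------------------------------------
# Rank correlation, F1, MCC


def spearman(u, v) -> float:
    """Spearman correlation: Pearson product-moment on mean ranks.

    Ties receive their average rank. NaN (with a warning) when either
    vector is constant after ranking.
    """
    u, v = _as_scores(u), _as_scores(v)
    if len(u) != len(v):
        raise ValueError("length mismatch")
    if len(u) < 2:
        raise ValueError("need at least two residues")
    ru = scipy.stats.rankdata(u)
    rv = scipy.stats.rankdata(v)
    if np.ptp(ru) == 0 or np.ptp(rv) == 0:
        logger.warning("spearman undefined for constant input")
        return float("nan")
    ru = ru - ru.mean()
    rv = rv - rv.mean()
    return float((ru * rv).sum() / math.sqrt((ru ** 2).sum() * (rv ** 2).sum()))


def f1_binary(pred, obs, positive: str) -> dict[str, float]:
    """Precision, recall and F1 (percent) for one positive class.

    With no predicted positives precision is NaN (flagged); with no
    observed positives recall is NaN. F1 is 0 whenever precision + recall
    is 0 or either is undefined with the other 0.
    """
    p, o = _as_labels(pred), _as_labels(obs)
    if len(p) != len(o):
        raise ValueError("length mismatch")
    tp = sum(a == positive and b == positive for a, b in zip(p, o))
    fp = sum(a == positive and b != positive for a, b in zip(p, o))
    fn = sum(a != positive and b == positive for a, b in zip(p, o))
    if tp + fp == 0:
        logger.warning("no predicted positives: precision undefined")
        precision = float("nan")
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no observed positives: recall undefined")
        recall = float("nan")
    else:
        recall = 100.0 * tp / (tp + fn)
    pr = 0.0 if math.isnan(precision) else precision
    rc = 0.0 if math.isnan(recall) else recall
    f1 = 0.0 if pr + rc == 0 else 2.0 * rc * pr / (rc + pr)
    return {"precision": precision, "recall": recall, "f1": f1}


def mcc_conservation(pred, obs, conserved_threshold: int = 5) -> float:
    """Matthews correlation after binarizing nine-class conservation.

    Classes above ``conserved_threshold`` (default 5, so classes 6-9) count
    as conserved. NaN (flagged) when the 2x2 table is degenerate.
    """
    p = np.asarray(list(pred), dtype=int)
    o = np.asarray(list(obs), dtype=int)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    pb = p > conserved_threshold
    ob = o > conserved_threshold
    tp = int((pb & ob).sum())
    tn = int((~pb & ~ob).sum())
    fp = int((pb & ~ob).sum())
    fn = int((~pb & ob).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC undefined: degenerate contingency table")
        return float("nan")
    return (tp * tn - fp * fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# Segments and Q_ok


@dataclass(frozen=True)
class Segment:
    """A maximal run of one label, as a 0-based half-open interval."""

    type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment needs start < end")

    def __len__(self) -> int:
        return self.end - self.start


def extract_segments(labels, seg_type: str) -> list[Segment]:
    """Maximal runs of ``seg_type`` in a categorical track, in order."""
    s = _as_labels(labels)
    segments = []
    start = None
    for i, ch in enumerate(s):
        if ch == seg_type and start is None:
            start = i
        elif ch != seg_type and start is not None:
            segments.append(Segment(seg_type, start, i))
            start = None
    if start is not None:
        segments.append(Segment(seg_type, start, len(s)))
    return segments


def segment_match(pred: Segment, obs: Segment, max_shift: int = 5) -> bool:
    """A predicted segment matches an observed one iff start and end each
    differ by at most ``max_shift`` residues and the intersection covers at
    least half of the union."""
    if pred.type != obs.type:
        raise ValueError("segment types differ")
    if abs(pred.start - obs.start) > max_shift or abs(pred.end - obs.end) > max_shift:
        return False
    inter = max(0, min(pred.end, obs.end) - max(pred.start, obs.start))
    union = max(pred.end, obs.end) - min(pred.start, obs.start)
    return 2 * inter >= union


def protein_segments_correct(pred_track, obs_track, seg_type: str,
                             max_shift: int = 5) -> bool:
    """All observed segments of a type matched one-to-one, in order, with no
    extra predicted segments."""
    pred_segs = extract_segments(pred_track, seg_type)
    obs_segs = extract_segments(obs_track, seg_type)
    if len(pred_segs) != len(obs_segs):
        return False
    return all(segment_match(p, o, max_shift) for p, o in zip(pred_segs, obs_segs))


def q_ok(pairs, seg_type: str, max_shift: int = 5) -> float:
    """Percentage of proteins whose segments of a type are all predicted
    correctly, over proteins that have at least one observed segment of
    that type.

    ``pairs`` is an iterable of (pred_track, obs_track).
    """
    n_with, n_correct = 0, 0
    for pred_track, obs_track in pairs:
        if not extract_segments(obs_track, seg_type):
            continue
        n_with += 1
        if protein_segments_correct(pred_track, obs_track, seg_type, max_shift):
            n_correct += 1
    if n_with == 0:
        raise ValueError(f"no protein has an observed segment of type {seg_type!r}")
    return 100.0 * n_correct / n_with


# ---------------------------------------------------------------------------
# Random baselines


def baseline_shuffle_labels(p, n: int, seed: int = 0) -> dict[str, float]:
    """Expected accuracy of drawing predictions from the class distribution.

    Both labels and predictions are drawn i.i.d. from ``p``; the closed
    form of the expected accuracy is 100 * sum(p_c^2). Returns the closed
    form and a simulated value over ``n`` draws.
    """
    p = np.asarray(p, dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class distribution must sum to 1")
    rng = np.random.default_rng(seed)
    k = len(p)
    obs = rng.choice(k, size=n, p=p)
    pred = rng.choice(k, size=n, p=p)
    return {
        "expected": 100.0 * float((p ** 2).sum()),
        "simulated": 100.0 * float((obs == pred).mean()),
    }


def baseline_majority(obs_tracks, alphabet) -> tuple[str, float]:
    """Predict the globally most frequent class everywhere.

    Ties break to the lowest class index in ``alphabet``. Returns the
    winning class and the resulting per-residue accuracy over all chains.
    """
    counts = {c: 0 for c in alphabet}
    total = 0
    for track in obs_tracks:
        for ch in _as_labels(track):
            counts[ch] += 1
            total += 1
    if total == 0:
        raise ValueError("no residues")
    best = max(alphabet, key=lambda c: (counts[c], -alphabet.index(c)))
    return best, 100.0 * counts[best] / total
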