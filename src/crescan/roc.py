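"""Threshold calibration by ROC analysis on a genome with known sites.

Every scanned window is labelled positive (it is a known binding site) or
negative (everything else), and the bit-score threshold is swept: at each
threshold t, TPR(t) is the fraction of positives scoring >= t and FPR(t) the
fraction of negatives scoring >= t.  Because a window overlapping a true
site by half the motif or more shares most of its sequence with it, such
windows are excluded from the negatives by default (strict mode keeps them).

The default sweep covers integer thresholds 9..19 bits, the range where a
well-trained 14-position bacterial operator matrix trades sensitivity
against specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .motif import Pssm, ValidationError, score_kmer
from .scan import GenomeSequence, ScoredWindow, scan

__all__ = [
    "LabeledWindows",
    "RocCurve",
    "RocPoint",
    "label_windows",
    "roc_curve",
    "auroc",
    "choose_threshold",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(range(9, 20))


@dataclass(frozen=True)
class LabeledWindows:
    """Window scores partitioned into known-site positives and negatives."""

    positive_scores: np.ndarray
    negative_scores: np.ndarray
    n_excluded: int = 0      # negatives dropped for overlapping a positive
    missing_sites: tuple = ()  # known sites not found in the genome

    def __post_init__(self):
        object.__setattr__(
            self, "positive_scores", np.asarray(self.positive_scores, float)
        )
        object.__setattr__(
            self, "negative_scores", np.asarray(self.negative_scores, float)
        )


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


@dataclass(frozen=True)
class RocCurve:
    points: tuple[RocPoint, ...]
    auroc: float | None = None

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


def label_windows(
    windows: Iterable[ScoredWindow],
    known_sites: Sequence,
    mode: str = "coordinates",
    motif_width: int | None = None,
    exclude_overlap: bool = True,
) -> LabeledWindows:
    """Partition scanned windows into positives and negatives.

    Parameters
    ----------
    known_sites
        In ``mode="coordinates"``: (contig, start) pairs (1-based window
        starts).  In ``mode="sequences"``: site sequences; every window
        whose sequence would equal one is positive — pass windows that carry
        their sequence score from the same PSSM, matching is by coordinates
        of occurrences, so in this mode pass (contig, start) occurrences
        resolved beforehand or use :func:`label_windows_by_sequence`.
    exclude_overlap
        Drop from the negatives any window overlapping a positive start by
        at least half the motif width (requires ``motif_width``); strict
        mode (False) keeps all non-identical windows as negatives.
    """
    if mode != "coordinates":
        raise ValidationError(
            "label_windows handles coordinate mode; use label_windows_by_sequence"
        )
    if not known_sites:
        raise ValidationError("known-site set is empty; ROC is undefined")
    wanted = {(c, int(s)) for c, s in known_sites}
    pos, neg = [], []
    n_excluded = 0
    pos_starts_by_contig: dict[str, set[int]] = {}
    for c, s in wanted:
        pos_starts_by_contig.setdefault(c, set()).add(s)
    half = (motif_width // 2) if motif_width else 0
    neg_candidates = []
    found = set()
    for w in windows:
        key = (w.contig, w.start)
        if key in wanted:
            pos.append(w.score)
            found.add(key)
        else:
            neg_candidates.append(w)
    missing = tuple(sorted(wanted - found))
    if missing:
        warnings.warn(
            f"{len(missing)} known site(s) not found among scanned windows; "
            "excluded from positives",
            stacklevel=2,
        )
    if not pos:
        raise ValidationError("no known site matched a scanned window")
    for w in neg_candidates:
        if exclude_overlap and half:
            starts = pos_starts_by_contig.get(w.contig, ())
            if any(abs(w.start - s) <= half for s in starts):
                n_excluded += 1
                continue
        neg.append(w.score)
    if not neg:
        raise ValidationError("negative set is empty; ROC is undefined")
    return LabeledWindows(
        positive_scores=np.array(pos),
        negative_scores=np.array(neg),
        n_excluded=n_excluded,
        missing_sites=missing,
    )


def label_windows_by_sequence(
    pssm: Pssm,
    genomes: Iterable[GenomeSequence],
    site_sequences: Sequence[str],
    strand_mode: str = "forward",
    exclude_overlap: bool = True,
) -> LabeledWindows:
    """Sequence-mode labelling: every genome window equal to a known site
    sequence is a positive.  Convenience wrapper that scans, locates
    occurrences and delegates to coordinate-mode labelling."""
    if not site_sequences:
        raise ValidationError("known-site set is empty; ROC is undefined")
    siteset = {s.upper() for s in site_sequences}
    k = pssm.width
    for s in siteset:
        if len(s) != k:
            raise ValidationError(f"site {s!r} length != motif width {k}")
    coords = []
    all_windows = []
    genomes = list(genomes)
    for g in genomes:
        seq = g.sequence
        for w in scan(pssm, g, strand_mode=strand_mode):
            all_windows.append(w)
            if seq[w.start - 1 : w.end] in siteset:
                coords.append((w.contig, w.start))
    if not coords:
        missing = tuple(sorted(siteset))
        raise ValidationError(
            f"none of the {len(missing)} known site sequences occur in the genome"
        )
    return label_windows(
        all_windows,
        sorted(set(coords)),
        motif_width=k,
        exclude_overlap=exclude_overlap,
    )


def roc_curve(
    labeled: LabeledWindows,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    with_auroc: bool = True,
) -> RocCurve:
    """TPR/FPR at each threshold (score >= threshold counts as detected)."""
    pos = labeled.positive_scores
    neg = labeled.negative_scores
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative")
    thr = np.asarray(sorted(thresholds), float)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= t via binary search on the sorted arrays
    tpr = 1.0 - np.searchsorted(pos_sorted, thr, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thr, side="left") / neg.size
    points = tuple(
        RocPoint(float(t), float(tp), float(fp)) for t, tp, fp in zip(thr, tpr, fpr)
    )
    return RocCurve(points=points, auroc=auroc(labeled) if with_auroc else None)


def auroc(labeled: LabeledWindows) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, midranks for ties.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    pos = labeled.positive_scores
    neg = labeled.negative_scores
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def choose_threshold(
    curve: RocCurve,
    criterion: str = "youden",
    fpr_ceiling: float | None = None,
    fixed: float | None = None,
) -> RocPoint:
    """Pick an operating point from a ROC curve.

    criterion:
        ``"youden"`` — maximise Youden's J = TPR - FPR (lowest threshold on
        ties);
        ``"fpr_ceiling"`` — highest TPR subject to FPR <= ``fpr_ceiling``;
        ``"fixed"`` — report the curve point at threshold ``fixed`` (which
        must be on the sweep).
    """
    if not curve.points:
        raise ValidationError("empty ROC curve")
    if criterion == "youden":
        return max(curve.points, key=lambda p: (p.tpr - p.fpr, -p.threshold))
    if criterion == "fpr_ceiling":
        if fpr_ceiling is None:
            raise ValidationError("fpr_ceiling criterion needs a ceiling value")
        feasible = [p for p in curve.points if p.fpr <= fpr_ceiling]
        if not feasible:
            raise ValidationError(f"no threshold achieves FPR <= {fpr_ceiling}")
        return max(feasible, key=lambda p: (p.tpr, -p.fpr))
    if criterion == "fixed":
        if fixed is None:
            raise ValidationError("fixed criterion needs a threshold value")
        for p in curve.points:
            if p.threshold == fixed:
                return p
        raise ValidationError(f"threshold {fixed} is not on the sweep")
    raise ValidationError(f"unknown criterion {criterion!r}")
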