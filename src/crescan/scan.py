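"""Sliding-window genome scoring and hit calling.

A genome is scanned by scoring every k-mer window with a PSSM.  Scanning is
streaming: the genome is processed in fixed-size chunks (vectorised with
numpy inside each chunk) and windows are yielded one at a time, so the full
per-window score vector never has to be resident.  Summary statistics use
Welford's single-pass mean/variance update, merged across chunks with the
standard parallel-combine formula.

Coordinates are 1-based inclusive internally (``start..end`` spans k bases);
BED export converts to 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from intervaltree import IntervalTree

from .motif import Pssm, ValidationError, encode

__all__ = [
    "GenomeSequence",
    "ScoredWindow",
    "ScanSummary",
    "HitTable",
    "scan",
    "scan_summary",
    "scan_and_call",
    "call_hits",
    "annotate_nearest_feature",
]

_CHUNK = 1 << 16


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: identifier plus uppercase sequence."""

    identifier: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


class ScoredWindow(NamedTuple):
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, start + k - 1
    strand: str
    score: float


@dataclass
class ScanSummary:
    """Streaming statistics over all scored windows of a scan."""

    n_scored: int = 0
    n_skipped: int = 0
    mean: float = 0.0
    _m2: float = 0.0
    min: float = math.inf
    max: float = -math.inf

    @property
    def sd(self) -> float:
        return math.sqrt(self._m2 / self.n_scored) if self.n_scored else float("nan")

    @property
    def n_total(self) -> int:
        return self.n_scored + self.n_skipped

    def _update_chunk(self, scores: np.ndarray, n_skipped: int) -> None:
        # Chan et al. parallel combine of (count, mean, M2) aggregates.
        self.n_skipped += n_skipped
        nb = scores.size
        if nb == 0:
            return
        mb = float(scores.mean())
        m2b = float(((scores - mb) ** 2).sum())
        na = self.n_scored
        if na == 0:
            self.n_scored, self.mean, self._m2 = nb, mb, m2b
        else:
            delta = mb - self.mean
            n = na + nb
            self.mean += delta * nb / n
            self._m2 += m2b + delta * delta * na * nb / n
            self.n_scored = n
        self.min = min(self.min, float(scores.min()))
        self.max = max(self.max, float(scores.max()))


@dataclass
class HitTable:
    """Windows at or above a threshold, sorted by descending score then coordinate."""

    hits: list[ScoredWindow]
    threshold: float
    summary: ScanSummary | None = None

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: (-h.score, h.contig, h.start))

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def _chunk_scores(pssm_w: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and validity mask for every window start in an encoded chunk."""
    k = pssm_w.shape[1]
    n = idx.size - k + 1
    bad = (idx < 0).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k : k + n] - cum[:n]) == 0 if n > 0 else np.zeros(0, bool)
    safe = np.where(idx < 0, 0, idx)
    scores = np.zeros(n)
    for j in range(k):
        scores += pssm_w[safe[j : j + n], j]
    return scores, valid


def _revcomp_matrix(w: np.ndarray) -> np.ndarray:
    # Scoring the reverse complement of window s with w equals scoring s with
    # w flipped in both base (A<->T, C<->G) and position order.
    return w[::-1, ::-1]


def scan(
    pssm: Pssm,
    genome: GenomeSequence,
    strand_mode: str = "forward",
    emit: str = "best",
    summary: ScanSummary | None = None,
    chunk_size: int = _CHUNK,
) -> Iterator[ScoredWindow]:
    """Yield a ScoredWindow for every k-mer start position of a contig.

    Parameters
    ----------
    strand_mode
        ``"forward"`` scores the given strand only; ``"both"`` also scores
        each window's reverse complement.
    emit
        In ``"both"`` mode, ``"best"`` yields one window per start (the
        higher-scoring strand, '+' on ties) while ``"all"`` yields both
        strands.  Ignored in forward mode.
    summary
        Optional ScanSummary accumulated in the same pass.  Windows
        containing non-ACGT bases are skipped and counted there.
    """
    if strand_mode not in ("forward", "both"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    if emit not in ("best", "all"):
        raise ValidationError(f"unknown emit policy {emit!r}")
    k = pssm.width
    L = genome.length
    if L < k:
        raise ValidationError(
            f"contig {genome.identifier!r} length {L} is shorter than motif width {k}"
        )
    w_fwd = pssm.w
    w_rev = _revcomp_matrix(w_fwd) if strand_mode == "both" else None
    contig = genome.identifier

    for chunk_start in range(0, L - k + 1, chunk_size):
        block = genome.sequence[chunk_start : chunk_start + chunk_size + k - 1]
        n = min(chunk_size, L - k + 1 - chunk_start)
        idx = encode(block)
        fwd, valid = _chunk_scores(w_fwd, idx)
        fwd, valid = fwd[:n], valid[:n]
        if strand_mode == "both":
            rev = _chunk_scores(w_rev, idx)[0][:n]
        starts = np.nonzero(valid)[0]
        if summary is not None:
            if strand_mode == "both" and emit == "all":
                summary._update_chunk(
                    np.concatenate([fwd[valid], rev[valid]]), int(n - starts.size)
                )
            elif strand_mode == "both":
                summary._update_chunk(
                    np.maximum(fwd[valid], rev[valid]), int(n - starts.size)
                )
            else:
                summary._update_chunk(fwd[valid], int(n - starts.size))
        for i in starts:
            start = chunk_start + int(i) + 1
            end = start + k - 1
            if strand_mode == "forward":
                yield ScoredWindow(contig, start, end, "+", float(fwd[i]))
            elif emit == "all":
                yield ScoredWindow(contig, start, end, "+", float(fwd[i]))
                yield ScoredWindow(contig, start, end, "-", float(rev[i]))
            else:
                if rev[i] > fwd[i]:
                    yield ScoredWindow(contig, start, end, "-", float(rev[i]))
                else:
                    yield ScoredWindow(contig, start, end, "+", float(fwd[i]))


def scan_summary(
    pssm: Pssm, genome: GenomeSequence, strand_mode: str = "forward", **kw
) -> ScanSummary:
    """Single-pass score statistics without retaining any windows."""
    summary = ScanSummary()
    for _ in scan(pssm, genome, strand_mode=strand_mode, summary=summary, **kw):
        pass
    return summary


def call_hits(windows: Iterable[ScoredWindow], threshold: float) -> HitTable:
    """Keep windows scoring at or above ``threshold`` (ties count as detected)."""
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return HitTable(
        hits=[w for w in windows if w.score >= threshold], threshold=threshold
    )


def scan_and_call(
    pssm: Pssm,
    genomes: Iterable[GenomeSequence],
    threshold: float,
    strand_mode: str = "forward",
    min_length_warn: bool = True,
) -> tuple[HitTable, ScanSummary]:
    """Scan several contigs in one pass, returning hits plus pooled summary.

    Contigs shorter than the motif are excluded with a warning rather than
    raising, so mixed-length FASTA files scan cleanly.
    """
    import warnings as _w

    summary = ScanSummary()
    hits: list[ScoredWindow] = []
    for g in genomes:
        if g.length < pssm.width:
            if min_length_warn:
                _w.warn(
                    f"contig {g.identifier!r} shorter than motif width; skipped",
                    stacklevel=2,
                )
            continue
        for win in scan(pssm, g, strand_mode=strand_mode, summary=summary):
            if win.score >= threshold:
                hits.append(win)
    table = HitTable(hits=hits, threshold=threshold, summary=summary)
    return table, summary


@dataclass(frozen=True)
class AnnotatedHit:
    window: ScoredWindow
    location: str          # "within CDS" | "upstream" | "intergenic"
    gene: str | None
    distance_bp: int | None


def annotate_nearest_feature(
    hits: HitTable,
    features,
    upstream_window: int = 500,
) -> list[AnnotatedHit]:
    """Label hits relative to a gene table.

    ``features`` is an iterable of records with attributes/keys
    contig, start, end (1-based inclusive), strand and name — e.g. the
    DataFrame rows produced by :func:`crescan.io.read_features`.

    A hit overlapping a gene span is "within CDS" (distance 0, ties broken by
    the first overlapping gene in table order).  Otherwise, if a gene start
    (strand-aware: the 5' end) lies within ``upstream_window`` bp downstream
    of the hit, it is "upstream" of that gene, with the gap in bp.  Else
    "intergenic".
    """
    recs = _feature_records(features)
    trees: dict[str, IntervalTree] = {}
    by_contig: dict[str, list[dict]] = {}
    for r in recs:
        trees.setdefault(r["contig"], IntervalTree()).addi(
            r["start"], r["end"] + 1, r
        )
        by_contig.setdefault(r["contig"], []).append(r)

    contigs_seen = {h.contig for h in hits}
    unknown = {r["contig"] for r in recs} - contigs_seen if recs else set()
    if hits.hits and recs and not (set(trees) & contigs_seen):
        raise ValidationError(
            f"feature table contigs {sorted(set(trees))} match no hit contig"
        )

    out: list[AnnotatedHit] = []
    for h in hits:
        tree = trees.get(h.contig)
        overlapping = sorted(tree[h.start : h.end + 1], key=lambda iv: iv.begin) if tree else []
        if overlapping:
            gene = overlapping[0].data
            out.append(AnnotatedHit(h, "within CDS", gene["name"], 0))
            continue
        best = None
        for r in by_contig.get(h.contig, []):
            if r["strand"] == "-":
                # 5' end of a minus-strand gene is its higher coordinate
                gene_start = r["end"]
                dist = h.start - gene_start
            else:
                gene_start = r["start"]
                dist = gene_start - h.end
            if 0 < dist <= upstream_window and (best is None or dist < best[1]):
                best = (r, dist)
        if best is not None:
            out.append(AnnotatedHit(h, "upstream", best[0]["name"], best[1]))
        else:
            out.append(AnnotatedHit(h, "intergenic", None, None))
    return out


def _feature_records(features) -> list[dict]:
    try:  # pandas DataFrame
        return features.to_dict("records")
    except AttributeError:
        return [dict(r) for r in features]
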