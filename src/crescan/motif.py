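"""Position-specific scoring matrices for bacterial operator sites.

The model is the classical additive log-odds motif model: a collection of
aligned, equal-length binding sites is tallied into a 4 x k count matrix,
smoothed with a pseudocount, normalised to per-position base frequencies
``f[b, i]``, and converted to a score matrix

    w[b, i] = log2( f[b, i] / p_b )

against a background base distribution ``p``.  A k-mer's score is the sum of
its per-position entries, in bits.  Per-position conservation is the relative
entropy (Kullback-Leibler divergence) of the column against the background,
also in bits.

Everything here is strand-explicit DNA over {A, C, G, T}; training sites must
be unambiguous, while degenerate IUPAC codes are supported only for consensus
*patterns* (see :func:`degenerate_match`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "SiteCollection",
    "CountMatrix",
    "BackgroundModel",
    "FrequencyMatrix",
    "Pssm",
    "PalindromeReport",
    "ValidationError",
    "build_count_matrix",
    "to_frequencies",
    "estimate_background",
    "build_pssm",
    "score_kmer",
    "consensus_sequence",
    "information_content",
    "palindrome_positions",
    "degenerate_match",
    "reverse_complement",
    "encode",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC nucleotide codes -> the set of unambiguous bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Lookup table mapping byte values of A/C/G/T (either case) to 0..3, -1 otherwise.
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


class ValidationError(ValueError):
    """Invalid user input (bad sequence, malformed matrix, ...)."""


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into ACGT; non-ACGT become -1."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiteCollection:
    """Aligned training binding sites, all of one width k.

    Parameters
    ----------
    sites
        DNA strings over {A, C, G, T}; equal length, k >= 2.
    source_label
        Free-text provenance (e.g. the database the sites came from).
    """

    sites: tuple[str, ...]
    source_label: str = ""

    def __init__(self, sites: Sequence[str], source_label: str = ""):
        sites = tuple(s.upper() for s in sites)
        if not sites:
            raise ValidationError("site collection is empty")
        k = len(sites[0])
        for idx, s in enumerate(sites):
            if len(s) != k:
                raise ValidationError(
                    f"site {idx} has length {len(s)}, expected {k} (ragged collection)"
                )
            bad = set(s) - set(ALPHABET)
            if bad:
                raise ValidationError(
                    f"site {idx} contains non-ACGT character(s) {sorted(bad)}"
                )
        if k < 2:
            raise ValidationError(f"motif width must be >= 2, got {k}")
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "source_label", source_label)

    @property
    def width(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass(frozen=True)
class CountMatrix:
    """Base counts per motif position; every column sums to ``n_sites``."""

    counts: np.ndarray  # (4, k) int
    n_sites: int

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape[0] != 4 or c.ndim != 2:
            raise ValidationError(f"count matrix must be 4 x k, got {c.shape}")
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        colsums = c.sum(axis=0)
        if not (colsums == self.n_sites).all():
            raise ValidationError(
                f"count columns must each sum to n_sites={self.n_sites}, got {colsums}"
            )
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BackgroundModel:
    """Base probabilities (A, C, G, T) of the genomic background."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (4,):
            raise ValidationError("background must have 4 probabilities (A,C,G,T)")
        if (p <= 0).any():
            raise ValidationError(
                "background probabilities must all be positive; "
                "use estimate_background(..., floor=...) for degenerate genomes"
            )
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"background probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "p", p)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base probabilities; columns sum to 1."""

    f: np.ndarray  # (4, k)
    pseudocount: float = 0.0
    n_sites: int = 0

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        if f.shape[0] != 4 or f.ndim != 2:
            raise ValidationError(f"frequency matrix must be 4 x k, got {f.shape}")
        if (f < 0).any():
            raise ValidationError("frequencies must be non-negative")
        colsums = f.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError(f"frequency columns must sum to 1, got {colsums}")
        if self.pseudocount > 0 and (f == 0).any():
            raise ValidationError("pseudocount > 0 but zero frequencies present")
        object.__setattr__(self, "f", f)

    @property
    def width(self) -> int:
        return self.f.shape[1]


@dataclass(frozen=True)
class Pssm:
    """Log-odds score matrix in bits: ``w[b, i] = log2(f[b, i] / p_b)``."""

    w: np.ndarray  # (4, k), may contain -inf under the permissive zero policy
    background: BackgroundModel = field(default_factory=BackgroundModel.uniform)

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape[0] != 4 or w.ndim != 2:
            raise ValidationError(f"score matrix must be 4 x k, got {w.shape}")
        object.__setattr__(self, "w", w)

    @property
    def width(self) -> int:
        return self.w.shape[1]

    @property
    def max_score(self) -> float:
        """Upper bound on any k-mer's score: sum of per-column maxima."""
        return float(self.w.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.w.min(axis=0).sum())

    def score(self, kmer: str) -> float:
        return score_kmer(self, kmer)


@dataclass(frozen=True)
class PalindromeReport:
    """Dyad-symmetry report for one even-length sequence.

    ``matches[i]`` is True when position i in the left half-site pairs
    (Watson-Crick) with its mirror position k-1-i in the right half-site.
    """

    sequence: str
    matches: tuple[bool, ...]

    @property
    def half_width(self) -> int:
        return len(self.matches)

    @property
    def count(self) -> int:
        return sum(self.matches)


def build_count_matrix(sites: SiteCollection) -> CountMatrix:
    """Tally base occurrences per position across the aligned sites."""
    k = sites.width
    counts = np.zeros((4, k), dtype=np.int64)
    for s in sites:
        idx = encode(s)
        counts[idx, np.arange(k)] += 1
    return CountMatrix(counts=counts, n_sites=len(sites))


def to_frequencies(counts: CountMatrix, pseudocount: float = 0.5) -> FrequencyMatrix:
    """Laplace-smoothed base frequencies.

    ``f[b, i] = (counts[b, i] + a) / (n + 4 a)`` with pseudocount ``a`` added
    to every cell; ``a = 0`` gives the raw maximum-likelihood frequencies
    (which may contain zeros).
    """
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    denom = counts.n_sites + 4.0 * pseudocount
    f = (counts.counts + pseudocount) / denom
    return FrequencyMatrix(f=f, pseudocount=pseudocount, n_sites=counts.n_sites)


def estimate_background(
    genome: str,
    both_strands: bool = False,
    floor: float = 1e-6,
) -> BackgroundModel:
    """Mononucleotide background composition of a genome sequence.

    Non-ACGT characters are ignored.  With ``both_strands=True``,
    complementary base counts are averaged, yielding a strand-symmetric
    background (p_A = p_T, p_C = p_G).  Zero counts are floored at ``floor``
    and renormalised, with a warning; pass ``floor=0`` to disable and get a
    hard error instead.
    """
    idx = encode(genome)
    counts = np.bincount(idx[idx >= 0], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("genome contains no A/C/G/T bases")
    if both_strands:
        counts = (counts + counts[::-1]) / 2.0  # A<->T, C<->G under ACGT order
    p = counts / counts.sum()
    if (p == 0).any():
        if floor <= 0:
            raise ValidationError(
                f"background has zero-probability base(s) at indices {np.where(p == 0)[0]}"
            )
        warnings.warn(
            f"background contains absent base(s); flooring probabilities at {floor}",
            stacklevel=2,
        )
        p = np.maximum(p, floor)
        p = p / p.sum()
    return BackgroundModel(p=p)


def build_pssm(
    freqs: FrequencyMatrix,
    background: BackgroundModel | None = None,
    zero_policy: str = "strict",
) -> Pssm:
    """Convert frequencies to a log-odds bit-score matrix.

    Parameters
    ----------
    zero_policy
        ``"strict"`` raises on zero frequencies (which would score -inf);
        ``"allow"`` keeps the -inf entries, treating an unseen base as an
        outright veto.
    """
    if background is None:
        background = BackgroundModel.uniform()
    if zero_policy not in ("strict", "allow"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "strict" and (freqs.f == 0).any():
        raise ValidationError(
            "frequency matrix has zero cells; use a pseudocount or zero_policy='allow'"
        )
    with np.errstate(divide="ignore"):
        w = np.log2(freqs.f / background.p[:, None])
    return Pssm(w=w, background=background)


def score_kmer(pssm: Pssm, seq: str) -> float:
    """Additive bit score of one k-mer: sum over positions of ``w[base, pos]``."""
    k = pssm.width
    if len(seq) != k:
        raise ValidationError(f"sequence length {len(seq)} != motif width {k}")
    idx = encode(seq)
    if (idx < 0).any():
        bad = seq[int(np.argmax(idx < 0))]
        raise ValidationError(f"ambiguous base {bad!r} in sequence {seq!r}")
    return float(pssm.w[idx, np.arange(k)].sum())


def consensus_sequence(pssm: Pssm) -> tuple[str, float]:
    """Highest-scoring k-mer and its score.

    Per position the maximal-score base is chosen; ties break
    lexicographically (A < C < G < T), which np.argmax's first-hit rule
    implements directly under the ACGT row order.
    """
    best = np.argmax(pssm.w, axis=0)
    seq = "".join(ALPHABET[b] for b in best)
    return seq, score_kmer(pssm, seq)


def information_content(
    freqs: FrequencyMatrix, background: BackgroundModel | None = None
) -> np.ndarray:
    """Per-position conservation in bits: KL(f_i || p).

    Terms with f = 0 contribute 0.  With a uniform background this equals
    2 - H(f_i), the familiar sequence-logo column height.  Total motif
    information is the sum over positions.
    """
    if background is None:
        background = BackgroundModel.uniform()
    f = freqs.f
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(f / background.p[:, None])
    terms = np.where(f > 0, terms, 0.0)
    return terms.sum(axis=0)


def palindrome_positions(seq: str) -> PalindromeReport:
    """Count dyad-symmetric positions of an even-length site.

    Position i of the left half-site matches when ``seq[i]`` is the
    Watson-Crick complement of the mirrored base ``seq[k-1-i]`` — the
    signature of an inverted-repeat operator bound by a protein dimer.
    The count is invariant under reverse-complementing the input.
    """
    seq = seq.upper()
    k = len(seq)
    if k % 2 != 0:
        raise ValidationError(f"palindrome analysis requires even length, got {k}")
    if set(seq) - set(ALPHABET):
        raise ValidationError(f"ambiguous base in sequence {seq!r}")
    comp = seq.translate(_COMPLEMENT)
    matches = tuple(seq[i] == comp[k - 1 - i] for i in range(k // 2))
    return PalindromeReport(sequence=seq, matches=matches)


def degenerate_match(seq: str, pattern: str) -> tuple[bool, int]:
    """Match a sequence against an IUPAC degenerate pattern.

    Returns ``(full_match, mismatch_count)`` where a position matches iff the
    base is in the expansion of the pattern's code (N = any, W = A/T, ...).
    """
    seq = seq.upper()
    pattern = pattern.upper()
    if len(seq) != len(pattern):
        raise ValidationError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    mismatches = 0
    for base, code in zip(seq, pattern):
        try:
            allowed = IUPAC_CODES[code]
        except KeyError:
            raise ValidationError(f"invalid IUPAC code {code!r} in pattern") from None
        if base not in allowed:
            mismatches += 1
    return mismatches == 0, mismatches
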