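"""Ground-truthed synthetic inputs for the scanning pipeline.

The generators emulate the statistical structure the PSSM model assumes:

* training sites are drawn column-independently from a stated 4 x k
  frequency matrix (product-multinomial — no dinucleotide correlation, to
  match the additive scoring model);
* background genomes are i.i.d. draws from a stated base composition;
* motif instances are *substituted* (not inserted) at known, non-overlapping
  positions, preserving genome length and all downstream coordinates.

A fixed seed makes every generator byte-reproducible, so benchmarks double
as regression fixtures.  The default motif emulates a catabolite-control
(cre-type) operator: a 14-position partial palindrome following the pattern
TGNAANCGNWNNCW, with ~0.94 weight on each determined base and an A/T-split
at the W positions, giving a total information content just over 12 bits —
enough for planted sites to stand clear of the background score maximum in
genomes up to ~1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motif import (
    ALPHABET,
    BackgroundModel,
    FrequencyMatrix,
    SiteCollection,
    ValidationError,
    build_count_matrix,
    reverse_complement,
    to_frequencies,
)
from .scan import GenomeSequence, HitTable

__all__ = [
    "SyntheticSpec",
    "SyntheticBenchmark",
    "cre_like_frequency_matrix",
    "sample_sites",
    "synth_genome",
    "plant_sites",
    "make_benchmark",
    "recovery_report",
]

_CRE_CONSENSUS_PATTERN = "TGNAANCGNWNNCW"


def cre_like_frequency_matrix(
    strong: float = 0.94, weak_split: float = 0.47
) -> FrequencyMatrix:
    """Frequency matrix of a cre-type operator motif (width 14).

    Determined positions put ``strong`` on the consensus base (remainder
    split evenly); W positions put ``weak_split`` on each of A and T; N
    positions are uniform.
    """
    cols = []
    rest = (1.0 - strong) / 3.0
    other = (1.0 - 2 * weak_split) / 2.0
    for code in _CRE_CONSENSUS_PATTERN:
        if code == "N":
            cols.append([0.25, 0.25, 0.25, 0.25])
        elif code == "W":
            cols.append([weak_split, other, other, weak_split])
        else:
            col = [rest] * 4
            col[ALPHABET.index(code)] = strong
            cols.append(col)
    return FrequencyMatrix(f=np.array(cols).T, pseudocount=0.0, n_sites=0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to regenerate one benchmark deterministically."""

    freqs: FrequencyMatrix
    n_sites: int = 44
    genome_length: int = 100_000
    background: BackgroundModel = field(default_factory=BackgroundModel.uniform)
    n_planted: int = 10
    positions: Sequence[int] | str = "random"
    strand_policy: str = "forward"
    seed: int = 0

    def __post_init__(self):
        if self.n_planted * self.freqs.width > self.genome_length:
            raise ValidationError("planted sites cannot fit in the genome")


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Generated sites + genome + planted-site truth, with provenance."""

    spec: SyntheticSpec
    sites: SiteCollection
    genome: GenomeSequence
    truth: tuple[tuple[int, str, str], ...]  # (1-based start, strand, sequence)

    @property
    def truth_starts(self) -> tuple[int, ...]:
        return tuple(t[0] for t in self.truth)


def _check_freqs(freqs: FrequencyMatrix) -> np.ndarray:
    f = np.asarray(freqs.f, float)
    return f


def sample_sites(
    freqs: FrequencyMatrix, n: int, seed: int | np.random.Generator = 0
) -> SiteCollection:
    """Draw n sites, each position independently from its column distribution."""
    if n < 1:
        raise ValidationError(f"need n >= 1 sites, got {n}")
    f = _check_freqs(freqs)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = f.shape[1]
    # one multinomial draw per (site, position) via inverse-CDF on uniforms
    cdf = np.cumsum(f, axis=0)
    u = rng.random((n, k))
    idx = (u[:, None, :] > cdf[None, :, :]).sum(axis=1)
    sites = ["".join(ALPHABET[b] for b in row) for row in idx]
    return SiteCollection(sites, source_label=f"synthetic(n={n})")


def synth_genome(
    length: int,
    background: BackgroundModel | None = None,
    seed: int | np.random.Generator = 0,
    identifier: str = "synthetic_contig",
) -> GenomeSequence:
    """I.i.d. background sequence of the given length."""
    if length < 1:
        raise ValidationError(f"genome length must be >= 1, got {length}")
    if background is None:
        background = BackgroundModel.uniform()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(4, size=length, p=background.p)
    seq = "".join(ALPHABET[b] for b in idx)
    return GenomeSequence(identifier=identifier, sequence=seq)


def plant_sites(
    genome: GenomeSequence,
    freqs: FrequencyMatrix,
    m: int,
    positions: Sequence[int] | str = "random",
    strand_policy: str = "forward",
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> tuple[GenomeSequence, tuple[tuple[int, str, str], ...]]:
    """Substitute m motif draws into a genome at recorded 1-based positions.

    ``positions`` is either explicit 1-based starts or ``"random"`` for
    uniform non-overlapping placement (bounded rejection sampling).
    ``strand_policy``: "forward" plants the drawn site as-is, "random"
    reverse-complements each with probability 1/2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = freqs.width
    L = genome.length
    if strand_policy not in ("forward", "random"):
        raise ValidationError(f"unknown strand_policy {strand_policy!r}")
    if m == 0:
        return genome, ()
    if isinstance(positions, str):
        if positions != "random":
            raise ValidationError(f"unknown position policy {positions!r}")
        starts: list[int] = []
        tries = 0
        while len(starts) < m:
            cand = int(rng.integers(1, L - k + 2))
            if all(abs(cand - s) >= k for s in starts):
                starts.append(cand)
            tries += 1
            if tries > max_tries * m:
                raise ValidationError(
                    f"could not place {m} non-overlapping sites in {tries} tries"
                )
    else:
        starts = [int(s) for s in positions]
        if len(starts) != m:
            raise ValidationError("number of positions != m")
        ordered = sorted(starts)
        for a, b in zip(ordered, ordered[1:]):
            if b - a < k:
                raise ValidationError(f"planted sites at {a} and {b} overlap")
        if ordered[0] < 1 or ordered[-1] + k - 1 > L:
            raise ValidationError("planted site outside the genome")
    drawn = sample_sites(freqs, m, seed=rng)
    seq = list(genome.sequence)
    truth = []
    for start, site in zip(starts, drawn):
        strand = "+"
        planted = site
        if strand_policy == "random" and rng.random() < 0.5:
            strand = "-"
            planted = reverse_complement(site)
        seq[start - 1 : start - 1 + k] = planted
        truth.append((start, strand, site))
    return (
        GenomeSequence(identifier=genome.identifier, sequence="".join(seq)),
        tuple(sorted(truth)),
    )


def make_benchmark(spec: SyntheticSpec) -> SyntheticBenchmark:
    """Generate sites, genome and planted truth from one spec + seed.

    All three draws come from a single seeded generator, so the whole
    benchmark is a pure function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    sites = sample_sites(spec.freqs, spec.n_sites, seed=rng)
    genome = synth_genome(spec.genome_length, spec.background, seed=rng)
    genome, truth = plant_sites(
        genome,
        spec.freqs,
        spec.n_planted,
        positions=spec.positions,
        strand_policy=spec.strand_policy,
        seed=rng,
    )
    return SyntheticBenchmark(spec=spec, sites=sites, genome=genome, truth=truth)


def recovery_report(
    benchmark: SyntheticBenchmark,
    hits: HitTable,
    auroc_value: float | None = None,
) -> dict:
    """Compare pipeline output against the planted truth.

    Reports the fraction of planted starts present in the hit table
    (sensitivity at the table's threshold) and, by re-training a frequency
    matrix on the benchmark's sampled sites, the maximum absolute per-cell
    error against the generating matrix.
    """
    truth_starts = set(benchmark.truth_starts)
    if not truth_starts:
        sensitivity = float("nan")
    else:
        hit_starts = {h.start for h in hits if h.contig == benchmark.genome.identifier}
        sensitivity = len(truth_starts & hit_starts) / len(truth_starts)
    refit = to_frequencies(build_count_matrix(benchmark.sites), pseudocount=0.0)
    max_cell_error = float(np.abs(refit.f - benchmark.spec.freqs.f).max())
    report = {
        "n_planted": len(truth_starts),
        "threshold": hits.threshold,
        "sensitivity": sensitivity,
        "matrix_max_cell_error": max_cell_error,
    }
    if auroc_value is not None:
        report["auroc"] = float(auroc_value)
    return report
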