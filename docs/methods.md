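# Methods

## Model

`crescan` implements the standard additive (position-independent) motif
model for protein-DNA binding sites.  Given n aligned sites of width k over
{A,C,G,T}, the count matrix `c[b,i]` is smoothed and normalised,

    f[b,i] = (c[b,i] + a) / (n + 4a),

and scored against a background base distribution p as log-odds in bits,

    w[b,i] = log2(f[b,i] / p_b),     score(s) = Σ_i w[s_i, i].

Per-position conservation is the relative entropy `IC_i = Σ_b f[b,i]
log2(f[b,i]/p_b)`; under a uniform background this reduces to the familiar
logo height `2 − H(f_i)`.  Two identities anchor the implementation and its
tests: a column equal to the background scores zero everywhere, and the
expected score of background sequence is `−Σ_i KL(p ‖ f_i) ≤ 0` — genome
scans therefore have strongly negative means, and real sites stand out by
tens of bits.

The model assumes independent positions (no dinucleotide structure), sites
given in a single, pre-aligned orientation, and a 0th-order background.
Motif discovery from unaligned sequence is out of scope.

## Parameters and defaults

- **Pseudocount a = 0.5 per cell.**  With ~44 training sites this keeps all
  scores finite while perturbing observed frequencies by at most ~1%.
  `a = 0` is allowed; zero cells then either raise (strict policy) or score
  −∞ (treating an unseen base as a veto).
- **Background: uniform by default, genome-composition or explicit via
  config.**  Scores are only comparable across studies when the background
  convention is stated; both conventions are first-class here.  Note that a
  perfectly conserved k-mer scores exactly 2k bits under a uniform
  background, but can exceed 2k under a skewed genome background — a
  consensus score above 2k is the signature of a composition-adjusted
  matrix.  Estimated backgrounds floor zero probabilities at 1e-6 (with a
  warning) and renormalise.
- **Strand mode: forward-only by default** (a single-strand scan); `both`
  scores each window's reverse complement too and emits the better strand
  ('+' on ties) or both.
- **Threshold sweep: integers 9–19 bits by default**, the informative range
  for a 14-position operator matrix; any grid can be supplied.
- **Negative-set definition for ROC:** windows overlapping a known site by
  ≥ k/2 bp are excluded from the negatives (they share most of their
  sequence with a positive); a strict mode keeps every non-identical window.
  Detection uses `score ≥ threshold`, so ties count as detected.
- **Upstream annotation window: 500 bp**, a typical bacterial
  promoter-proximal span; hits inside a gene are "within CDS", otherwise the
  nearest strand-aware gene start within the window makes them "upstream".
- **Coordinates:** 1-based inclusive internally; BED I/O converts to 0-based
  half-open.  The BED score column carries raw bits (2 dp), not the 0–1000
  convention.

## Numerical choices

Scanning is streaming: chunks of 64 kb (plus k−1 overlap) are encoded to
integer indices and scored vectorised; windows containing non-ACGT bases
are skipped and counted rather than zero-scored, keeping the score
distribution clean.  Summary statistics use Welford/Chan single-pass
mean-variance merging, so the full per-window score vector is never held in
memory.  Consensus ties break lexicographically (A < C < G < T).  AUROC is
the rank-based Mann-Whitney estimator with midranks for ties; the
trapezoidal integral of a dense ROC grid agrees with it to 1e-3 in tests.

## Synthetic data: what it does and does not emulate

The generator reproduces exactly the structure the model assumes: training
sites drawn column-independently from a stated frequency matrix, i.i.d.
background genomes of stated composition, and motif draws substituted (not
inserted — lengths and downstream coordinates are preserved) at recorded,
non-overlapping positions, optionally reverse-complemented.  One seed
determines every byte of a benchmark.

The default motif emulates a 14-position cre-type operator built from the
degenerate consensus TGNAANCGNWNNCW: determined positions carry 0.94 on the
consensus base, W positions split 0.47/0.47 between A and T, N positions
are uniform — total information ≈ 12.4 bits, chosen so that planted sites
separate from the background maximum in genomes up to ~1 Mb (a motif's
top background score over N windows grows like the upper tail of the score
distribution, so ≥ 12 bits of information keeps well-drawn sites clear at
N ≈ 1e6).

Real genomes are not i.i.d.: they have skewed and locally varying
composition, repeats, and real sites co-evolve with their regulator
(correlated positions, mixed orientations).  Passing the synthetic
benchmarks shows the machinery is correct under the model's own
assumptions; it does not certify sensitivity/specificity on real genomes,
which is what the ROC calibration against a genome with curated sites is
for.

Test and benchmark problem sizes (44 training sites, 50–100 kb genomes,
10 planted sites, 1e4 sites for recovery checks) mirror the study
conditions the pipeline targets while keeping the whole suite in seconds.

## Design notes

- The published supplementary scoring matrix for the CcpA/GlyR3 study is
  not redistributed here; the TSV loader (`pos A C G T` layout or its
  transpose, auto-detected; JASPAR counts also supported) reproduces
  printed site scores directly when a user supplies such a matrix.  All
  matrix round-trips are exact to 6 decimals.
- Palindrome counting compares each left-half base to the complement of its
  mirror position; the count is invariant under reverse complement, and
  requires even width (odd-width input is an error, not a truncation).
- Training sites must be pure ACGT; degenerate codes appear only in
  consensus patterns, with full IUPAC support in `degenerate_match`.

## Known limitations

Single-motif, fixed-width scanning only; no higher-order background, no
positional priors, no EM/Gibbs discovery, no p-value calibration of scores
(thresholds are calibrated empirically by ROC instead).  AUROC on heavily
imbalanced genome scans is dominated by the negative class; the per-point
TPR/FPR table is the more interpretable output.
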