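# crescan

Cross-species discovery of bacterial operator binding sites with
position-specific scoring matrices (PSSMs).

## The problem

Carbon-catabolite regulators of the LacI family — CcpA in *Bacillus
subtilis*, GlyR3 in *Clostridium thermocellum* — bind short, partially
palindromic DNA operators (cre-type sites, width 14).  When a regulator's
own binding sites are unknown but a homolog's are well catalogued, the
homolog's sites can train a scoring matrix that is then used to scan the
target genome for candidate operators.  `crescan` implements that pipeline
for anyone doing bacterial regulatory-site prediction:

1. **build** — tally a collection of aligned known sites into counts,
   smooth with a pseudocount, and form the log-odds matrix
   `w[b,i] = log2(f[b,i] / p_b)` in bits, with per-position information
   content `IC_i = Σ_b f[b,i]·log2(f[b,i]/p_b)`;
2. **calibrate** — sweep a score threshold over the source genome, where the
   known sites provide labels, and report the ROC curve (TPR/FPR per
   threshold, rank-based AUROC) plus an operating point (Youden's J, an FPR
   ceiling, or a fixed threshold);
3. **scan** — score every k-mer window of a target genome (streaming, either
   strand), call hits above threshold, and write BED;
4. **characterise** — annotate hits against a gene table (within CDS /
   upstream / intergenic), count palindromic (dyad-symmetric) positions,
   and match against a degenerate IUPAC consensus such as `TGNAANCGNWNNCW`.

A seeded synthetic-data generator (sites drawn column-independently from a
stated frequency matrix; i.i.d. background genomes; motif instances planted
at recorded coordinates) makes every stage testable against ground truth.

## Worked example

```python
from crescan import *

bench = make_benchmark(SyntheticSpec(freqs=cre_like_frequency_matrix(), seed=0))
pssm  = build_pssm(to_frequencies(build_count_matrix(bench.sites), 0.5))
windows = list(scan(pssm, bench.genome))
labeled = label_windows(windows, [(bench.genome.identifier, s)
                                  for s in bench.truth_starts], motif_width=14)
hits = call_hits(iter(windows), threshold=5.0)
print(recovery_report(bench, hits, auroc(labeled)))
```

prints

```
{'n_planted': 10, 'threshold': 5.0, 'sensitivity': 0.9,
 'matrix_max_cell_error': 0.1818..., 'auroc': 0.9981...}
```

meaning: of 10 operator instances planted in a 100 kb genome, 9 score at or
above 5 bits (the tenth drew an unusually degenerate sequence from the
motif model); the matrix re-trained from only 44 sampled sites misestimates
the worst cell of the generating frequency matrix by 0.18; and a random
planted site outscores a random background window 99.8% of the time.

Dyad symmetry of four known/candidate GlyR3-type operators:

```sh
$ crescan palindrome TGAAAGCGCTTTCA TGAACGCGCGTACA TGTAAACGGTGTCA GTAAATCGGTTGCA
sequence        half_width      count   matches
TGAAAGCGCTTTCA  7       7       1111111
TGAACGCGCGTACA  7       6       1111110
TGTAAACGGTGTCA  7       4       1101100
GTAAATCGGTTGCA  7       3       0101100
```

The same stages are available as CLI subcommands (`crescan build / scan /
roc / simulate / palindrome`; exit code 2 on validation errors), and the
`examples/` directory holds one short narrative script per capability.

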