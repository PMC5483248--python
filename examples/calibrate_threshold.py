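"""Calibrate a detection threshold by ROC analysis on a genome with known sites.

Sweeps integer thresholds 9..19 bits over a benchmark genome whose true
site positions are known, printing TPR/FPR per threshold, the AUROC, and
the Youden-optimal operating point.
"""

from crescan import (
    SyntheticSpec,
    build_count_matrix,
    build_pssm,
    choose_threshold,
    cre_like_frequency_matrix,
    label_windows,
    make_benchmark,
    roc_curve,
    scan,
    to_frequencies,
)

bench = make_benchmark(SyntheticSpec(freqs=cre_like_frequency_matrix(), seed=2))
pssm = build_pssm(to_frequencies(build_count_matrix(bench.sites), 0.5))
windows = list(scan(pssm, bench.genome))
labeled = label_windows(
    windows,
    [(bench.genome.identifier, s) for s in bench.truth_starts],
    motif_width=14,
)

curve = roc_curve(labeled, range(9, 20))
print("threshold  TPR    FPR")
for p in curve:
    print(f"{p.threshold:9.0f}  {p.tpr:.2f}  {p.fpr:.6f}")
print(f"AUROC {curve.auroc:.4f}")

fine = roc_curve(labeled, [x / 2 for x in range(-60, 60)])
best = choose_threshold(fine, "youden")
print(f"Youden threshold {best.threshold:g} bits -> TPR {best.tpr:.2f}, "
      f"FPR {best.fpr:.6f}")
# Raising the threshold trades sensitivity (TPR) for specificity (1-FPR);
# the Youden point maximises TPR - FPR.
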