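"""Dyad-symmetry analysis of candidate operator sequences.

LacI-family repressors bind as dimers, so their operators tend toward
inverted-repeat (palindromic) structure.  For each 14-mer we count the
left-half positions whose base Watson-Crick-pairs with the mirrored
right-half base, and check the sequence against the degenerate cre
consensus TGNAANCGNWNNCW.
"""

from crescan import degenerate_match, palindrome_positions

candidates = {
    "optimum": "TGAAAGCGCTTTCA",
    "celC": "TGAACGCGCGTACA",
    "manB": "TGTAAACGGTGTCA",
    "celT": "GTAAATCGGTTGCA",
}

print("site     sequence         palindrome  consensus-mismatches")
for name, seq in candidates.items():
    rep = palindrome_positions(seq)
    _, mism = degenerate_match(seq, "TGNAANCGNWNNCW")
    print(f"{name:8s} {seq}  {rep.count}/{rep.half_width}         {mism}")
# Higher palindrome counts indicate stronger dyad symmetry — the optimum
# sequence is a perfect 7/7 palindrome, weaker candidates drop toward 3/7.
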