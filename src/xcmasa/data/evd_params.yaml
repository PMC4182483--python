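# Constants of the expectation function EF(R_M) = theta * exp(a*R_M - b*n - c).
# a: slope in RMSD (1/Angstrom, must be > 0); b: per-matched-residue penalty;
# c: scale offset.  Calibration rationale: docs/methods.md, "Match significance".
a: 12.0
b: 3.6
c: -1.0
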