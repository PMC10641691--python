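"""Build every relationship matrix of the analysis: pedigree A and its
inverse, pedigree dominance D, genomic additive G_A and dominance G_D on
the QC'ed genotypes, and the single-step blend H.
"""

import numpy as np

from common import RESULTS, load_program

from rrsgs import (
    MarkerMatrix,
    build_A,
    build_A_inverse,
    build_D_pedigree,
    build_GA,
    build_GD,
    build_H,
    build_H_inverse,
)

program = load_program()
genotypes = MarkerMatrix.read_csv(RESULTS / "genotypes_qc.csv")

A = build_A(program.pedigree)
Ainv = build_A_inverse(program.pedigree)
D = build_D_pedigree(program.pedigree)
GA = build_GA(genotypes)
GD = build_GD(genotypes)
H = build_H(A, GA, genotypes.ids)
Hinv = build_H_inverse(A, GA, genotypes.ids, tau=1.0)

for name, K in [("A", A), ("GA", GA), ("GD", GD), ("H", H)]:
    K.write_csv(RESULTS / f"kinship_{name}.csv")

print(f"A: {len(A.ids)} ids, mean diagonal {np.diag(A.values).mean():.3f}")
print(f"G_A: {len(GA.ids)} genotyped ids, mean diagonal {np.diag(GA.values).mean():.3f}")
print(f"G_D: mean diagonal {np.diag(GD.values).mean():.3f}")
print(f"H: blends {len(A.ids) - len(GA.ids)} ungenotyped with {len(GA.ids)} genotyped")
print(f"max |A^-1 A - I| = {np.abs(Ainv.values @ A.values - np.eye(len(A.ids))).max():.2e}")
idx = [A._index[i] for i in GA.ids]
A22 = A.values[np.ix_(idx, idx)]
print(f"mean(G_A - A22) = {np.mean(GA.values - A22):+.4f} "
      "(genomic matrix estimating pedigree expectation)")
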