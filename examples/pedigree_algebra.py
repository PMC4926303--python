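"""Pedigree algebra on a toy herd: inbreeding, relationships, A-inverse.

Builds a five-animal pedigree containing a full-sib mating, then prints the
inbreeding coefficients (the full-sib offspring must come out at F = 0.25),
the numerator relationship matrix, and the per-generation inbreeding rate
for a pair of mean-F values.
"""

import numpy as np

from polledsim import (
    FEMALE,
    MALE,
    Pedigree,
    a_inverse,
    delta_f,
    inbreeding_coefficients,
    relationship_matrix,
)

ped = Pedigree()
ped.add_animals(0, 0, [MALE, FEMALE], 0, [0.0, 0.0])          # unrelated founders
ped.add_animals([1, 1], [2, 2], [MALE, FEMALE], 1, [0.0, 0.0])  # full sibs
ped.add_animals(3, 4, MALE, 2, 0.0)                            # full-sib mating

f = inbreeding_coefficients(ped)
print("inbreeding coefficients:", np.round(f, 4))
print("  -> the offspring of two full sibs is inbred at F = 0.25")

a = relationship_matrix(ped)
print("\nnumerator relationship matrix A:")
print(np.round(a, 3))
print("  -> a_ii = 1 + F_i; full sibs are related at a = 0.5")

ainv = a_inverse(ped).toarray()
print("\nmax |A @ A^-1 - I| =", np.abs(ainv @ a - np.eye(5)).max())

rate = delta_f(0.1249, 0.1210)
print(f"\ndelta_F from mean F 0.1210 -> 0.1249: {rate:.4%} per generation")
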