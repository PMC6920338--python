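"""Deduce in-silico hybrid genotypes from inbred parents.

Builds a tiny parent panel, filters markers on minor allele frequency and
missingness, and derives F1 hybrid codes as parental means.
"""

import numpy as np

from hybridgs import (GenotypeMatrix, MarkerFilterSpec, build_hybrid_matrix,
                      deduce_hybrid_code, filter_markers)

# single-locus worked examples: hybrid code is the parental mean
print("A1A1 x A1A2 ->", deduce_hybrid_code(-1, 0))   # -0.5
print("A2A2 x A1A2 ->", deduce_hybrid_code(1, 0))    # 0.5
print("A1A2 x A1A2 ->", deduce_hybrid_code(0, 0))    # 0.0

# a 5-marker, 4-parent panel; one rare and one gappy marker will be dropped
codes = np.array([
    [-1, -1, 1, 1],
    [-1, 1, -1, 1],
    [-1, -1, -1, -1],            # monomorphic: MAF 0
    [1, np.nan, np.nan, -1],     # 50% missing
    [1, -1, 1, -1],
])
parents = GenotypeMatrix(codes, [f"m{k}" for k in range(5)],
                         ["P1", "P2", "P3", "P4"])
kept, report = filter_markers(parents, MarkerFilterSpec(maf_min=0.1, missing_max=0.25))
print(f"\nmarker QC: kept {report.n_kept}/{report.n_input} "
      f"(MAF fails: {report.n_failed_maf}, missingness fails: {report.n_failed_missing})")

hybrids = build_hybrid_matrix(kept, [("P1", "P2"), ("P1", "P3"), ("P2", "P4")])
print("\nhybrid codes (markers x hybrids):")
print(hybrids.individual_ids)
print(hybrids.codes)
# each column is an F1: e.g. P1 x P2 at m0 is (-1 + -1)/2 = -1
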