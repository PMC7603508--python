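#!/usr/bin/env python
"""Closed-form GEBV precision grid over training size N = {10, 269, 534,
1000}, effective loci M in [1, 1e6], and h2 = {0.5, 0.8}, with trait-
architecture classes and the very-high (>= 0.8) precision flag."""

from common import outdir
from refpop import precision

out = outdir("precision")
grid = precision.precision_grid()
grid.to_csv(out / "precision_grid.tsv", sep="\t", index=False)

for N in (10, 269, 534, 1000):
    for h2 in (0.5, 0.8):
        sub = grid[(grid.N == N) & (grid.h2 == h2) & grid.very_high]
        m_max = sub.M.max() if len(sub) else 0
        print(f"N={N:5d} h2={h2}: very-high precision up to M={m_max} "
              f"({precision.classify_architecture(max(m_max, 1))})")
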