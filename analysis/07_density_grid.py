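#!/usr/bin/env python
"""SNP-density experiment on the harvest-like trait: GWAS region counts
and cross-validated predictive ability over evenly spaced subsets
(default ladder truncated to the panel, 5 seeds each), plus the scaffold
panel and the LD-thinned panel as alternative feature selections."""

import pandas as pd

from common import SEED, RESULTS, desk_population, outdir
from refpop.densitygrid import DensityExperimentSpec, run_grid

out = outdir("density_grid")
sim = desk_population()
panel = sim.panel
lsm = pd.read_csv(RESULTS / "phenotypes" / "lsmeans.csv")
y = (lsm[lsm.trait == "harvest"].set_index("genotype")["lsmean"]
     .reindex(panel.ids).to_numpy())

spec = DensityExperimentSpec(seeds_per_density=5, cv_repetitions=10)
res = run_grid(panel, y, spec, scaffold_idx=sim.scaffold_idx, seed=SEED)
res.per_run.to_csv(out / "per_run.tsv", sep="\t", index=False)
res.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
print(res.summary.to_string(index=False))
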