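#!/usr/bin/env python
"""Simulate the desk-scale reference population and write its artifacts.

Outputs (results/simulation/): phased full-density VCF, scaffold VCF,
marker map TSV, 3-column pedigree TSV, tree-level phenotype CSV, and a
ground-truth summary JSON."""

import json

from common import desk_population, outdir
from refpop import ioformats

out = outdir("simulation")
sim = desk_population()

ioformats.write_vcf(sim.panel, out / "full.vcf",
                    haplotypes=sim.haplotypes.haplotypes)
ioformats.write_vcf(sim.scaffold, out / "scaffold.vcf")
ioformats.write_marker_map(sim.panel, out / "map.tsv")
ioformats.write_pedigree(sim.pedigree, out / "pedigree.tsv")
ioformats.write_phenotypes(sim.phenotypes, out / "phenotypes.csv")

truth_summary = {
    t: {"n_causal": len(tr.causal_idx),
        "realized_fractions": {k: round(float(v), 4)
                               for k, v in tr.realized_fractions.items()}}
    for t, tr in sim.truth.items()
}
(out / "truth.json").write_text(json.dumps(truth_summary, indent=1) + "\n")

print(f"population: {sim.panel.n_individuals} genotypes "
      f"({sum(1 for t in sim.panel.group['type'] if t == 'accession')} founders, "
      f"{len(sim.pedigree.families())} families)")
print(f"markers: {sim.panel.n_markers} full / {sim.scaffold.n_markers} scaffold")
print(f"phenotype records: {len(sim.phenotypes)}")
print("realized variance fractions:",
      json.dumps(truth_summary, indent=1))
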