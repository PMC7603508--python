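"""Shared setup for the numbered analysis drivers: one desk-scale
population (seed 1) and the results directory."""

from pathlib import Path

from refpop import simdata

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def desk_population() -> simdata.SimResult:
    """Desk-scale analogue of the reference population: ~540 genotypes
    (269 founders in 10 origin groups + 27 full-sib families), 20,000 SNPs
    on 17 chromosomes, 1,000-SNP scaffold, 6 environments x 2 blocks, and
    two phenology-like traits."""
    cfg = simdata.SimConfig(
        seed=SEED,
        trait_specs=[
            simdata.TraitSpec("harvest"),
            simdata.TraitSpec("floral", n_causal=400,
                              var_fraction_genotype=0.22,
                              var_fraction_environment=0.43,
                              var_fraction_gxe=0.18,
                              var_fraction_spatial=0.05,
                              var_fraction_residual=0.12,
                              trait_offset_days=110.0),
        ])
    return simdata.simulate_population(cfg)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
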