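"""End-to-end orchestration: simulate -> impute -> LD -> structure ->
phenotypes -> GWAS -> prediction -> density grid -> precision.

Stages communicate only through on-disk artifacts under the output
directory (no hidden state), so partial reruns are possible; the manifest
records per-stage outputs, content hashes, seeds and wall time. Identical
config and seed give a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gpred, gwas, imputeval, ld, pheno, precision, structure
from .densitygrid import DensityExperimentSpec, run_grid
from .ioformats import (write_marker_map, write_pedigree, write_phenotypes,
                        write_vcf)
from .simdata import SimConfig, simulate_population


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(config: SimConfig, outdir, density_spec: DensityExperimentSpec | None = None,
            cv_repetitions: int = 10) -> dict:
    """Run every stage at desk scale; returns the consolidated report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {"seed": config.seed}

    def stage(name, fn):
        t0 = time.time()
        outputs = fn()
        manifest.append({
            "stage": name, "wall_s": round(time.time() - t0, 2),
            "outputs": {str(p): _hash_file(Path(p)) for p in outputs},
        })

    # 1. simulate
    sim = simulate_population(config)

    def s_sim():
        write_vcf(sim.panel, outdir / "full.vcf", haplotypes=sim.haplotypes.haplotypes)
        write_vcf(sim.scaffold, outdir / "scaffold.vcf")
        write_marker_map(sim.panel, outdir / "map.tsv")
        write_pedigree(sim.pedigree, outdir / "pedigree.tsv")
        write_phenotypes(sim.phenotypes, outdir / "phenotypes.csv")
        report["simulate"] = {
            "n_individuals": sim.panel.n_individuals,
            "n_markers": sim.panel.n_markers,
            "n_scaffold": sim.scaffold.n_markers,
            "traits": [t.name for t in config.trait_specs],
        }
        return [outdir / f for f in
                ["full.vcf", "scaffold.vcf", "map.tsv", "pedigree.tsv", "phenotypes.csv"]]

    stage("simulate", s_sim)

    # 2. imputation evaluation
    def s_impute():
        res = imputeval.evaluate_family_imputation(sim)
        payload = {
            "accuracy_individuals": res.accuracy_individuals,
            "accuracy_markers": res.accuracy_markers,
            "fraction_imputed_pct": res.fraction_imputed,
            "n_flagged_mendelian": res.n_flagged_mendelian,
        }
        report["impute"] = payload
        p = outdir / "impute.json"
        p.write_text(json.dumps(payload, indent=1) + "\n")
        return [p]

    stage("impute", s_impute)

    # 3. LD
    def s_ld():
        pairs = ld.sample_pairs(sim.panel, seed=config.seed)
        dec = ld.decay_summary(pairs)
        payload = {
            "n_pairs": len(pairs),
            "threshold_distance_bp": dec.threshold_distance,
            "windowed_means": dec.windowed_means,
        }
        report["ld"] = payload
        p = outdir / "ld.json"
        p.write_text(json.dumps(payload, indent=1) + "\n")
        return [p]

    stage("ld", s_ld)

    # 4. structure
    def s_structure():
        acc_rows = [i for i, t in enumerate(sim.panel.group["type"]) if t == "accession"]
        prog_rows = [i for i, t in enumerate(sim.panel.group["type"]) if t == "progeny"]
        acc = sim.panel.subset_individuals(acc_rows)
        prog = sim.panel.subset_individuals(prog_rows)
        d = structure.distance(acc)
        newick = structure.nj_tree(d)
        (outdir / "nj.nwk").write_text(newick + "\n")
        model, supp = structure.pca_project(acc, prog, n_components=5)
        scores = pd.DataFrame(
            np.vstack([model.active_scores, supp]),
            columns=[f"PC{i+1}" for i in range(model.active_scores.shape[1])],
        )
        scores.insert(0, "individual", list(acc.ids) + list(prog.ids))
        scores["group"] = ["accession"] * len(acc.ids) + ["progeny"] * len(prog.ids)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
        report["structure"] = {
            "pc_variance_pct": (100 * model.explained_variance_ratio[:2]).tolist(),
        }
        return [outdir / "nj.nwk", outdir / "pca_scores.tsv"]

    stage("structure", s_structure)

    # 5. phenotypes: spatial adjustment, heritability, LS-means
    lsmeans_by_trait: dict[str, pd.Series] = {}

    def s_pheno():
        fits, adjusted = pheno.spatial_adjust_all(sim.phenotypes)
        write_phenotypes(adjusted, outdir / "adjusted.csv")
        rep = {}
        for spec in config.trait_specs:
            tr = spec.name
            h2_env = {env: pheno.h2_individual(adjusted, env, tr)
                      for env in adjusted.environments()}
            keep = pheno.exclude_low_h2(h2_env)
            sub = pheno.TreeRecordTable(
                adjusted.df[adjusted.df["environment"].isin(keep)])
            vd, h2m = pheno.fit_multienv(sub, tr, compute_ci=False)
            lsm = pheno.ls_means(sub, keep, tr)
            lsmeans_by_trait[tr] = lsm.set_index("genotype")["lsmean"]
            rep[tr] = {
                "h2_individual": {e: r.H2 for e, r in h2_env.items()},
                "environments_retained": keep,
                "h2_multi": h2m.H2,
                "variance_fractions": vd.fractions,
            }
        lsall = pd.concat(
            [pd.DataFrame({"genotype": s.index, "trait": t, "lsmean": s.values})
             for t, s in lsmeans_by_trait.items()], ignore_index=True)
        lsall.to_csv(outdir / "lsmeans.csv", index=False)
        report["pheno"] = rep
        return [outdir / "adjusted.csv", outdir / "lsmeans.csv"]

    stage("pheno", s_pheno)

    # 6/7. GWAS + prediction per trait
    K = gwas.kinship(sim.panel)

    def s_assoc():
        rep = {}
        paths = []
        for tr, lsm in lsmeans_by_trait.items():
            y = lsm.reindex(sim.panel.ids).to_numpy(float)
            scan = gwas.mlmm_scan(sim.panel, y, K)
            scan.regions.to_csv(outdir / f"gwas_{tr}.tsv", sep="\t", index=False)
            cv = gpred.cross_validate(sim.panel.dosage.astype(float), y,
                                      repetitions=cv_repetitions, seed=config.seed)
            rep[tr] = {
                "n_regions": len(scan.regions),
                "alpha_star": scan.alpha_star,
                "cofactors": scan.cofactors,
                "predictive_ability": cv.mean_ability,
            }
            paths.append(outdir / f"gwas_{tr}.tsv")
        report["assoc"] = rep
        return paths

    stage("gwas+predict", s_assoc)

    # 8. density grid (first trait)
    def s_grid():
        spec = density_spec or DensityExperimentSpec(
            densities=(500, 1000, 2500, 5000, 10000, 20000),
            seeds_per_density=3, cv_repetitions=5)
        tr = config.trait_specs[0].name
        y = lsmeans_by_trait[tr].reindex(sim.panel.ids).to_numpy(float)
        res = run_grid(sim.panel, y, spec, K=K, scaffold_idx=sim.scaffold_idx,
                       seed=config.seed)
        res.per_run.to_csv(outdir / "density_grid.tsv", sep="\t", index=False)
        res.summary.to_csv(outdir / "density_summary.tsv", sep="\t", index=False)
        report["density_grid"] = {
            "trait": tr,
            "summary": res.summary.to_dict(orient="records"),
        }
        return [outdir / "density_grid.tsv", outdir / "density_summary.tsv"]

    stage("density_grid", s_grid)

    # 9. precision
    def s_precision():
        grid = precision.precision_grid()
        grid.to_csv(outdir / "precision_grid.tsv", sep="\t", index=False)
        report["precision"] = {
            "very_high_threshold": precision.VERY_HIGH,
            "examples": {
                "N10_M10_h08": precision.precision(10, 10, 0.8),
                "N269_M100_h08": precision.precision(269, 100, 0.8),
                "N534_M100_h05": precision.precision(534, 100, 0.5),
            },
        }
        return [outdir / "precision_grid.tsv"]

    stage("precision", s_precision)

    report["config"] = asdict(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_js) + "\n")
    return report


def _js(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))
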