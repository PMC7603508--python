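"""On-disk formats: VCF genotypes, TSV pedigree/marker map, CSV phenotypes, JSON results.

VCF is read through cyvcf2 and restricted to a GT-only biallelic-SNP dialect;
multi-allelic or non-SNP records are rejected and counted. Writers are plain
deterministic text emitters. Positions are 1-based (VCF convention),
chromosome labels "1".."17", distances in bp.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import MISSING, GenotypePanel, Pedigree, PedigreeRecord, TreeRecordTable

log = logging.getLogger("refpop")


# ----------------------------------------------------------------- VCF

def write_vcf(panel: GenotypePanel, path, haplotypes: np.ndarray | None = None) -> None:
    """Write a GT-only VCF 4.2 file.

    If ``haplotypes`` (n, 2, m binary) is given, genotypes are written phased
    ("0|1"); otherwise unphased with the conventional het ordering "0/1".
    REF/ALT are fixed placeholder alleles (A/C): only dosages carry signal.
    """
    path = Path(path)
    n, m = panel.dosage.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.ids) + "\n")
        for j in range(m):
            fields = [
                str(panel.chrom[j]), str(panel.pos[j]), str(panel.marker_ids[j]),
                "A", "C", ".", "PASS", ".", "GT",
            ]
            if haplotypes is not None:
                gts = [f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}" for i in range(n)]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(panel.dosage[i, j])] for i in range(n)]
            fh.write("\t".join(fields + gts) + "\n")


def read_vcf(path, tier: str = "full") -> GenotypePanel:
    """Read a biallelic-SNP GT-only VCF into a :class:`GenotypePanel`.

    Multi-allelic and non-SNP records are skipped; the count is logged.
    Missing genotypes are only accepted for ``tier="scaffold"``.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc
    ids = list(vcf.samples)
    chrom, pos, mids, rows = [], [], [], []
    n_rejected = 0
    for lineno, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_rejected += 1
            continue
        g = np.asarray(v.gt_types, dtype=np.int16)  # 0/1/2 dosage, 3 missing
        g[g == 3] = MISSING
        if tier == "full" and (g == MISSING).any():
            raise ValueError(f"missing genotype in full-tier VCF at record {lineno} ({v.ID})")
        chrom.append(str(v.CHROM))
        pos.append(v.POS)
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        rows.append(g)
    if n_rejected:
        log.info("read_vcf: rejected %d multi-allelic/non-SNP records", n_rejected)
    dosage = (
        np.array(rows, dtype=np.int16).T
        if rows
        else np.zeros((len(ids), 0), dtype=np.int16)
    )
    return GenotypePanel(
        ids=ids,
        dosage=dosage,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        marker_ids=np.array(mids, dtype=object),
        tier=tier,
    )


# ------------------------------------------------------- TSV / CSV

def write_marker_map(panel: GenotypePanel, path) -> None:
    panel.marker_map().to_csv(path, sep="\t", index=False)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tmother\tfather\n")
        for r in ped.records:
            fh.write(f"{r.id}\t{r.mother or ''}\t{r.father or ''}\n")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = [
        PedigreeRecord(row["id"], row["mother"] or None, row["father"] or None)
        for _, row in df.iterrows()
    ]
    return Pedigree(records)


def write_phenotypes(table: TreeRecordTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_phenotypes(path) -> TreeRecordTable:
    return TreeRecordTable(pd.read_csv(path))


# ------------------------------------------------------------- JSON

def write_results(path, stage: str, params: dict, seed, metrics: dict) -> None:
    """Uniform results record: {stage, params, seed, metrics}."""
    payload = {"stage": stage, "params": params, "seed": seed, "metrics": metrics}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonable, sort_keys=True)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
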