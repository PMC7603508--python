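"""Shared in-memory containers for the pipeline.

Three containers move between all stages: a :class:`GenotypePanel`
(individuals x biallelic SNP dosages with a physical marker map), a
:class:`Pedigree` (individual/mother/father triples), and a
:class:`TreeRecordTable` (per-tree phenotypes with field coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel, legal only on scaffold-tier panels


@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix with a sorted marker map.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers, row order of ``dosage``.
    dosage : ndarray of shape (n_individuals, n_markers)
        Alternate-allele counts in {0, 1, 2}; ``MISSING`` (-1) marks
        unobserved values and is only legal when ``tier == "scaffold"``.
    chrom : ndarray of str
        Chromosome label per marker ("1".."17").
    pos : ndarray of int
        1-based physical position (bp) per marker.
    marker_ids : ndarray of str
        Unique marker identifiers.
    group : dict
        Optional per-individual labels, e.g. ``{"type": [...], "origin": [...]}``.
    tier : str
        "full" or "scaffold".
    """

    ids: list[str]
    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    marker_ids: np.ndarray
    group: dict = field(default_factory=dict)
    tier: str = "full"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.validate()

    # -- contracts -----------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} dosage rows")
        if not (len(self.chrom) == len(self.pos) == len(self.marker_ids) == m):
            raise ValueError("marker map length does not match dosage columns")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids are not unique")
        # map must be sorted by (chromosome, position); chromosomes compare
        # numerically when they look numeric
        key = [self._chrom_key(c) for c in self.chrom]
        order = sorted(range(m), key=lambda i: (key[i], self.pos[i]))
        if order != list(range(m)):
            raise ValueError("marker map is not sorted by (chromosome, position)")
        vals = np.unique(self.dosage)
        allowed = {0, 1, 2} | ({MISSING} if self.tier == "scaffold" else set())
        bad = set(np.rint(vals).astype(int)) - allowed
        if bad or (self.tier == "full" and (self.dosage == MISSING).any()):
            raise ValueError(f"illegal dosage values for tier={self.tier!r}: {sorted(bad)}")

    @staticmethod
    def _chrom_key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    # -- convenience ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "id": self.marker_ids}
        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset_markers(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            ids=list(self.ids),
            dosage=self.dosage[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            marker_ids=self.marker_ids[idx],
            group={k: list(v) for k, v in self.group.items()},
            tier=self.tier,
        )

    def subset_individuals(self, which) -> "GenotypePanel":
        if all(isinstance(w, str) for w in which):
            lookup = {g: i for i, g in enumerate(self.ids)}
            rows = [lookup[w] for w in which]
        else:
            rows = list(which)
        return GenotypePanel(
            ids=[self.ids[i] for i in rows],
            dosage=self.dosage[rows],
            chrom=self.chrom,
            pos=self.pos,
            marker_ids=self.marker_ids,
            group={k: [list(v)[i] for i in rows] for k, v in self.group.items()},
            tier=self.tier,
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (missing values excluded)."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class PedigreeRecord:
    id: str
    mother: str | None
    father: str | None


class Pedigree:
    """Acyclic id/mother/father triples; founders have null parents."""

    def __init__(self, records: list[PedigreeRecord]):
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pedigree ids: {dup}")
        known = set(ids)
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for r in self.records:
            for parent in (r.mother, r.father):
                if parent is None:
                    continue
                if parent not in known:
                    raise ValueError(f"unknown parent id {parent!r} for {r.id!r}")
                g.add_edge(parent, r.id)
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cycle}") from None
        # stable: keep file order among ties
        rank = {x: i for i, x in enumerate(order)}
        self.records.sort(key=lambda r: (rank[r.id],))
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, id_: str) -> PedigreeRecord:
        return self._by_id[id_]

    def founders(self) -> list[str]:
        return [r.id for r in self.records if r.mother is None and r.father is None]

    def progeny(self) -> list[str]:
        return [r.id for r in self.records if r.mother is not None or r.father is not None]

    def families(self) -> dict[tuple[str, str], list[str]]:
        fams: dict[tuple[str, str], list[str]] = {}
        for r in self.progeny():
            rec = self._by_id[r]
            fams.setdefault((rec.mother, rec.father), []).append(r)
        return fams


class TreeRecordTable:
    """Per-tree phenotypes: genotype, environment, block, row, col, trait, value.

    Backed by a pandas DataFrame with exactly those columns; ``value`` is a
    day-of-year number (Jan 1 = 1), real-valued by default.
    """

    COLUMNS = ["genotype", "environment", "block", "row", "col", "trait", "value"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing phenotype columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["trait", "environment", "row", "col"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate field position: trait=%s env=%s row=%d col=%d"
                % (first["trait"], first["environment"], first["row"], first["col"])
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def environments(self) -> list[str]:
        return list(dict.fromkeys(self.df["environment"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.df[self.df["trait"] == trait].reset_index(drop=True)

    def check_genotypes(self, panel: GenotypePanel) -> None:
        unknown = set(self.df["genotype"]) - set(panel.ids)
        if unknown:
            raise ValueError(f"phenotype genotypes absent from panel: {sorted(unknown)[:5]}")
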