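"""Population structure: genetic distances, neighbor-joining tree, PCA.

The accession (founder) group is the "active" set; progeny can be projected
onto the accession PCA as supplementary individuals, i.e. centered with the
active-set marker means and multiplied by the active loadings, so they do
not influence the components themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as skbio_nj
from sklearn.decomposition import PCA

from .datamodel import GenotypePanel


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v


def distance(panel: GenotypePanel, metric: str = "allele-share") -> DistanceMatrix:
    """Pairwise dissimilarity between individuals.

    "allele-share": mean over markers of |d_a - d_b| / 2, i.e. 0 for
    identical genotypes and 1 for opposite homozygotes everywhere.
    "euclidean": Euclidean distance of dosage vectors.
    """
    D = panel.dosage.astype(float)
    n = D.shape[0]
    if metric == "allele-share":
        out = np.zeros((n, n))
        for a in range(n):
            out[a] = np.abs(D - D[a]).mean(axis=1) / 2.0
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 0.0)
    elif metric == "euclidean":
        sq = (D**2).sum(axis=1)
        out = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * D @ D.T, 0.0))
        np.fill_diagonal(out, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=list(panel.ids), values=out, metric=metric)


def nj_tree(d: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree (Saitou-Nei agglomeration) as Newick.

    Negative branch lengths are clamped to zero with the length transferred
    to the adjacent branch, preserving path lengths between leaves.
    """
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = SkbioDistanceMatrix(d.values, ids=[str(i) for i in d.ids])
    tree = skbio_nj(dm, neg_as_zero=False)
    _clamp_negative_branches(tree)
    return str(tree).strip()


def _clamp_negative_branches(tree) -> None:
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            if node.parent is not None:
                sibs = [s for s in node.parent.children if s is not node]
                for s in sibs:
                    if s.length is not None:
                        s.length += -node.length
            node.length = 0.0


@dataclass
class PcaModel:
    mean: np.ndarray
    scale: np.ndarray | None
    loadings: np.ndarray                 # (m_kept, k)
    kept_markers: np.ndarray
    active_scores: np.ndarray            # (n_active, k)
    explained_variance_ratio: np.ndarray
    active_ids: list[str]


def pca_project(active: GenotypePanel, supplementary: GenotypePanel | None = None,
                n_components: int = 10, scale: bool = False
                ) -> tuple[PcaModel, np.ndarray | None]:
    """PCA of the active set; supplementary individuals projected afterwards.

    Marker centering (and optional unit-variance scaling) uses ACTIVE
    individuals only; markers constant in the active set are dropped with a
    count recorded via the model's ``kept_markers``. Supplementary scores
    are the centered (scaled) supplementary dosages times the active
    loadings.
    """
    X = active.dosage.astype(float)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0) if scale else np.arange(X.shape[1])
    X = X[:, kept]
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    mean = X.mean(axis=0)
    sc = X[:, :].std(axis=0) if scale else None
    Xc = (X - mean) / sc if scale else X - mean
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(Xc)
    model = PcaModel(
        mean=mean, scale=sc, loadings=p.components_.T, kept_markers=kept,
        active_scores=scores, explained_variance_ratio=p.explained_variance_ratio_,
        active_ids=list(active.ids),
    )
    supp_scores = None
    if supplementary is not None:
        if supplementary.n_markers != active.n_markers:
            raise ValueError("active and supplementary panels must share the marker map")
        S = supplementary.dosage.astype(float)[:, kept]
        Sc = (S - mean) / sc if scale else S - mean
        supp_scores = Sc @ model.loadings
    return model, supp_scores
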