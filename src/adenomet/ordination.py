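"""Distance matrices and ordinations with deterministic sign conventions.

Euclidean distances feed the metabolome analyses (PERMANOVA, PCA);
unweighted UniFrac (via scikit-bio) and principal coordinate analysis feed
the microbiome side.  Both PCA and PCoA fix each axis's sign so that the
sample coordinate of largest magnitude is positive, which makes leading-axis
correlations reproducible across runs (the underlying eigenvectors are only
defined up to sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix

from .data_model import FeatureTable

__all__ = [
    "OrdinationResult",
    "euclidean_distance",
    "unweighted_unifrac",
    "pca",
    "pcoa",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x axes
    axis_var_explained: np.ndarray   # nonincreasing fractions
    eigenvalues: np.ndarray          # PCoA: full spectrum incl. negatives
    method: str

    def axis(self, k: int) -> np.ndarray:
        """1-based axis accessor (axis(1) is PC1/PCo1)."""
        return self.coordinates[:, k - 1]


def _apply_sign_convention(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude coordinate is positive."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if len(col) == 0:
            continue
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def euclidean_distance(t: FeatureTable) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples; requires no missing cells."""
    if not np.isfinite(t.values).all():
        raise ValueError("euclidean_distance requires a table with no missing values")
    return DistanceMatrix(squareform(pdist(t.values)), ids=t.sample_ids)


def unweighted_unifrac(otu: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence phylogenetic beta diversity between samples.

    Presence is count > 0.  Every OTU observed in any sample must be a leaf
    of the tree, and every sample must contain at least one present OTU.
    """
    counts = np.where(otu.detected, otu.values, 0.0)
    present_any = (counts > 0).any(axis=0)
    leaf_names = {tip.name for tip in tree.tips()}
    offending = [f for f, keep in zip(otu.feature_ids, present_any)
                 if keep and f not in leaf_names]
    if offending:
        raise ValueError(f"OTUs absent from tree: {offending[:10]}")
    empty = [s for s, row in zip(otu.sample_ids, counts) if not (row > 0).any()]
    if empty:
        raise ValueError(f"samples with no present OTUs: {empty[:10]}")
    return beta_diversity(
        "unweighted_unifrac",
        counts,
        ids=otu.sample_ids,
        taxa=otu.feature_ids,
        tree=tree,
        validate=True,
    )


def pca(t: FeatureTable, n_axes: int | None = None) -> OrdinationResult:
    """Centered (not variance-scaled) principal component analysis."""
    if not np.isfinite(t.values).all():
        raise ValueError("pca requires a table with no missing values")
    X = t.values
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if m < 2:
        raise ValueError("need at least 2 features")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    eig = s ** 2 / (n - 1)
    keep = s > s.max() * 1e-12 if s.max() > 0 else np.zeros_like(s, bool)
    scores = scores[:, keep]
    eig = eig[keep]
    if n_axes is not None:
        scores = scores[:, :n_axes]
        eig_kept = eig[:n_axes]
    else:
        eig_kept = eig
    var_expl = eig_kept / eig.sum() if eig.sum() > 0 else eig_kept
    return OrdinationResult(
        sample_ids=list(t.sample_ids),
        coordinates=_apply_sign_convention(scores),
        axis_var_explained=var_expl,
        eigenvalues=eig,
        method="pca",
    )


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS) via Gower centering.

    Eigendecomposition of -1/2 J d^2 J.  Axes for positive eigenvalues are
    returned scaled by sqrt(eigenvalue); negative eigenvalues are reported in
    ``eigenvalues`` but contribute neither axes nor variance-explained
    denominator (no Cailliez/Lingoes correction is applied).
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    a = -0.5 * dm ** 2
    row = a.mean(axis=1, keepdims=True)
    G = a - row - row.T + a.mean()
    G = (G + G.T) / 2
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1e-300) * 1e-9
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    var_expl = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        var_expl = var_expl[:n_axes]
    if coords.size:
        coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        sample_ids=list(d.ids),
        coordinates=_apply_sign_convention(coords),
        axis_var_explained=var_expl,
        eigenvalues=eigvals,
        method="pcoa",
    )
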