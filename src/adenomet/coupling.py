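"""Overall microbiome-metabolome association.

Three complementary views of how tightly the two omics blocks move together:
(1) rank correlation of the leading ordination axes (microbiome PCo1 vs
metabolome PC1), overall and within strata, with Fisher r-to-z comparisons
between strata; (2) the RV coefficient (coinertia) with a row-permutation
test; (3) symmetric Procrustes superimposition with a protest-style
permutation test.  Axis orientation is arbitrary, so axis correlations are
reported both signed and in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SampleMetadata
from .ordination import OrdinationResult
from .stats import (
    CorrelationComparison,
    CorrelationResult,
    fisher_r_to_z_compare,
    spearman,
)

__all__ = ["CouplingResult", "axis_correlation", "coinertia_rv", "procrustes_test"]


@dataclass
class CouplingResult:
    axis_rho: CorrelationResult | None = None
    axis_rho_by_stratum: dict[str, CorrelationResult] = field(default_factory=dict)
    stratum_comparisons: dict[str, CorrelationComparison] = field(default_factory=dict)
    rv: float | None = None
    rv_p: float | None = None
    procrustes_m2: float | None = None
    procrustes_corr: float | None = None
    procrustes_p: float | None = None

    @property
    def axis_abs_rho(self) -> float | None:
        return abs(self.axis_rho.rho) if self.axis_rho is not None else None


def _aligned_axes(
    micro_ord: OrdinationResult, metab_ord: OrdinationResult
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if micro_ord.sample_ids != metab_ord.sample_ids:
        raise ValueError("ordinations are not sample-aligned")
    return micro_ord.axis(1), metab_ord.axis(1), list(micro_ord.sample_ids)


def axis_correlation(
    micro_ord: OrdinationResult,
    metab_ord: OrdinationResult,
    meta: SampleMetadata,
    strata: list[str] = ("group", "sex"),
    min_stratum_n: int = 3,
) -> CouplingResult:
    """Spearman correlation of microbiome PCo1 vs metabolome PC1.

    Computed overall and within each level of the given stratifying factors
    (plus their interaction when two factors are given).  Strata smaller than
    ``min_stratum_n`` are skipped.  Pairwise comparisons of per-level
    correlations within each factor use the Fisher r-to-z test.
    """
    x, y, ids = _aligned_axes(micro_ord, metab_ord)
    frame = meta.frame.loc[ids]
    out = CouplingResult()
    out.axis_rho = spearman(x, y)

    def levels_of(series: pd.Series) -> list[str]:
        cat = pd.Categorical(series)
        return [str(lv) for lv in cat.categories if (cat == lv).sum() >= min_stratum_n]

    label_sets: dict[str, pd.Series] = {}
    for f in strata:
        label_sets[f] = frame[f].astype(str)
    if len(strata) == 2:
        label_sets["x".join(strata)] = (
            frame[strata[0]].astype(str) + ":" + frame[strata[1]].astype(str)
        )

    for fname, labels in label_sets.items():
        lvl_rhos: dict[str, CorrelationResult] = {}
        for lv in sorted(labels.unique()):
            mask = (labels == lv).to_numpy()
            if mask.sum() < min_stratum_n:
                continue
            r = spearman(x[mask], y[mask])
            key = f"{fname}={lv}"
            out.axis_rho_by_stratum[key] = r
            lvl_rhos[lv] = r
        lvls = sorted(lvl_rhos)
        for i in range(len(lvls)):
            for j in range(i + 1, len(lvls)):
                r1, r2 = lvl_rhos[lvls[i]], lvl_rhos[lvls[j]]
                if min(r1.n, r2.n) < 4 or max(abs(r1.rho), abs(r2.rho)) >= 1:
                    continue
                out.stratum_comparisons[f"{fname}:{lvls[i]}|{lvls[j]}"] = (
                    fisher_r_to_z_compare(r1.rho, r1.n, r2.rho, r2.n)
                )
    return out


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV = trace(X'Y Y'X) / sqrt(trace((X'X)^2) trace((Y'Y)^2))."""
    Xc = _center(np.asarray(X, float))
    Yc = _center(np.asarray(Y, float))
    sxx = Xc.T @ Xc
    syy = Yc.T @ Yc
    sxy = Xc.T @ Yc
    num = float(np.sum(sxy * sxy))
    den = float(np.sqrt(np.sum(sxx * sxx) * np.sum(syy * syy)))
    if den == 0:
        raise ValueError("zero-variance block")
    return num / den


def coinertia_rv(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """RV coefficient between two sample-aligned configurations with a
    row-permutation significance test (coinertia analysis)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks are not sample-aligned")
    rv_obs = rv_coefficient(X, Y)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += rv_coefficient(X[perm], Y) >= rv_obs - 1e-12
    return rv_obs, (1 + hits) / (1 + n_perm)


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Procrustes residual m^2 after translation/rotation/scaling."""
    Xc = _center(X)
    Yc = _center(Y)
    nx = np.linalg.norm(Xc)
    ny = np.linalg.norm(Yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance configuration")
    Xc = Xc / nx
    Yc = Yc / ny
    s = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Symmetric Procrustes comparison of two configurations.

    Both are centered and scaled to unit sum of squares; the optimal rotation
    comes from the SVD of Y'X.  Returns (m2, correlation, p) where
    correlation = sqrt(1 - m2) and p is a protest-style row-permutation
    p-value on the correlation.  Configurations with different axis counts
    are truncated to the common count.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks are not sample-aligned")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    k = min(X.shape[1], Y.shape[1])
    X = X[:, :k]
    Y = Y[:, :k]
    m2 = _procrustes_m2(X, Y)
    corr = float(np.sqrt(1.0 - m2))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        corr_star = np.sqrt(1.0 - _procrustes_m2(X[perm], Y))
        hits += corr_star >= corr - 1e-12
    return m2, corr, (1 + hits) / (1 + n_perm)


def couple(
    micro_ord: OrdinationResult,
    metab_ord: OrdinationResult,
    meta: SampleMetadata,
    strata: list[str] = ("group", "sex"),
    n_axes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> CouplingResult:
    """Full coupling summary: axis correlation + RV + Procrustes.

    By default all positive-eigenvalue axes of each ordination enter the
    multivariate tests; ``n_axes`` truncates both blocks.
    """
    res = axis_correlation(micro_ord, metab_ord, meta, strata=strata)
    X = micro_ord.coordinates
    Y = metab_ord.coordinates
    if n_axes is not None:
        X = X[:, :n_axes]
        Y = Y[:, :n_axes]
    rng = np.random.default_rng(seed)
    res.rv, res.rv_p = coinertia_rv(X, Y, n_perm=n_perm, seed=rng)
    res.procrustes_m2, res.procrustes_corr, res.procrustes_p = procrustes_test(
        X, Y, n_perm=n_perm, seed=rng
    )
    return res
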