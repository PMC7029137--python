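"""Permutation and classical tests used throughout the pipeline.

Implements distance-based PERMANOVA with marginal (drop-one), sequential, and
single-factor (unadjusted) sums of squares; the covariate-adjusted
permutation F-test for individual features (Freedman-Lane residual
permutation by default); Storey's q-value with spline pi0 estimation;
Benjamini-Hochberg and Bonferroni adjustments; an exact r x c Fisher test by
table enumeration; Spearman correlation; and the Fisher r-to-z comparison of
two correlation coefficients.

All permutation p-values use the bias-corrected estimator
``p = (1 + #{T* >= T_obs}) / (1 + B)`` and are reproducible given a seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .data_model import SampleMetadata

__all__ = [
    "PermanovaResult",
    "FeatureTestResult",
    "MultipleTestingResult",
    "CorrelationResult",
    "CorrelationComparison",
    "FisherExactResult",
    "permanova",
    "permanova_partial_batch",
    "permutation_f_test",
    "permutation_f_tests",
    "storey_qvalue",
    "bh_fdr",
    "bonferroni_adjust",
    "fisher_exact_rxc",
    "spearman",
    "spearman_matrix",
    "fisher_r_to_z_compare",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    ss: float
    var_explained_pct: float
    pseudo_F: float
    p: float
    mode: str
    n_perm: int


@dataclass
class FeatureTestResult:
    feature_id: str
    F_obs: float
    p: float
    direction: int
    group_means: dict[str, float]


@dataclass
class MultipleTestingResult:
    feature_ids: list[str]
    p: np.ndarray
    q: np.ndarray
    pi0: float
    method: str


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass
class CorrelationComparison:
    rho1: float
    n1: int
    rho2: float
    n2: int
    z: float
    p: float


@dataclass
class FisherExactResult:
    p: float
    n_tables: int
    monte_carlo: bool


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _dummies(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummy block (reference = first observed level)."""
    cat = pd.Categorical(series)
    levels = [lv for lv in cat.categories if (cat == lv).any()]
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than two observed levels")
    cols = []
    names = []
    for lv in levels[1:]:
        cols.append((cat == lv).astype(float))
        names.append(f"{name}[{lv}]")
    return np.column_stack(cols), names


def design_matrix(meta: SampleMetadata | pd.DataFrame,
                  factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies for the given metadata factors."""
    frame = meta.frame if isinstance(meta, SampleMetadata) else meta
    n = len(frame)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for f in factors:
        blk, nm = _dummies(frame[f], f)
        blocks.append(blk)
        names.extend(nm)
    return np.hstack(blocks), names


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix onto col(X) and its rank."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > max(diag.max(), 1e-300) * 1e-10
    return q[:, keep]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -1/2 J d^2 J; trace(G) is the total SS."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def permanova(
    d: DistanceMatrix,
    meta: SampleMetadata,
    factors: list[str],
    mode: str = "marginal",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> list[PermanovaResult]:
    """Distance-based multivariate ANOVA with permutation p-values.

    ``mode="marginal"`` fits each factor alone (one-term models);
    ``mode="adjusted"`` reports each factor's drop-one SS in the full model
    (order-invariant); ``mode="sequential"`` adds factors in the given order
    (order-dependent, provided for completeness).  P-values come from free
    permutation of sample labels.
    """
    if mode not in ("marginal", "adjusted", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = list(d.ids)
    frame = meta.frame.loc[ids]
    n = len(ids)
    G = gower_center(d.data)
    ss_total = float(np.trace(G))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # precompute hat matrices and per-term (numerator H, df, denominator) specs
    terms: list[dict] = []
    if mode == "marginal":
        for f in factors:
            X, _ = design_matrix(frame, [f])
            H, r = _hat(X)
            terms.append({"factor": f, "H_num": H, "H_sub": None,
                          "df": r - 1, "H_den": H, "den_rank": r})
    else:
        X_full, _ = design_matrix(frame, factors)
        H_full, r_full = _hat(X_full)
        if mode == "adjusted":
            for f in factors:
                others = [g for g in factors if g != f]
                if others:
                    X_o, _ = design_matrix(frame, others)
                    H_o, r_o = _hat(X_o)
                else:
                    H_o, r_o = _hat(np.ones((n, 1)))
                terms.append({"factor": f, "H_num": H_full, "H_sub": H_o,
                              "df": r_full - r_o, "H_den": H_full,
                              "den_rank": r_full})
        else:  # sequential
            prev_H, prev_r = _hat(np.ones((n, 1)))
            for f in factors:
                upto = factors[: factors.index(f) + 1]
                X_u, _ = design_matrix(frame, upto)
                H_u, r_u = _hat(X_u)
                terms.append({"factor": f, "H_num": H_u, "H_sub": prev_H,
                              "df": r_u - prev_r, "H_den": H_full,
                              "den_rank": r_full})
                prev_H, prev_r = H_u, r_u

    def term_stats(Gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.empty(len(terms))
        F = np.empty(len(terms))
        for k, t in enumerate(terms):
            num = float(np.vdot(t["H_num"], Gmat))
            if t["H_sub"] is not None:
                num -= float(np.vdot(t["H_sub"], Gmat))
            ss[k] = num
            ss_model_den = float(np.vdot(t["H_den"], Gmat))
            df_res = n - t["den_rank"]
            ms_res = (ss_total_local - ss_model_den) / df_res
            F[k] = (num / t["df"]) / ms_res if ms_res > 0 else np.inf
        return ss, F

    ss_total_local = ss_total
    ss_obs, F_obs = term_stats(G)

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, F_star = term_stats(Gp)
        exceed += F_star >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    out = []
    for k, t in enumerate(terms):
        out.append(PermanovaResult(
            factor=t["factor"],
            ss=float(ss_obs[k]),
            var_explained_pct=100.0 * float(ss_obs[k]) / ss_total,
            pseudo_F=float(F_obs[k]),
            p=float(pvals[k]),
            mode=mode,
            n_perm=n_perm,
        ))
    return out


def permanova_partial_batch(
    gowers: list[np.ndarray],
    meta_frame: pd.DataFrame,
    factor: str,
    covariates: list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Partial (covariate-adjusted) PERMANOVA of one factor over many
    distance matrices sharing the same samples.

    Used for pathway-level testing: each Gower matrix comes from the Euclidean
    distances of one pathway's member profiles, while the design (factor +
    covariates) and the permutation stream are shared.  Returns a DataFrame
    with columns ``ss``, ``r2_pct``, ``F``, ``p`` (one row per input matrix).
    """
    n = len(meta_frame)
    X_full, _ = design_matrix(meta_frame, [factor] + covariates)
    H_full, r_full = _hat(X_full)
    if covariates:
        X_red, _ = design_matrix(meta_frame, covariates)
        H_red, r_red = _hat(X_red)
    else:
        H_red, r_red = _hat(np.ones((n, 1)))
    df1 = r_full - r_red
    df2 = n - r_full
    Gstack = np.stack(gowers)               # (k, n, n)
    ss_tot = np.trace(Gstack, axis1=1, axis2=2)

    ss_full = np.einsum("ij,kij->k", H_full, Gstack)
    ss_red = np.einsum("ij,kij->k", H_red, Gstack)
    ss_obs = ss_full - ss_red
    ms_res = (ss_tot - ss_full) / df2
    F_obs = (ss_obs / df1) / ms_res

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exceed = np.zeros(len(gowers))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ix = np.ix_(perm, perm)
        Hf = H_full[ix]
        Hr = H_red[ix]
        sf = np.einsum("ij,kij->k", Hf, Gstack)
        sr = np.einsum("ij,kij->k", Hr, Gstack)
        num = sf - sr
        F_star = (num / df1) / ((ss_tot - sf) / df2)
        exceed += F_star >= F_obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({
        "ss": ss_obs,
        "r2_pct": 100.0 * ss_obs / ss_tot,
        "F": F_obs,
        "p": p,
    })


# ---------------------------------------------------------------------------
# per-feature permutation F-test
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        from scipy.linalg import qr as _qr
        _, r, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= diag.max() * 1e-10]
        bad += [names[j] for j in piv[len(diag):]]
        raise ValueError(f"collinear design; aliased terms: {sorted(set(bad))}")


def permutation_f_tests(
    Y: np.ndarray,
    meta: SampleMetadata | pd.DataFrame,
    group: str,
    covariates: list[str],
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    scheme: str = "freedman_lane",
    feature_ids: list[str] | None = None,
) -> list[FeatureTestResult]:
    """Covariate-adjusted permutation F-test, vectorized over features.

    For each column y of ``Y`` the observed statistic is the partial F
    comparing the full linear model (group + covariates) against the reduced
    model (covariates only).  Under ``scheme="freedman_lane"`` the reduced-
    model residuals are permuted and the partial F recomputed; under
    ``scheme="raw_label"`` the responses are permuted directly.  One shared
    permutation stream covers all features.
    """
    if scheme not in ("freedman_lane", "raw_label"):
        raise ValueError(f"unknown scheme {scheme!r}")
    frame = meta.frame if isinstance(meta, SampleMetadata) else meta
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    if n != len(frame):
        raise ValueError("response and metadata lengths differ")

    X_full, names_full = design_matrix(frame, [group] + covariates)
    if covariates:
        X_red, _ = design_matrix(frame, covariates)
    else:
        X_red = np.ones((n, 1))
    _check_full_rank(X_full, names_full)
    p_full = X_full.shape[1]
    if n < p_full + 2:
        raise ValueError("too few samples for the model")

    Q_full = _orthonormal_basis(X_full)
    Q_red = _orthonormal_basis(X_red)
    df1 = Q_full.shape[1] - Q_red.shape[1]
    df2 = n - Q_full.shape[1]

    def partial_F(Ymat: np.ndarray) -> np.ndarray:
        tot = np.einsum("ij,ij->j", Ymat, Ymat)
        rss_red = tot - np.einsum("ij,ij->j", Q_red.T @ Ymat, Q_red.T @ Ymat)
        rss_full = tot - np.einsum("ij,ij->j", Q_full.T @ Ymat, Q_full.T @ Ymat)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        return np.where(np.isfinite(F), F, np.inf)

    F_obs = partial_F(Y)

    E = Y - Q_red @ (Q_red.T @ Y)        # reduced-model residuals
    base = E if scheme == "freedman_lane" else Y
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exceed = np.zeros(m)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += partial_F(base[perm]) >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    # direction and group means from the observed data
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    # the first group dummy column sits right after the intercept
    g_col = 1
    directions = np.sign(beta[g_col]).astype(int)
    cat = pd.Categorical(frame[group])
    gm: dict[str, np.ndarray] = {}
    for lv in cat.categories:
        mask = np.asarray(cat == lv)
        if mask.any():
            gm[str(lv)] = Y[mask].mean(axis=0)

    fids = feature_ids if feature_ids is not None else [f"f{j}" for j in range(m)]
    out = []
    for j in range(m):
        out.append(FeatureTestResult(
            feature_id=fids[j],
            F_obs=float(F_obs[j]),
            p=float(pvals[j]),
            direction=int(directions[j]),
            group_means={k: float(v[j]) for k, v in gm.items()},
        ))
    return out


def permutation_f_test(
    y: np.ndarray,
    meta: SampleMetadata | pd.DataFrame,
    group: str,
    covariates: list[str],
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    scheme: str = "freedman_lane",
) -> FeatureTestResult:
    """Single-feature convenience wrapper around :func:`permutation_f_tests`."""
    return permutation_f_tests(
        np.asarray(y, dtype=float)[:, None], meta, group, covariates,
        n_perm=n_perm, seed=seed, scheme=scheme, feature_ids=["y"],
    )[0]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (intercept + df columns) at interior/boundary knots."""
    x = np.asarray(x, dtype=float)
    K = len(knots)

    def d(k):
        num = (np.maximum(x - knots[k], 0) ** 3
               - np.maximum(x - knots[K - 1], 0) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _estimate_pi0(p: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0_hat(lambda) on the grid 0.05..0.95 is fit with a natural cubic
    spline (3 df) and read off at lambda = 0.95, then clipped to (0, 1].
    """
    m = len(p)
    lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    knots = np.quantile(lambdas, [0.0, 1 / 3, 2 / 3, 1.0])
    B = _natural_spline_basis(lambdas, knots)
    coef, *_ = np.linalg.lstsq(B, pi0_l, rcond=None)
    at95 = float((_natural_spline_basis(np.array([0.95]), knots) @ coef)[0])
    return float(min(max(at95, 1.0 / m), 1.0))


def storey_qvalue(p: np.ndarray, feature_ids: list[str] | None = None,
                  pi0: float | None = None) -> MultipleTestingResult:
    """Storey q-values with spline-smoothed pi0 estimation.

    With fewer than 10 p-values the smoother is unreliable and pi0 falls back
    to 1 (q-values then equal Benjamini-Hochberg adjusted p-values).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 10:
            warnings.warn("fewer than 10 p-values; falling back to pi0 = 1")
            pi0 = 1.0
        else:
            pi0 = _estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    fids = feature_ids if feature_ids is not None else [str(i) for i in range(m)]
    return MultipleTestingResult(list(fids), p, q, float(pi0), "storey")


def bh_fdr(p: np.ndarray, feature_ids: list[str] | None = None) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up adjusted p-values (Storey with pi0 = 1)."""
    res = storey_qvalue(p, feature_ids, pi0=1.0)
    res.method = "bh"
    return res


def bonferroni_adjust(p: np.ndarray, m: int | None = None,
                      feature_ids: list[str] | None = None) -> MultipleTestingResult:
    """Bonferroni adjustment over a family of size ``m`` (>= len(p) allowed)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    fam = int(m) if m is not None else len(p)
    if fam < len(p):
        raise ValueError("family size smaller than number of tests")
    q = np.minimum(1.0, fam * p)
    fids = feature_ids if feature_ids is not None else [str(i) for i in range(len(p))]
    return MultipleTestingResult(list(fids), p, q, 1.0, "bonferroni")


# ---------------------------------------------------------------------------
# exact r x c Fisher test
# ---------------------------------------------------------------------------

def _table_logp_const(row: np.ndarray, col: np.ndarray) -> float:
    n = row.sum()
    return float(gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1))


def fisher_exact_rxc(
    table: np.ndarray,
    max_tables: int = 2_000_000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> FisherExactResult:
    """Exact two-sided Fisher test for an r x c contingency table.

    Enumerates all tables with the observed margins (rows in ascending margin
    order; the largest row is forced by the column remainders) and sums the
    multivariate-hypergeometric probabilities of tables no more probable than
    the observed one (relative tie tolerance 1e-12).  Above ``max_tables``
    enumerated tables, falls back to margin-preserving Monte Carlo sampling
    (Patefield algorithm via :func:`scipy.stats.random_table`), flagged in the
    result.
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (T < 0).any():
        raise ValueError("negative cell counts")
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all margins must be positive")
    const = _table_logp_const(row, col)
    logp_obs = const - float(gammaln(T + 1).sum())
    # tie tolerance: include tables whose probability is <= (1 + 1e-12) x observed
    cutoff = logp_obs + math.log1p(1e-12)

    order = np.argsort(row, kind="mergesort")
    rows_sorted = row[order]
    c = len(col)
    lg = gammaln(np.arange(int(row.sum()) + 2))

    count = 0
    total_logp: list[float] = []  # log-probs of tables in the two-sided tail

    def recurse(r_idx: int, rem_col: np.ndarray, acc_lgf: float):
        nonlocal count
        if count > max_tables:
            raise _EnumerationCap()
        if r_idx == len(rows_sorted) - 1:
            # last (largest) row forced by remaining column margins
            count += 1
            logp = const - (acc_lgf + lg[rem_col + 1].sum())
            if logp <= cutoff:
                total_logp.append(logp)
            return
        m_row = int(rows_sorted[r_idx])
        _compositions(m_row, rem_col, 0, np.zeros(c, dtype=np.int64),
                      r_idx, acc_lgf)

    def _compositions(remaining: int, rem_col: np.ndarray, j: int,
                      cells: np.ndarray, r_idx: int, acc_lgf: float):
        if j == c - 1:
            if remaining > rem_col[j]:
                return
            cells[j] = remaining
            new_rem = rem_col - cells
            recurse(r_idx + 1, new_rem,
                    acc_lgf + float(lg[cells + 1].sum()))
            return
        # prune: the rest of the row must fit in the remaining columns
        tail_cap = int(rem_col[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(remaining, int(rem_col[j]))
        for v in range(lo, hi + 1):
            cells[j] = v
            _compositions(remaining - v, rem_col, j + 1, cells, r_idx, acc_lgf)
        cells[j] = 0

    class _EnumerationCap(Exception):
        pass

    try:
        recurse(0, col.copy(), 0.0)
        pval = float(np.exp(np.array(total_logp)).sum()) if total_logp else 0.0
        return FisherExactResult(min(pval, 1.0), count, False)
    except _EnumerationCap:
        rng = np.random.default_rng(seed)
        sampler = sps.random_table(row, col)
        hits = 0
        drawn = 0
        chunk = 20_000
        while drawn < n_mc:
            k = min(chunk, n_mc - drawn)
            samples = sampler.rvs(size=k, random_state=rng)
            logps = const - gammaln(samples + 1).sum(axis=(1, 2))
            hits += int((logps <= cutoff).sum())
            drawn += k
        return FisherExactResult((1 + hits) / (1 + n_mc), drawn, True)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman(x: np.ndarray, y: np.ndarray, exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value.

    ``exact=True`` (n <= 9 only) computes the p-value by exhaustive
    enumeration of rank permutations instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two vectors of equal length n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only for n <= 9")
        rho_obs = float(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rho = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            hits += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        return CorrelationResult(rho_obs, hits / total, n)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), n)


def spearman_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and t-approximation p between columns of X and Y.

    Returns (rho, p) of shape (X columns, Y columns).  Vectorized: ranks each
    column, then computes the Pearson cross-correlation of the rank matrices.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n or n < 4:
        raise ValueError("aligned samples with n >= 4 required")
    RX = sps.rankdata(X, axis=0)
    RY = sps.rankdata(Y, axis=0)
    RX = RX - RX.mean(axis=0)
    RY = RY - RY.mean(axis=0)
    sx = np.sqrt((RX ** 2).sum(axis=0))
    sy = np.sqrt((RY ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RX.T @ RY) / np.outer(sx, sy)
    rho = np.clip(rho, -1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1, 0.0, p)
    return rho, p


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlation coefficients via Fisher's z."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each group")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return CorrelationComparison(r1, n1, r2, n2, float(z), float(p))
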