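"""Vendor-style scaling/imputation, prevalence filters, transforms, and
pathway aggregation for the metabolite and genus tables.

The metabolite chain is: raw intensities -> median-scaled with minimum-value
imputation (left-censoring assumption) -> prevalence + identity filter
-> log10.  The microbiome chain is: relative abundances -> prevalence filter
-> arcsine square root.  Pathway-level representations are either the member
profile matrix (for pathway PERMANOVA) or the sign-anchored first principal
component of the members (for the correlation screens).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import FeatureTable, MetaboliteAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayProfiles",
    "scale_impute",
    "filter_metabolites",
    "log10_transform",
    "filter_genera",
    "arcsine_sqrt_transform",
    "aggregate_pathways",
    "subpathway_pc1",
]


@dataclass
class PathwayProfiles:
    """A pathway's member profiles and (optionally) its PC1 summary."""

    pathway_id: str
    level: str                      # "superpathway" | "subpathway"
    member_feature_ids: list[str]
    member_matrix: np.ndarray       # samples x members, log10 scale
    sample_ids: list[str]
    pc1_scores: np.ndarray | None = None
    pc1_var_explained: float | None = None
    pc1_sign_flipped: bool | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_feature_ids)


def scale_impute(raw: FeatureTable) -> FeatureTable:
    """Rescale each metabolite so its median detected intensity is 1, then
    impute missing cells with the metabolite's post-scaling minimum detected
    value.

    Features never detected in any sample cannot be scaled and are dropped
    with a warning.  The detection mask is unchanged for retained features.
    """
    if raw.scale_tag != "raw":
        raise ValueError("scale_impute expects a raw table")
    det = raw.detected
    vals = raw.values
    if np.any((vals < 0) & det):
        raise ValueError("negative raw intensities")
    keep = det.any(axis=0)
    dropped = [f for f, k in zip(raw.feature_ids, keep) if not k]
    if dropped:
        logger.warning("scale_impute: dropping %d never-detected features: %s",
                       len(dropped), dropped[:5])
    t = raw.subset_features([f for f, k in zip(raw.feature_ids, keep) if k])
    vals = t.values.copy()
    det = t.detected
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        dj = det[:, j]
        med = np.median(vals[dj, j])
        if med <= 0:
            raise ValueError(f"nonpositive median for feature {t.feature_ids[j]!r}")
        scaled = vals[:, j] / med
        fill = scaled[dj].min()
        out[:, j] = np.where(dj, scaled, fill)
    return FeatureTable(out, det.copy(), t.sample_ids, t.feature_ids,
                        scale_tag="scaled_imputed")


def filter_metabolites(
    t: FeatureTable,
    annot: MetaboliteAnnotation,
    subset_samples: list[str],
    min_frac: float = 0.8,
) -> FeatureTable:
    """Keep metabolites of known identity detected in >= ``min_frac`` of the
    given samples (the adenoma + control groups; carcinoma samples never
    influence the filter)."""
    sub = t.subset_samples(subset_samples)
    frac = sub.detected.mean(axis=0)
    known = set(annot.known_ids())
    keep = [f for f, fr in zip(t.feature_ids, frac) if fr >= min_frac and f in known]
    if not keep:
        raise ValueError("no metabolites survive the prevalence/identity filter")
    return t.subset_features(keep)


def log10_transform(t: FeatureTable) -> FeatureTable:
    """Elementwise log base 10; requires an imputed, strictly positive table."""
    if t.scale_tag != "scaled_imputed":
        raise ValueError("log10_transform expects a scaled_imputed table")
    if (t.values <= 0).any():
        raise ValueError("nonpositive values cannot be log-transformed")
    return FeatureTable(np.log10(t.values), t.detected.copy(),
                        t.sample_ids, t.feature_ids, scale_tag="log10")


def filter_genera(
    g: FeatureTable, subset_samples: list[str], min_frac: float = 0.2
) -> FeatureTable:
    """Keep genera with nonzero abundance in >= ``min_frac`` of the samples."""
    sub = g.subset_samples(subset_samples)
    vals = np.where(sub.detected, sub.values, 0.0)
    frac = (vals > 0).mean(axis=0)
    keep = [f for f, fr in zip(g.feature_ids, frac) if fr >= min_frac]
    if not keep:
        raise ValueError("no genera survive the prevalence filter")
    return g.subset_features(keep)


def arcsine_sqrt_transform(g: FeatureTable) -> FeatureTable:
    """Variance-stabilizing asin(sqrt(x)) for proportions in [0, 1]."""
    vals = g.values
    if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
        raise ValueError("values outside [0, 1]")
    clipped = np.clip(vals, 0.0, 1.0)
    return FeatureTable(np.arcsin(np.sqrt(clipped)), g.detected.copy(),
                        g.sample_ids, g.feature_ids, scale_tag="arcsin_sqrt")


def aggregate_pathways(
    t: FeatureTable,
    annot: MetaboliteAnnotation,
    level: str,
    min_size: int = 5,
) -> list[PathwayProfiles]:
    """One :class:`PathwayProfiles` per pathway with >= ``min_size`` members
    present in the (already filtered) table; member order is lexicographic."""
    in_table = set(t.feature_ids)
    out: list[PathwayProfiles] = []
    for pid, members in annot.pathway_members(level).items():
        members = [m for m in members if m in in_table]
        if len(members) < min_size:
            continue
        sub = t.subset_features(members)
        out.append(PathwayProfiles(
            pathway_id=pid,
            level=level,
            member_feature_ids=members,
            member_matrix=sub.values.copy(),
            sample_ids=list(t.sample_ids),
        ))
    return out


def subpathway_pc1(p: PathwayProfiles, min_var: float = 0.2) -> PathwayProfiles | None:
    """PC1 summary of a pathway's member matrix, sign-anchored.

    Scores are the first principal component of the column-centered member
    matrix.  Pathways whose PC1 explains <= ``min_var`` of the variance are
    excluded (return None), as are zero-variance matrices.  The axis sign is
    flipped when the scores correlate negatively (Pearson) with the
    per-sample mean member intensity, so that "higher PC1" always reads as
    "higher average intensity"; exact zero correlation leaves the sign as is.
    """
    X = p.member_matrix
    if X.shape[1] < 1 or X.shape[0] < 3:
        raise ValueError("need >= 3 samples and >= 1 member")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        logger.warning("subpathway_pc1: zero-variance matrix for %s; excluded",
                       p.pathway_id)
        return None
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * s[0]
    var_expl = float(s[0] ** 2 / (s ** 2).sum())
    if var_expl <= min_var:
        return None
    mean_profile = X.mean(axis=1)
    mp = mean_profile - mean_profile.mean()
    corr_num = float(scores @ mp)
    flipped = corr_num < 0
    if flipped:
        scores = -scores
    return PathwayProfiles(
        pathway_id=p.pathway_id,
        level=p.level,
        member_feature_ids=list(p.member_feature_ids),
        member_matrix=p.member_matrix,
        sample_ids=list(p.sample_ids),
        pc1_scores=scores,
        pc1_var_explained=var_expl,
        pc1_sign_flipped=bool(flipped),
    )
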