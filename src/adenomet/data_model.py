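"""Domain containers shared by every analysis stage.

The package moves three kinds of tabular objects around: per-sample clinical
covariates (:class:`SampleMetadata`), samples x features numeric matrices with
an explicit detection mask (:class:`FeatureTable`), and the two-level chemical
class annotation of metabolites (:class:`MetaboliteAnnotation`).  Distance
matrices use :class:`skbio.stats.distance.DistanceMatrix` and phylogenies use
:class:`skbio.TreeNode`; thin validators here enforce the invariants the
pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "GROUP_LEVELS",
    "AGE_LEVELS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "SMOKING_LEVELS",
    "SCALE_TAGS",
    "SampleMetadata",
    "FeatureTable",
    "MetaboliteAnnotation",
    "AnalysisConfig",
    "validate_tree",
    "DistanceMatrix",
]

GROUP_LEVELS = ("control", "adenoma", "carcinoma")
AGE_LEVELS = ("50-59", "60-69", ">=70")
SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "hispanic", "black", "other_unknown")
SMOKING_LEVELS = ("smoker", "nonsmoker", "missing")

#: closed vocabularies per metadata column; "missing" only exists for smoking
METADATA_LEVELS: Mapping[str, tuple[str, ...]] = {
    "group": GROUP_LEVELS,
    "age_stratum": AGE_LEVELS,
    "sex": SEX_LEVELS,
    "race": RACE_LEVELS,
    "smoking": SMOKING_LEVELS,
}

SCALE_TAGS = ("raw", "scaled_imputed", "log10", "arcsin_sqrt", "relative")


class SampleMetadata:
    """Per-sample categorical covariates with closed level sets.

    Parameters
    ----------
    frame : pandas.DataFrame
        Indexed by sample id, with columns ``group``, ``age_stratum``,
        ``sex``, ``race``, ``smoking``.  Values must be drawn from the
        declared level sets; ``"missing"`` is legal only for smoking.
    """

    columns = ("group", "age_stratum", "sex", "race", "smoking")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        missing_cols = [c for c in self.columns if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"metadata lacks columns: {missing_cols}")
        for col in self.columns:
            levels = METADATA_LEVELS[col]
            bad = sorted(set(frame[col].astype(str)) - set(levels))
            if bad:
                raise ValueError(
                    f"metadata column {col!r} has values outside its level set: {bad}"
                )
            frame[col] = pd.Categorical(frame[col].astype(str), categories=levels)
        self.frame = frame[list(self.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def column(self, name: str) -> pd.Series:
        if name not in self.columns:
            raise KeyError(name)
        return self.frame[name]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, SampleMetadata) and self.frame.equals(other.frame)


@dataclass
class FeatureTable:
    """Samples x features matrix with an explicit detection mask.

    ``detected`` is False where the measurement was missing/not detected in
    the source file; ``values`` at those positions are only meaningful after
    imputation (``scale_tag`` records where in the transform chain the table
    sits).
    """

    values: np.ndarray
    detected: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    scale_tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected shapes differ")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "log10" and not self.detected.all():
            # imputation precedes the log transform
            if np.isnan(self.values[~self.detected]).any():
                raise ValueError("log10 table contains non-imputed missing values")
        if self.scale_tag == "relative":
            vals = np.where(self.detected, self.values, 0.0)
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("relative abundances outside [0, 1]")
            rs = vals.sum(axis=1)
            if not np.allclose(rs, 1.0, atol=1e-9):
                raise ValueError("relative abundance rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self, masked: bool = False) -> pd.DataFrame:
        """Return a DataFrame (samples x features); NaN where undetected if *masked*."""
        vals = self.values.copy()
        if masked:
            vals[~self.detected] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = self._index_of(self.sample_ids, sample_ids, "sample")
        return replace(
            self,
            values=self.values[idx],
            detected=self.detected[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = self._index_of(self.feature_ids, feature_ids, "feature")
        # a feature subset of a relative table no longer sums to 1 per row
        tag = self.scale_tag
        if tag == "relative" and len(idx) < self.n_features:
            tag = "raw"
        return replace(
            self,
            values=self.values[:, idx],
            detected=self.detected[:, idx],
            feature_ids=[self.feature_ids[i] for i in idx],
            scale_tag=tag,
        )

    @staticmethod
    def _index_of(have: list[str], want: Sequence[str], what: str) -> list[int]:
        pos = {s: i for i, s in enumerate(have)}
        missing = [s for s in want if s not in pos]
        if missing:
            raise KeyError(f"{what} ids not in table: {missing[:5]}")
        return [pos[s] for s in want]

    def with_tag(self, tag: str) -> "FeatureTable":
        return replace(self, scale_tag=tag)


class MetaboliteAnnotation:
    """Identity status and super/subpathway membership per metabolite.

    Every annotated metabolite maps to exactly one superpathway and one
    subpathway; metabolites of unknown identity carry ``identity_known=False``
    and empty pathway fields.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = ("identity_known", "superpathway", "subpathway")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation lacks columns: {missing}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate feature ids in annotation")
        frame["identity_known"] = frame["identity_known"].astype(bool)
        self.frame = frame

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.frame.index]

    def known_ids(self) -> list[str]:
        return [str(f) for f in self.frame.index[self.frame["identity_known"]]]

    def pathway_members(self, level: str) -> dict[str, list[str]]:
        """Map pathway id -> lexicographically sorted member feature ids."""
        if level not in ("superpathway", "subpathway"):
            raise ValueError(level)
        known = self.frame[self.frame["identity_known"]]
        out: dict[str, list[str]] = {}
        for pid, sub in known.groupby(level, observed=True, sort=True):
            if pid == "" or pd.isna(pid):
                continue
            out[str(pid)] = sorted(str(f) for f in sub.index)
        return out

    def superpathway_of(self, subpathway: str) -> str:
        sub = self.frame[self.frame["subpathway"] == subpathway]
        if sub.empty:
            raise KeyError(subpathway)
        return str(sub["superpathway"].iloc[0])


@dataclass
class AnalysisConfig:
    """Tunable thresholds and permutation settings for the full pipeline."""

    n_permutations: int = 999          # multivariate (distance-based) tests
    n_permutations_feature: int = 9999  # per-feature permutation F-tests
    rng_seed: int = 0
    fdr_metabolite: float = 0.2
    fdr_pathway: float = 0.1
    bonferroni_alpha: float = 0.05
    prevalence_metabolite: float = 0.8
    prevalence_genus: float = 0.2
    subpathway_min_size: int = 5
    subpathway_pc1_min_var: float = 0.2
    permutation_scheme: str = "freedman_lane"

    def __post_init__(self):
        for name in (
            "fdr_metabolite",
            "fdr_pathway",
            "bonferroni_alpha",
            "prevalence_metabolite",
            "prevalence_genus",
            "subpathway_pc1_min_var",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_permutations < 99 or self.n_permutations_feature < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.permutation_scheme not in ("freedman_lane", "raw_label"):
            raise ValueError(f"unknown permutation scheme {self.permutation_scheme!r}")


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check the invariants the UniFrac computation assumes.

    Leaf labels unique, branch lengths nonnegative, total branch length
    positive.  Returns the tree unchanged.
    """
    leaves = [t.name for t in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree leaf labels are not unique")
    total = 0.0
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None:
            continue
        if bl < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
        total += bl
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    return tree
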