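"""Residualized genus x metabolite / genus x subpathway correlation screens.

Abundance profiles (arcsine-sqrt genera; log10 metabolites or subpathway PC1
scores) are first replaced by their residuals from a linear model on the
clinical factors (group, age, sex, race, smoking), de-emphasizing
associations driven by those factors; Spearman correlations are then
computed on the residuals for every pair, with Bonferroni control over the
full pair family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FeatureTable, SampleMetadata
from .stats import bonferroni_adjust, design_matrix, spearman_matrix

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "residualize", "correlation_screen"]

TIER_EDGES = ((0.001, "q<0.001"), (0.01, "q<0.01"), (0.1, "q<0.1"))


@dataclass
class ScreenResult:
    pairs: pd.DataFrame          # genus_id, target_id, rho, p, q_bonferroni, tier
    family_size: int
    alpha: float

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.pairs[self.pairs["q_bonferroni"] < a]


def residualize(
    profiles: FeatureTable,
    meta: SampleMetadata,
    factors: list[str] = ("group", "age_stratum", "sex", "race", "smoking"),
) -> FeatureTable:
    """Replace each feature by its OLS residuals from the categorical design.

    Rank-deficient designs (aliased factor levels) keep a maximal independent
    column set, with a warning.  Residuals are column-mean zero.
    """
    if not np.isfinite(profiles.values).all():
        raise ValueError("residualize requires a table with no missing values")
    frame = meta.frame.loc[profiles.sample_ids]
    X, names = design_matrix(frame, list(factors))
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        dropped = [names[i] for i in range(len(keep)) if not keep[i]]
        logger.warning("residualize: dropping aliased design columns: %s", dropped)
    Q = q[:, keep]
    Y = profiles.values
    resid = Y - Q @ (Q.T @ Y)
    return FeatureTable(resid, profiles.detected.copy(), profiles.sample_ids,
                        profiles.feature_ids, scale_tag=profiles.scale_tag)


def _tier(q: float) -> str:
    for edge, label in TIER_EDGES:
        if q < edge:
            return label
    return "ns"


def correlation_screen(
    genus_resid: FeatureTable,
    target_resid: FeatureTable,
    alpha: float = 0.05,
) -> ScreenResult:
    """All-pairs Spearman between residualized genus and target profiles.

    The Bonferroni family is the full (#genera x #targets) grid.  The result
    lists every pair (sorted by adjusted p) with a significance tier
    annotation (+ q<0.1, * q<0.01, ** q<0.001); ``significant()`` applies the
    reporting threshold.
    """
    if genus_resid.sample_ids != target_resid.sample_ids:
        raise ValueError("screen blocks are not sample-aligned")
    rho, p = spearman_matrix(genus_resid.values, target_resid.values)
    n_g, n_t = rho.shape
    family = n_g * n_t
    gi, ti = np.meshgrid(np.arange(n_g), np.arange(n_t), indexing="ij")
    flat_p = p.ravel()
    adj = bonferroni_adjust(np.nan_to_num(flat_p, nan=1.0), m=family)
    frame = pd.DataFrame({
        "genus_id": [genus_resid.feature_ids[i] for i in gi.ravel()],
        "target_id": [target_resid.feature_ids[j] for j in ti.ravel()],
        "rho": rho.ravel(),
        "p": flat_p,
        "q_bonferroni": adj.q,
    })
    frame["tier"] = [_tier(q) for q in frame["q_bonferroni"]]
    frame = frame.sort_values(["q_bonferroni", "genus_id", "target_id"],
                              kind="mergesort").reset_index(drop=True)
    return ScreenResult(pairs=frame, family_size=family, alpha=alpha)
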