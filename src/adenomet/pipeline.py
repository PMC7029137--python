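"""Orchestration of the hierarchical case-control analysis.

The hierarchy compares the adenoma and control groups at three levels:
overall metabolomic profiles (PERMANOVA on Euclidean distances, marginal and
fully adjusted models), pathway-level profiles (partial PERMANOVA of the
group factor adjusted for sex and age, Benjamini-Hochberg within each
pathway level), and individual metabolites (covariate-adjusted permutation
F-tests with Storey q-values).  Companion tests with the roles of group and
sex swapped flag hits that also differ by sex.  The carcinoma group enters
only the follow-up analyses: fold-change direction/attenuation of the
metabolite hits, and a reduced-burden subpathway re-test of carcinoma vs
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisConfig,
    FeatureTable,
    MetaboliteAnnotation,
    SampleMetadata,
)
from .ordination import euclidean_distance
from .preprocess import (
    PathwayProfiles,
    aggregate_pathways,
    arcsine_sqrt_transform,
    filter_genera,
    filter_metabolites,
    log10_transform,
    scale_impute,
    subpathway_pc1,
)
from .stats import (
    PermanovaResult,
    bh_fdr,
    fisher_exact_rxc,
    gower_center,
    permanova,
    permanova_partial_batch,
    permutation_f_tests,
    storey_qvalue,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessedDataset",
    "FoldChangeResult",
    "HierarchyReport",
    "preprocess_dataset",
    "run_hierarchy",
    "fold_change_consistency",
    "carcinoma_subpathway_check",
    "check_matching",
]

HIERARCHY_FACTORS = ["group", "age_stratum", "sex", "race", "smoking"]


@dataclass
class PreprocessedDataset:
    """Filtered/transformed tables plus pathway structure, all samples."""

    metab_log10: FeatureTable
    annotation: MetaboliteAnnotation
    superpathways: list[PathwayProfiles]
    subpathways: list[PathwayProfiles]          # PERMANOVA set (size filter only)
    subpathway_pc1s: list[PathwayProfiles]      # screen set (size + PC1-variance)
    genus_arcsin: FeatureTable | None
    metadata: SampleMetadata
    config: AnalysisConfig

    def samples_in(self, groups: tuple[str, ...]) -> list[str]:
        g = self.metadata.frame["group"]
        return [s for s, v in zip(self.metadata.sample_ids, g) if v in groups]


def preprocess_dataset(
    metab_raw: FeatureTable,
    annot: MetaboliteAnnotation,
    meta: SampleMetadata,
    genus_rel: FeatureTable | None = None,
    config: AnalysisConfig | None = None,
) -> PreprocessedDataset:
    """Run the full preprocessing chain.

    Metabolites: median scaling + minimum imputation, then the prevalence
    (on adenoma+control samples only) and known-identity filters, then
    log10.  Genera: prevalence filter then arcsine square root.  Pathway
    profiles are built from the filtered log10 table; the screen set of
    subpathways additionally requires PC1 variance explained above the
    configured threshold.
    """
    cfg = config or AnalysisConfig()
    ac = [s for s, g in zip(meta.sample_ids, meta.frame["group"])
          if g in ("control", "adenoma")]
    if not ac:
        raise ValueError("no adenoma/control samples")
    scaled = scale_impute(metab_raw)
    filtered = filter_metabolites(scaled, annot, ac, cfg.prevalence_metabolite)
    lg = log10_transform(filtered)
    superp = aggregate_pathways(lg, annot, "superpathway", cfg.subpathway_min_size)
    subp = aggregate_pathways(lg, annot, "subpathway", cfg.subpathway_min_size)
    pc1s = []
    for p in subp:
        r = subpathway_pc1(p, cfg.subpathway_pc1_min_var)
        if r is not None:
            pc1s.append(r)
    genus = None
    if genus_rel is not None:
        genus = arcsine_sqrt_transform(
            filter_genera(genus_rel, ac, cfg.prevalence_genus))
    return PreprocessedDataset(lg, annot, superp, subp, pc1s, genus, meta, cfg)


@dataclass
class FoldChangeResult:
    feature_id: str
    fc_adenoma: float      # log10 mean difference, adenoma - control
    fc_carcinoma: float    # log10 mean difference, carcinoma - control
    ratio_adenoma: float   # 10 ** fc_adenoma
    ratio_carcinoma: float
    quadrant: str          # I..IV or "axis"
    attenuated: bool


@dataclass
class HierarchyReport:
    overall_marginal: list[PermanovaResult]
    overall_adjusted: list[PermanovaResult]
    superpathway: pd.DataFrame
    subpathway: pd.DataFrame
    metabolite: pd.DataFrame
    pi0: float

    @property
    def superpathway_hits(self) -> list[str]:
        return list(self.superpathway.index[self.superpathway["hit"]])

    @property
    def subpathway_hits(self) -> list[str]:
        return list(self.subpathway.index[self.subpathway["hit"]])

    @property
    def metabolite_hits(self) -> list[str]:
        return list(self.metabolite.index[self.metabolite["hit"]])

    @property
    def sex_flagged(self) -> list[str]:
        m = self.metabolite
        return list(m.index[m["hit"] & m["sex_flagged"]])


def _pathway_level_tests(
    profiles: list[PathwayProfiles],
    sample_ids: list[str],
    frame: pd.DataFrame,
    factor: str,
    covariates: list[str],
    n_perm: int,
    seed,
    fdr: float,
) -> pd.DataFrame:
    """Partial PERMANOVA of one factor across pathways, BH within the level."""
    pos = {s: i for i, s in enumerate(profiles[0].sample_ids)} if profiles else {}
    gowers = []
    for p in profiles:
        idx = [pos[s] for s in sample_ids]
        X = p.member_matrix[idx]
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        gowers.append(gower_center(d))
    if not gowers:
        return pd.DataFrame(columns=["n_members", "r2_pct", "F", "p", "q", "hit"])
    res = permanova_partial_batch(gowers, frame, factor, covariates,
                                  n_perm=n_perm, seed=seed)
    adj = bh_fdr(res["p"].to_numpy())
    out = pd.DataFrame({
        "n_members": [p.n_members for p in profiles],
        "r2_pct": res["r2_pct"].to_numpy(),
        "F": res["F"].to_numpy(),
        "p": res["p"].to_numpy(),
        "q": adj.q,
    }, index=pd.Index([p.pathway_id for p in profiles], name="pathway_id"))
    out["hit"] = out["q"] < fdr
    return out


def run_hierarchy(dataset: PreprocessedDataset,
                  config: AnalysisConfig | None = None) -> HierarchyReport:
    """Hierarchical adenoma-vs-control comparison (overall, pathway,
    metabolite), with sex-companion tests; fully seeded."""
    cfg = config or dataset.config
    ac = dataset.samples_in(("control", "adenoma"))
    lg = dataset.metab_log10.subset_samples(ac)
    frame = dataset.metadata.frame.loc[ac]
    meta_ac = dataset.metadata.subset(ac)
    ss = np.random.SeedSequence(cfg.rng_seed)
    seeds = [np.random.default_rng(s) for s in ss.spawn(7)]

    d_all = euclidean_distance(lg)
    overall_marg = permanova(d_all, meta_ac, HIERARCHY_FACTORS,
                             mode="marginal", n_perm=cfg.n_permutations,
                             seed=seeds[0])
    overall_adj = permanova(d_all, meta_ac, HIERARCHY_FACTORS,
                            mode="adjusted", n_perm=cfg.n_permutations,
                            seed=seeds[1])

    covs = ["sex", "age_stratum"]
    sup = _pathway_level_tests(dataset.superpathways, ac, frame, "group", covs,
                               cfg.n_permutations, seeds[2], cfg.fdr_pathway)
    sub = _pathway_level_tests(dataset.subpathways, ac, frame, "group", covs,
                               cfg.n_permutations, seeds[3], cfg.fdr_pathway)
    # sex companions at the pathway level (group and sex swap roles)
    sup_sex = _pathway_level_tests(dataset.superpathways, ac, frame, "sex",
                                   ["group", "age_stratum"],
                                   cfg.n_permutations, seeds[4], cfg.fdr_pathway)
    sub_sex = _pathway_level_tests(dataset.subpathways, ac, frame, "sex",
                                   ["group", "age_stratum"],
                                   cfg.n_permutations, seeds[4], cfg.fdr_pathway)
    for tab, sex_tab in ((sup, sup_sex), (sub, sub_sex)):
        if len(tab):
            tab["sex_q"] = sex_tab["q"].reindex(tab.index)
            tab["sex_flagged"] = tab["sex_q"] < cfg.fdr_pathway

    # metabolite level
    res_group = permutation_f_tests(
        lg.values, meta_ac, "group", covs,
        n_perm=cfg.n_permutations_feature, seed=seeds[5],
        scheme=cfg.permutation_scheme, feature_ids=lg.feature_ids)
    res_sex = permutation_f_tests(
        lg.values, meta_ac, "sex", ["group", "age_stratum"],
        n_perm=cfg.n_permutations_feature, seed=seeds[6],
        scheme=cfg.permutation_scheme, feature_ids=lg.feature_ids)
    p_group = np.array([r.p for r in res_group])
    p_sex = np.array([r.p for r in res_sex])
    mt = storey_qvalue(p_group, lg.feature_ids)
    mt_sex = storey_qvalue(p_sex, lg.feature_ids)
    metab = pd.DataFrame({
        "F": [r.F_obs for r in res_group],
        "p": p_group,
        "q": mt.q,
        "direction": [r.direction for r in res_group],
        "sex_p": p_sex,
        "sex_q": mt_sex.q,
    }, index=pd.Index(lg.feature_ids, name="feature_id"))
    metab["hit"] = metab["q"] < cfg.fdr_metabolite
    metab["sex_flagged"] = metab["sex_q"] < cfg.fdr_metabolite

    return HierarchyReport(overall_marg, overall_adj, sup, sub, metab,
                           pi0=mt.pi0)


def _quadrant(fa: float, fc: float) -> str:
    if fa == 0 or fc == 0:
        return "axis"
    if fa > 0:
        return "I" if fc > 0 else "IV"
    return "III" if fc < 0 else "II"


def fold_change_consistency(
    metab_log10: FeatureTable,
    meta: SampleMetadata,
    hits: list[str],
) -> tuple[list[FoldChangeResult], dict[str, int]]:
    """Adenoma-vs-control and carcinoma-vs-control fold changes.

    Fold changes are differences of group means on the log10 scale (also
    reported as 10**difference ratios).  For the hit features the summary
    counts how many change in the same direction in both comparisons
    (quadrants I/III) and how many of those are attenuated (carcinoma effect
    strictly between zero and the adenoma effect, i.e. between the x axis
    and the diagonal y = x).
    """
    groups = meta.frame.loc[metab_log10.sample_ids, "group"]
    masks = {g: (groups == g).to_numpy() for g in ("control", "adenoma", "carcinoma")}
    if not masks["carcinoma"].any():
        raise ValueError("no carcinoma samples")
    V = metab_log10.values
    mean_c = V[masks["control"]].mean(axis=0)
    fc_a = V[masks["adenoma"]].mean(axis=0) - mean_c
    fc_k = V[masks["carcinoma"]].mean(axis=0) - mean_c
    results = []
    consistent = attenuated = 0
    fid_pos = {f: j for j, f in enumerate(metab_log10.feature_ids)}
    for f in hits:
        j = fid_pos[f]
        fa, fk = float(fc_a[j]), float(fc_k[j])
        quad = _quadrant(fa, fk)
        att = quad in ("I", "III") and 0 < abs(fk) < abs(fa)
        results.append(FoldChangeResult(
            feature_id=f, fc_adenoma=fa, fc_carcinoma=fk,
            ratio_adenoma=float(10 ** fa), ratio_carcinoma=float(10 ** fk),
            quadrant=quad, attenuated=att))
        consistent += quad in ("I", "III")
        attenuated += att
    summary = {"n_hits": len(hits), "n_consistent": consistent,
               "n_attenuated": attenuated}
    return results, summary


def carcinoma_subpathway_check(
    dataset: PreprocessedDataset,
    adenoma_subpathway_hits: list[str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Re-test the adenoma-associated subpathways in carcinoma vs control.

    Restricting both the samples (carcinoma + control) and the multiple-
    testing family (only the adenoma hits) keeps the burden small, as the
    carcinoma group is much smaller.  BH within the restricted family;
    ``hit`` marks q < fdr_pathway.
    """
    cfg = config or dataset.config
    kc = dataset.samples_in(("control", "carcinoma"))
    frame = dataset.metadata.frame.loc[kc]
    profiles = [p for p in dataset.subpathways
                if p.pathway_id in set(adenoma_subpathway_hits)]
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(8)[7])
    return _pathway_level_tests(profiles, kc, frame, "group",
                                ["sex", "age_stratum"], cfg.n_permutations,
                                rng, cfg.fdr_pathway)


def check_matching(meta: SampleMetadata,
                   include_missing_smoking: bool = True) -> pd.DataFrame:
    """Exact r x c Fisher tests of each covariate against group membership.

    Verifies frequency matching (the factor distributions should not differ
    between groups).  The unrecorded-smoking level is kept as a row by
    default; ``include_missing_smoking=False`` restricts to complete cases.
    """
    frame = meta.frame
    groups = [g for g in frame["group"].cat.categories
              if (frame["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for factor in ("age_stratum", "sex", "race", "smoking"):
        col = frame[factor].astype(str)
        if factor == "smoking" and not include_missing_smoking:
            keep = col != "missing"
        else:
            keep = col.notna()
        tab = pd.crosstab(col[keep], frame["group"][keep].astype(str))
        tab = tab.loc[(tab.sum(axis=1) > 0), [g for g in groups if g in tab.columns]]
        if tab.shape[0] < 2:
            # a single observed level cannot be imbalanced across groups
            rows.append({"factor": factor, "p": 1.0, "monte_carlo": False,
                         "n": int(tab.to_numpy().sum())})
            continue
        res = fisher_exact_rxc(tab.to_numpy())
        rows.append({"factor": factor, "p": res.p,
                     "monte_carlo": res.monte_carlo,
                     "n": int(tab.to_numpy().sum())})
    return pd.DataFrame(rows).set_index("factor")
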