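"""Residualized genus x subpathway and genus x metabolite correlation screens.

On the adenoma+control samples: genus profiles (arcsine-sqrt relative
abundances at >=20% prevalence) and targets (subpathway PC1 scores, and all
retained log10 metabolites) are residualized against group, age, sex, race
and smoking; Spearman correlations are Bonferroni-adjusted over the full
pair family (#genera x #targets).  Pairs at q < 0.05 are reported with tier
annotations (+ q<0.1, * q<0.01, ** q<0.001).

Writes screen_subpathways.tsv and screen_metabolites.tsv under results/.
"""

import sys
from pathlib import Path

import numpy as np

from adenomet import io as aio
from adenomet.data_model import AnalysisConfig, FeatureTable
from adenomet.pipeline import preprocess_dataset
from adenomet.screen import correlation_screen, residualize

ROOT = Path(__file__).resolve().parent.parent
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
COHORT = ROOT / "results" / "cohort"
FACTORS = ["group", "age_stratum", "sex", "race", "smoking"]


def main():
    metab = aio.read_feature_table(COHORT / "metabolites_raw.tsv")
    annot = aio.read_annotation(COHORT / "annotation.tsv")
    meta = aio.read_metadata(COHORT / "metadata.tsv")
    genus = aio.read_feature_table(COHORT / "genus_relabund.tsv").with_tag("relative")
    ds = preprocess_dataset(metab, annot, meta, genus, AnalysisConfig(rng_seed=SEED))
    ac = ds.samples_in(("control", "adenoma"))
    meta_ac = meta.subset(ac)

    genus_r = residualize(ds.genus_arcsin.subset_samples(ac), meta_ac, FACTORS)
    pc1 = FeatureTable(
        np.column_stack([p.pc1_scores for p in ds.subpathway_pc1s])[
            [ds.metab_log10.sample_ids.index(s) for s in ac]],
        np.ones((len(ac), len(ds.subpathway_pc1s)), bool),
        ac, [p.pathway_id for p in ds.subpathway_pc1s], scale_tag="log10")
    sub_r = residualize(pc1, meta_ac, FACTORS)
    met_r = residualize(ds.metab_log10.subset_samples(ac), meta_ac, FACTORS)

    sub_res = correlation_screen(genus_r, sub_r)
    met_res = correlation_screen(genus_r, met_r)
    sub_res.pairs.to_csv(ROOT / "results" / "screen_subpathways.tsv",
                         sep="\t", index=False)
    met_res.pairs.to_csv(ROOT / "results" / "screen_metabolites.tsv",
                         sep="\t", index=False)

    for name, res in (("genus x subpathway", sub_res),
                      ("genus x metabolite", met_res)):
        sig = res.significant()
        print(f"{name}: family of {res.family_size} pairs, "
              f"{len(sig)} Bonferroni-significant at q<0.05 "
              f"({(sig['rho'] < 0).sum()} negative, "
              f"{(sig['rho'] > 0).sum()} positive)")
        if len(sig):
            top = sig.iloc[0]
            print(f"  strongest: {top['genus_id']} ~ {top['target_id']} "
                  f"(rho={top['rho']:+.2f}, q={top['q_bonferroni']:.2e}, "
                  f"{top['tier']})")


if __name__ == "__main__":
    main()
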