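"""Generate the default synthetic paired cohort and write its tables.

The cohort emulates a three-group colorectal screening study: 102 controls,
102 adenoma patients and 36 carcinoma patients, frequency-matched on age,
sex and race; ~600 untargeted metabolites in a superpathway/subpathway
hierarchy with left-censored missingness and 24 planted adenoma-associated
metabolites; and a paired microbiome (OTU counts on a random phylogeny,
aggregated to genera) coupled to the metabolome through a shared latent
factor targeting a |rho| ~ 0.68 leading-axis correlation.

Outputs under results/cohort/: the raw tables in the same delimited formats
the readers consume, plus truth.json with every planted signal.
"""

import json
import sys
from pathlib import Path

from adenomet import io as aio
from adenomet.synthetic import SyntheticConfig, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    coh = generate_cohort(SyntheticConfig(seed=SEED))
    aio.write_feature_table(coh.metab_raw, OUT / "metabolites_raw.tsv")
    aio.write_annotation(coh.annotation, OUT / "annotation.tsv")
    aio.write_feature_table(coh.genus_rel, OUT / "genus_relabund.tsv")
    aio.write_feature_table(coh.otu_counts, OUT / "otu_counts.tsv")
    aio.write_newick(coh.tree, OUT / "tree.nwk")
    aio.write_metadata(coh.metadata, OUT / "metadata.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "seed": SEED,
        "differential_metabolite_ids": coh.truth.differential_metabolite_ids,
        "differential_signs": coh.truth.differential_signs,
        "perturbed_subpathway_ids": coh.truth.perturbed_subpathway_ids,
        "sex_effect_ids": coh.truth.sex_effect_ids,
        "carcinoma_ratio_by_subpathway": coh.truth.carcinoma_ratio_by_subpathway,
        "latent_factor": coh.truth.latent_factor.tolist(),
    }, indent=2) + "\n")
    n = coh.metadata.frame["group"].value_counts()
    print(f"cohort written to {OUT} (seed={SEED})")
    print(f"  groups: {dict(n)}")
    print(f"  metabolites: {coh.metab_raw.n_features} "
          f"({len(coh.truth.differential_metabolite_ids)} planted differential)")
    print(f"  genera: {coh.genus_rel.n_features}, OTUs: {coh.otu_counts.n_features}")


if __name__ == "__main__":
    main()
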