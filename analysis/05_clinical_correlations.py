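"""Within-case correlations between gradient scores and clinical scales.

Correlates the case group's DMN principal-gradient network score, and each
DMN subdivision parcel's score, with CESD and HAMD; the planted coupling is
negative (lower DMN gradient, more severe symptoms).
"""

import pandas as pd

from _common import RESULTS, flagship_pipeline
from gradhier.hierarchy import subdivision_scores
from gradhier.stats import correlate_with_scales, multiplicity_adjust

sim, result = flagship_pipeline()
RESULTS.mkdir(exist_ok=True)

wide = result.principal_scores()
network_corr = correlate_with_scales(
    wide[["subject_id", "Default"]],
    sim.cohort.table,
    score_columns=["Default"],
    group="case",
    scope="network",
)

sub = subdivision_scores(result.aligned_subjects, sim.metadata, network="Default")
parcel_wide = sub.pivot(index="subject_id", columns="parcel_label", values="gradient_score")
parcel_wide = parcel_wide.reset_index()
parcel_corr = correlate_with_scales(
    parcel_wide,
    sim.cohort.table,
    score_columns=[c for c in parcel_wide.columns if c != "subject_id"],
    group="case",
    scope="parcel",
)

tab = pd.DataFrame(
    [
        {
            "scope": r.scope,
            "score_variable": r.score_variable,
            "clinical_scale": r.clinical_scale,
            "pearson_r": r.pearson_r,
            "p_value": r.p_value,
            "n": r.n,
        }
        for r in network_corr + parcel_corr
    ]
)
tab["p_fdr_bh"] = multiplicity_adjust(tab["p_value"].to_numpy())
tab.to_csv(RESULTS / "clinical_correlations.tsv", sep="\t", index=False)

net = tab[tab["scope"] == "network"]
print("within-case DMN network score vs clinical scales:")
print(net[["clinical_scale", "pearson_r", "p_value"]].round(4).to_string(index=False))
parcels = tab[tab["scope"] == "parcel"]
n_neg = (parcels["pearson_r"] < 0).sum()
print(f"\nDMN subdivision parcels: {n_neg}/{len(parcels)} negative correlations "
      f"({(parcels['p_fdr_bh'] < 0.05).sum()} significant after BH-FDR)")
print(f"wrote clinical_correlations.tsv to {RESULTS}")
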