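"""Resistance-Activated Cluster calling and drug-class concentration.

Flags clusters whose active-cell odds exceed the line background (Fisher
exact, BH-adjusted) and compares the calls with the planted truth; also
reports which drug class concentrates in the called RACs.
"""

import pandas as pd

from common import TABLES, ensure_run, load_truth

run_dir = ensure_run()
truth = load_truth(run_dir)
planted = set(truth["active_clusters"])

table = pd.read_csv(run_dir / "05_rac" / "rac_table.tsv", sep="\t")
dce = pd.read_csv(run_dir / "05_rac" / "drug_class_enrichment.tsv", sep="\t")
table.to_csv(TABLES / "05_rac_table.tsv", sep="\t", index=False)
dce.to_csv(TABLES / "05_drug_class_enrichment.tsv", sep="\t", index=False)

called = set(table.loc[table["is_rac"], "cluster_id"])
sens = len(called & planted) / len(planted)
fp = len(called - planted)
print(f"RACs called: {sorted(called)}")
print(f"sensitivity vs planted clusters: {100 * sens:.1f}%  "
      f"({fp} false-positive clusters)")
print("status counts:", table.loc[table["is_rac"], "status"]
      .value_counts().to_dict())
top = dce.sort_values("p_adj").iloc[0]
print(f"most concentrated drug class in RACs: {top['drug_class']} "
      f"(OR {top['odds_ratio']:.1f}, adj p {top['p_adj']:.2e}; "
      f"planted: {truth['concentrated_class']})")
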