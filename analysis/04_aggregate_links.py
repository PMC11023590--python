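#!/usr/bin/env python
"""Aggregate the published coefficient tables: significant-link means for
religions and education levels, the sign matrix across contexts, the
majority-minus-minority religion differences under all three significance
policies, and the cumulative education-level gains.

Uses the shipped printed tables; writes results/aggregation/.
"""
import json
from pathlib import Path

from ethos.aggregation import (
    coupling_averages,
    cross_table_differences,
    education_level_sums,
    link_sign_matrix,
    load_all_tables,
    load_summary_stats,
    mean_significant_links,
)

OUT = Path("results/aggregation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = load_all_tables()
    stats = load_summary_stats()

    avg = coupling_averages(tables)
    print(f"average couplings: health->happiness {avg['eta3']:.3f}, "
          f"lagged happiness->health {avg['theta3']:.3f}")

    link_sign_matrix(tables, alpha=0.10).to_csv(OUT / "sign_matrix.csv")

    means = {f"{tid}/{eq}/{group}":
             mean_significant_links(tables[(tid, eq)], group, 0.10)
             for tid in ("T3", "T4", "T5", "T6") for eq in ("LS", "HLEB")
             for group in ("REL", "EDU")}
    print("mean significant religion links (happiness):",
          [round(means[f"{t}/LS/REL"], 2) for t in ("T3", "T4", "T5", "T6")])
    print("mean significant religion links (health):   ",
          [round(means[f"{t}/HLEB/REL"], 2) for t in ("T3", "T4", "T5", "T6")])

    for eq in ("LS", "HLEB"):
        for policy in ("raw", "zero_ns", "null_if_either_ns"):
            d = cross_table_differences(tables[("T3", eq)], tables[("T5", eq)],
                                        policy=policy)
            d.to_csv(OUT / f"diff_majority_minus_minority_{eq}_{policy}.csv",
                     index=False)

    sums = {}
    for ctx, (soc, ind) in {"majority": ("T3", "T6"),
                            "minority": ("T5", "T4")}.items():
        for eq in ("LS", "HLEB"):
            s = education_level_sums(tables[(soc, eq)], tables[(ind, eq)], stats)
            sums[f"{ctx}/{eq}"] = s.to_dict("records")
            print(f"cumulative education sums, {ctx} context, {eq}: "
                  f"{[round(r['cumulative'], 2) for r in s.to_dict('records')]}")
    payload = {"couplings": avg,
               "mean_significant_links": {k: (None if v != v else v)
                                          for k, v in means.items()},
               "education_level_sums": sums}
    (OUT / "aggregation.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
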