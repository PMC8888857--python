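#!/usr/bin/env python
"""Crude decile odds ratios from the published per-decile counts.

Recomputes, with the package's 2x2 estimator, the case/control odds
ratio of every PRS decile against the median decile from the counts
printed for the two hypertension cohorts, flagging the rows where the
crude cross-product ratio reproduces the printed OR at two decimals
(the remaining printed values are consistent with covariate-adjusted
estimates, which per-decile counts alone cannot reproduce).
"""

from pathlib import Path

import pandas as pd

from pathprs.assoc import odds_ratio_2x2

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

# decile -> (cases, controls, printed OR); decile 5 is the reference
TARGET = {1: (28, 102, 0.44), 2: (34, 96, 0.56), 3: (44, 85, 0.82),
          4: (50, 79, 1.0), 5: (50, 79, 1.0), 6: (55, 74, 1.17),
          7: (68, 61, 1.76), 8: (67, 62, 1.70), 9: (75, 54, 2.18),
          10: (90, 39, 3.62)}
VALIDATION = {1: (70, 155, 0.32), 2: (93, 132, 0.51), 3: (98, 126, 0.56),
              4: (110, 114, 0.69), 5: (130, 94, 1.0), 6: (132, 92, 1.03),
              7: (136, 88, 1.11), 8: (147, 76, 1.39), 9: (169, 55, 2.21),
              10: (183, 41, 3.21)}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, counts in (("target", TARGET), ("validation", VALIDATION)):
        ref_ca, ref_co, _ = counts[5]
        for decile, (n_ca, n_co, printed) in counts.items():
            res = odds_ratio_2x2(n_ca, n_co, ref_ca, ref_co)
            crude = round(res["odds_ratio"], 2)
            rows.append({
                "cohort": label, "decile": decile, "n_cases": n_ca,
                "n_controls": n_co, "crude_or": crude, "printed_or": printed,
                "ci_low": round(res["ci_low"], 2),
                "ci_high": round(res["ci_high"], 2),
                "p_value": res["p_value"],
                "reproduces_print": crude == printed,
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "published_decile_ors.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    n_match = int(table["reproduces_print"].sum())
    print(f"\n{n_match}/20 printed ORs equal the crude cross-product ratio "
          "(including the two reference deciles); the rest differ in the "
          "second decimal, as expected if they were covariate-adjusted.")


if __name__ == "__main__":
    main()
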