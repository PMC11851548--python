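#!/usr/bin/env python
"""Population and expression statistics on the published inputs.

Reproduces the segregation chi-square for the reported 156:44 F2 counts
(under both degrees-of-freedom conventions), the short-day heading-date
contrast, worked 2^-ddCt examples, and a DEG screen of a synthetic
differential-expression table under the log2FC > 0.5 & padj < 0.05 rule.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from bsamap.genstats import (
    QpcrSample,
    chi_square_gof,
    filter_degs,
    relative_expression,
    trait_compare,
)


def main() -> None:
    common.RESULTS.mkdir(exist_ok=True)
    rows = []

    seg1 = chi_square_gof((156, 44), (3, 1))
    seg2 = chi_square_gof((156, 44), (3, 1), df=2)
    rows.append(("segregation_chi2", seg1.chi2))
    rows.append(("segregation_p_df1", seg1.p))
    rows.append(("segregation_p_df2", seg2.p))
    print(f"F2 segregation 156:44 vs 3:1 -> chi2 {seg1.chi2:.4f}; "
          f"p {seg1.p:.4f} (df=1) / {seg2.p:.4f} (df=2)")

    trait = trait_compare([63.3, 63.3, 63.3], [71.6, 71.6, 71.6])
    rows.append(("heading_date_difference_days", trait["mean_difference"]))
    print(f"short-day heading dates 63.3 vs 71.6 -> difference "
          f"{trait['mean_difference']:.1f} days")

    fc = relative_expression(QpcrSample(25.0, 20.0, 22.0, 20.0))
    rows.append(("ddct_example_fold_change", fc))
    print(f"2^-ddCt example (sample Ct 25/20 vs calibrator 22/20): fold change {fc:g}")

    rng = np.random.default_rng(common.DEMO_SEED)
    table = pd.DataFrame(
        {"gene": [f"g{i:03d}" for i in range(400)],
         "log2fc": rng.normal(0, 0.6, 400),
         "padj": rng.uniform(0, 1, 400) ** 2}
    )
    up, down = filter_degs(table)
    rows.append(("deg_up", len(up)))
    rows.append(("deg_down", len(down)))
    print(f"DEG screen of a synthetic 400-gene table: {len(up) + len(down)} DEGs "
          f"({len(up)} up, {len(down)} down)")

    out = common.RESULTS / "04_stats.tsv"
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
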