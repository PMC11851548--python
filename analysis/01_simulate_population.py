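#!/usr/bin/env python
"""Simulate the mapping population and check its Mendelian segregation.

Builds the demo cross (EMS mutant x progenitor, F1 selfed to F2, one
heterozygous F2 founder selfed into an F3 family of 200) and asks whether
the late:normal phenotype counts are consistent with the 3:1 ratio expected
for a monogenic recessive trait.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from bsamap.genstats import chi_square_gof


def main() -> None:
    run = common.demo_run()
    seg = pd.read_csv(run / "segregation.tsv", sep="\t")
    truth = pd.read_csv(run / "truth.tsv", sep="\t")
    normal, late = int(seg.normal[0]), int(seg.late[0])
    res = chi_square_gof((normal, late), (3, 1))
    out = common.RESULTS / "01_segregation.tsv"
    seg.to_csv(out, sep="\t", index=False)
    print(f"simulated F3 family: {normal} normal : {late} late "
          f"(expected 150:50 under 3:1)")
    print(f"chi2 = {res.chi2:.4f}, df = {res.df}, p = {res.p:.4f} -> "
          f"{'consistent with' if res.p > 0.05 else 'deviates from'} 3:1")
    print(f"{len(truth)} simulated variants, "
          f"{int(truth.is_causal.sum())} causal; truth table at {run/'truth.tsv'}")
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
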