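"""Institutional-delivery odds ratios by wealth quintile and covariates.

Reads the per-round odds-ratio tables written by 02 (re-running the
pipeline if needed) and prints the wealth-quintile block: unadjusted and
covariate-adjusted odds ratios with 95% intervals, mirroring the layout of
a survey report's determinants table.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for year in (2008, 2013):
        run_dir = ROOT / f"survey_{year}"
        if not (run_dir / "delivery_or_adjusted.csv").exists():
            raise SystemExit("run analysis/02_concentration_analysis.py first")
        print(f"== {year}: odds of facility delivery ==")
        for kind in ("unadjusted", "adjusted"):
            t = pd.read_csv(run_dir / f"delivery_or_{kind}.csv")
            wq = t[t["covariate"] == "wealth_quintile"].copy()
            wq["95% CI"] = wq.apply(
                lambda r: f"({r.ci_low:.2f}, {r.ci_high:.2f})", axis=1)
            print(f"-- {kind} --")
            print(wq[["level", "odds_ratio", "95% CI", "p_value"]]
                  .round(3).to_string(index=False))
        rich = pd.read_csv(run_dir / "delivery_or_unadjusted.csv").query(
            "covariate == 'wealth_quintile' and level == 'richest'").iloc[0]
        print(f"{year}: richest-vs-poorest unadjusted OR "
              f"{rich.odds_ratio:.2f} (SE {rich.or_se:.3f})")


if __name__ == "__main__":
    main()
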