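"""Cohort statistics over the sealing outputs.

Reads results/sealing.csv (produced by 03_deploy_and_seal.py), rebuilds the
grouped summary (BAV0 / BAV1 / pooled BAV / TAV columns with a test-selected
p-value per row), screens baseline covariates for association with
interleaflet-triangle malapposition at p < 0.1, and runs the stepwise
linear regression on the retained candidates.  Also reproduces the
published worked examples directly from printed summary statistics.
"""

import json
from pathlib import Path

import pandas as pd

from tavrseal import stats
from tavrseal.pipeline import SCREEN_CANDIDATES

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    print("published worked examples (from printed summary statistics):")
    for label, args in [
        ("  total malapposition %  ", (22.7, 10.5, 26, 15.5, 9.8, 17)),
        ("  malapposed leaflet mm^2", (71.8, 40.1, 26, 56.8, 30.1, 17)),
        ("  apposed leaflet mm^2   ", (612.4, 154.3, 26, 611.5, 193.6, 17)),
    ]:
        print(f"{label}: p = {stats.pooled_t_from_summary(*args).p_value:.4f}")
    print(f"  moderate PVL (Fisher)  : p = "
          f"{stats.fisher_exact_2x2([[5, 21], [1, 16]]).p_value:.4f}")
    print(f"  pacemaker (Fisher)     : p = "
          f"{stats.fisher_exact_2x2([[2, 24], [2, 15]]).p_value:.4f}")

    sealing_path = OUT / "sealing.csv"
    if not sealing_path.exists():
        print(f"\n{sealing_path} not found -- run 03_deploy_and_seal.py first")
        return
    table = pd.read_csv(sealing_path)
    group = stats.group_summary(table, [
        c for c in table.columns
        if c.startswith(("apposed_area", "malapposed_area", "malapposition",
                         "apposition"))])
    group.to_csv(OUT / "group_summary.csv", index=False)
    print("\ngrouped sealing summary (BAV vs TAV p-values):")
    print(group[["variable", "BAV", "TAV", "p_value", "test"]].to_string())

    retained, pvals, _ = stats.univariate_screen(
        table, "malapposition_pct_triangle", SCREEN_CANDIDATES)
    print(f"\nunivariate screen (p < 0.1): retained {retained}")
    if retained:
        model = stats.stepwise_lm(table, "malapposition_pct_triangle", retained)
        print(f"stepwise model terms: {model.terms}")
        print(f"coefficients: { {k: round(v, 3) for k, v in model.coefficients.items()} }")
        print(f"per-term p: { {k: round(v, 4) for k, v in model.p_values.items()} }")
        (OUT / "stepwise_model.json").write_text(json.dumps({
            "terms": model.terms, "coefficients": model.coefficients,
            "p_values": model.p_values, "screen_p_values": pvals}, indent=2))


if __name__ == "__main__":
    main()
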