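"""Stagewise statistics: is the requirement to change u-shaped?

Reads the feature table produced by 02_run_pipeline.py and reports, for
frustration and negative-link density: the Shapiro-Wilk gate, the
Kruskal-Wallis multi-stage comparison, and the Dunn/BH post hoc table.
Then models frustration on negative density (nested polynomial fits with
partial-F selection) and tests the stage x density interaction.
Tables are written under results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from frustnet import (
    STAGES,
    dunn_posthoc,
    fit_poly_and_select,
    interaction_test,
    kruskal_wallis,
    mann_whitney,
    normality_gate,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--features", type=Path, default=ROOT / "results" / "pipeline" / "features.csv"
    )
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = parser.parse_args()
    if not args.features.is_file():
        raise SystemExit(f"{args.features} missing; run 02_run_pipeline.py first")
    table = pd.read_csv(args.features)
    args.out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(table["stage"])]

    for feature in ("frustration", "neg_density"):
        groups = {s: table.loc[table["stage"] == s, feature].to_numpy() for s in stages}
        gate = normality_gate(groups)
        kw = kruskal_wallis(groups)
        route = "nonparametric" if gate.nonparametric else "parametric"
        print(f"\n=== {feature} ===")
        print(f"Shapiro-Wilk gate: {route} "
              f"(min p = {min(gate.p_by_group.values()):.2e})")
        print(f"Kruskal-Wallis: H = {kw.statistic:.2f}, df = {kw.df:.0f}, "
              f"p = {kw.pvalue:.3e}")
        medians = {s: float(pd.Series(v).median()) for s, v in groups.items()}
        print("stage medians:", {s: round(m, 4) for s, m in medians.items()})
        print("minimum-median stage:", min(medians, key=medians.get))
        dunn = dunn_posthoc(groups)
        dunn.to_csv(args.out / f"dunn_{feature}.csv", index=False)
        print(f"Dunn/BH post hoc ({int(dunn['significant'].sum())} of "
              f"{len(dunn)} pairs significant) -> dunn_{feature}.csv")

    sel = fit_poly_and_select(table)
    print("\n=== frustration ~ negative density ===")
    for (a, b), (f_stat, p) in sel.f_tests.items():
        print(f"degree {b} vs {a}: F = {f_stat:.2f}, p = {p:.3e}")
    print(f"selected degree: {sel.selected_degree}")
    coef = sel.coefficients[sel.selected_degree]
    print("coefficients (ascending powers):", [f"{c:.4g}" for c in coef])
    inter = interaction_test(table, degree=sel.selected_degree)
    print(f"stage x density interaction: F = {inter.statistic:.2f}, "
          f"df = {inter.df}, p = {inter.pvalue:.3e}")

    males = table.loc[table["sex"] == "male", "frustration"]
    females = table.loc[table["sex"] == "female", "frustration"]
    mw = mann_whitney(males, females)
    print(f"\nsex comparison (frustration, pooled): U = {mw.statistic:.0f}, "
          f"p = {mw.pvalue:.3f} (no sex effect is planted by default, so any "
          "significance here is a false positive of this seed)")

    rows = [
        {"comparison": f"deg{b}_vs_deg{a}", "F": f, "p": p}
        for (a, b), (f, p) in sel.f_tests.items()
    ]
    rows.append({"comparison": "stage_x_density", "F": inter.statistic, "p": inter.pvalue})
    pd.DataFrame(rows).to_csv(args.out / "model_selection.csv", index=False)
    print(f"\nmodel-selection table -> {args.out / 'model_selection.csv'}")


if __name__ == "__main__":
    main()
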