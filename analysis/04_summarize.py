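"""Cross-condition summaries for the demo cohort.

Computes the overall (all-cells) residual, each cell type's difference from
it, the cell-weighted SD of residuals, a weighted correlation of estimated
vs true residuals, a washout-recovery table from a second simulated
late-timepoint cohort, and a delta-delta-Ct estimate from a matched
synthetic qPCR table. Writes results/summary/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kdquant import counts_io, nb_model, summaries
from kdquant.synthetic import CellTypeSpec, CohortSpec, generate_cohort, generate_qpcr_table

RESULTS = Path("results")


def late_timepoint_spec(seed: int = 21) -> CohortSpec:
    # same design as 01_simulate but with washed-out (higher) residuals
    return CohortSpec(
        cell_types=[
            CellTypeSpec("astrocyte", 0.40, 1.5e-4, 2.0, residual=0.85),
            CellTypeSpec("neuron", 0.40, 3.0e-4, 2.0, residual=0.60),
            CellTypeSpec("microglia", 0.20, 0.8e-4, 2.0, residual=0.95),
        ],
        n_animals_per_arm=4,
        cells_per_animal=2000,
        seed=seed,
        target_name="Prnp",
        weeks_post_dose=24.0,
    )


def main() -> None:
    out = RESULTS / "summary"
    out.mkdir(parents=True, exist_ok=True)
    est = pd.read_csv(RESULTS / "fit" / "estimates.tsv", sep="\t")
    table = counts_io.read_pseudobulk(RESULTS / "pseudobulk.tsv")

    overall = nb_model.overall_residual(table, "control")
    profile = summaries.difference_from_overall(
        "demo_12wk",
        est["cell_type"].tolist(),
        est["residual"].to_numpy(),
        100.0 * overall.residual,
        n_cells=est["n_cells"].to_numpy(),
    )
    profile.to_frame().to_csv(out / "profile.tsv", sep="\t", index=False)
    wsd = summaries.weighted_sd(profile.residuals, est["n_cells"].to_numpy())
    print(f"overall residual: {100 * overall.residual:.1f}% of control")
    for ct, diff in zip(profile.cell_types, profile.differences):
        print(f"  {ct:<10} difference from overall: {diff:+6.1f} points")
    print(f"cell-weighted SD of residuals: {wsd:.1f} points")

    truth = {"astrocyte": 56.0, "neuron": 30.0, "microglia": 80.0}
    rho, p = summaries.weighted_pearson(
        est["residual"].to_numpy(),
        np.array([truth[ct] for ct in est["cell_type"]]),
        est["n_cells"].to_numpy(),
    )
    print(f"weighted Pearson estimated vs true residuals: rho={rho:.3f}, P={p:.2g}")

    # washout: fit a late-timepoint cohort and tabulate recovery per cell type
    late = generate_cohort(late_timepoint_spec())
    late_table = counts_io.aggregate_pseudobulk(late.counts, late.annotations, "Prnp")
    late_design = nb_model.DesignSpec.from_table(late_table, "control")
    late_fit = nb_model.fit_nb_offset_model(late_table, late_design)
    late_est = nb_model.estimates_to_frame(
        nb_model.residual_fractions(late_fit, late_design, late_table)
    )
    late_est["residual"] = 100.0 * late_est["residual"]
    merged = est.merge(late_est, on="cell_type", suffixes=("_early", "_late"))
    merged["recovery_points"] = [
        summaries.recovery(e, l)
        for e, l in zip(merged["residual_early"], merged["residual_late"])
    ]
    merged[["cell_type", "residual_early", "residual_late", "recovery_points"]].to_csv(
        out / "recovery.tsv", sep="\t", index=False
    )
    print("washout recovery (percentage points, 12 -> 24 weeks):")
    for _, row in merged.iterrows():
        print(f"  {row.cell_type:<10} {row.residual_early:5.1f}% -> "
              f"{row.residual_late:5.1f}%  (+{row.recovery_points:.1f})")

    # matched bulk qPCR: residual truth = overall residual of the cohort
    q = generate_qpcr_table(overall.residual, n_per_arm=4, ct_noise_sd=0.15, seed=31)
    _, per_arm = summaries.ddct_residual(q, "control")
    qpcr = float(per_arm.loc[per_arm.treatment == "ASO", "residual_percent"].iloc[0])
    print(f"bulk qPCR ddCt residual: {qpcr:.1f}% "
          f"(single-nucleus overall: {100 * overall.residual:.1f}%)")
    (out / "summary.json").write_text(json.dumps(
        {"overall_residual_percent": 100 * overall.residual,
         "weighted_sd_points": wsd,
         "rho_est_vs_truth": rho,
         "qpcr_residual_percent": qpcr}, indent=2))


if __name__ == "__main__":
    main()
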