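"""Quantify GLUT expression per visual field with dual-observer replication.

Each field's stained-area fraction is read three times by each of two
simulated observers; the grand mean is the consensus value recorded for the
analysis.  Writes per-group medians of the consensus stained fraction per
marker under results/.
"""

from pathlib import Path

from glutmorph import CohortDesign, generate_cohort
from glutmorph.pipeline import simulate_stain_measurements

SEED = 0
RESULTS = Path("results")


def main():
    cohort = generate_cohort(CohortDesign(seed=SEED))
    meas = simulate_stain_measurements(cohort, SEED)
    RESULTS.mkdir(exist_ok=True)

    summary = (
        meas.groupby(["marker", "group"])
        .consensus_fraction.agg(
            n_fields="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .round(4)
        .reset_index()
    )
    summary.to_csv(RESULTS / "stain_fraction_by_group.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\n{len(meas)} field consensus measurements written")


if __name__ == "__main__":
    main()
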