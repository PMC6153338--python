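"""Generate the synthetic study cohorts used by the downstream analyses.

Writes, under results/data/:
  * a four-preset cohort (bursting / tonic / irregular / quiet, 10 neurons
    each) with ground-truth labels, as spike + metadata CSVs;
  * a two-group burst-effect cohort (15 cells per group; the second group's
    mean burst length is doubled) for the group-comparison analysis.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from gnburst.io import write_spike_csv
from gnburst.pattern_classifier import Pattern
from gnburst.synthetic_data import STANDARD_PRESETS, CohortSpec, generate_cohort

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    groups = tuple(
        (("saline", pat.value), 10, preset) for pat, preset in STANDARD_PRESETS.items()
    )
    cohort = generate_cohort(CohortSpec(groups=groups, master_seed=SEED))
    write_spike_csv([tr for tr, _, _ in cohort], OUT / "presets_spikes.csv", OUT / "presets_meta.csv")
    pd.DataFrame(
        {
            "neuron_id": [tr.neuron_id for tr, _, _ in cohort],
            "true_pattern": [t.pattern.value for _, t, _ in cohort],
        }
    ).to_csv(OUT / "presets_truth.csv", index=False)
    print(f"four-preset cohort: {len(cohort)} neurons → {OUT}/presets_*.csv")

    base = STANDARD_PRESETS[Pattern.BURSTING]
    effect = dataclasses.replace(base, spikes_per_burst_mean=12.0)
    pair = generate_cohort(
        CohortSpec(
            groups=(
                (("saline", "diestrus"), 15, base),
                (("ka_long", "diestrus"), 15, effect),
            ),
            master_seed=SEED + 1,
        )
    )
    write_spike_csv([tr for tr, _, _ in pair], OUT / "effect_spikes.csv", OUT / "effect_meta.csv")
    print(f"burst-effect cohort: {len(pair)} neurons → {OUT}/effect_*.csv")


if __name__ == "__main__":
    main()
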