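"""Simulate the benchmark breath cohort and write it to results/data/.

Generates the strong-signal benchmark cohort (25 cases vs 186 controls,
three planted discriminant VOC features, season/zone batch effects, paired
room-air samples with contaminant and ambient-dominant features) and writes
the four artifacts as CSV/JSON so the later steps can load them.
"""

import argparse
import json
from pathlib import Path

from breathvoc.core_data import write_feature_meta, write_sample_meta
from breathvoc.synthetic_data import GeneratorConfig, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 42) -> None:
    config = GeneratorConfig(
        n_case=25, n_control=186, n_discriminant=3, effect_log2=2.0, seed=seed
    )
    table, sample_meta, feature_meta, truth = generate_cohort(config)

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    table.write(out / "feature_table.csv")
    write_sample_meta(sample_meta, out / "sample_meta.csv")
    write_feature_meta(feature_meta, out / "feature_meta.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "discriminant_ids": truth.discriminant_ids,
                "contaminant_ids": truth.contaminant_ids,
                "ambient_dominant_ids": truth.ambient_dominant_ids,
                "true_betas": truth.true_betas,
                "seed": seed,
            },
            fh,
            indent=2,
        )

    n_breath = sum(1 for m in sample_meta if m.sample_type == "breath")
    n_train = sum(
        1 for m in sample_meta
        if m.sample_type == "breath" and m.split == "train"
    )
    print(f"wrote cohort to {out}")
    print(f"  {n_breath} breath samples ({n_train} train / "
          f"{n_breath - n_train} validation), each with one ambient partner")
    print(f"  {len(table.feature_ids)} features; planted discriminants: "
          f"{truth.discriminant_ids}")
    print(f"  contaminants: {truth.contaminant_ids}; "
          f"ambient-dominant: {truth.ambient_dominant_ids}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    main(parser.parse_args().seed)
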