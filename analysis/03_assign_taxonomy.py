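#!/usr/bin/env python
"""MAG quality control, species clustering and protein-to-MAG assignment on
the synthetic community; verify against truth.

Requires 01_simulate_community.py.  Writes results/species_clusters.tsv.
"""

from pathlib import Path

import pandas as pd

from pulquant.pipeline import RunConfig, taxonomy_stage
from pulquant.synthetic_data import GeneratorConfig, generate_community

SEED = 11
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    in_dir = ROOT / "scratch/synthetic/clean"
    truth = generate_community(GeneratorConfig(seed=SEED, clean=True), in_dir)
    cfg = RunConfig.from_dir(in_dir, ROOT / "scratch/taxa_out")

    species, assignments, _ = taxonomy_stage(cfg)
    pd.DataFrame(
        [
            {"representative": s.representative, "members": ",".join(sorted(s.members))}
            for s in species
        ]
    ).sort_values("representative").to_csv(
        ROOT / "results/species_clusters.tsv", sep="\t", index=False
    )

    correct = sum(assignments[p] == m for p, m in truth.mag_assign_truth.items())
    n = len(truth.mag_assign_truth)
    unassigned = sum(v == "unassigned" for v in assignments.values())
    print(f"species clusters: {len(species)} (from {len(truth.mags)} MAGs, QC drops "
          f"{len(truth.mags) - len(truth.retained_mags)})")
    print(f"protein->MAG assignment: {correct}/{n} correct, {unassigned} unassigned")
    reps = {s.representative for s in species}
    print(f"representatives match truth: {reps == set(truth.representatives.values())}")


if __name__ == "__main__":
    main()
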