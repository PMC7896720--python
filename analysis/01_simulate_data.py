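#!/usr/bin/env python
"""Generate the synthetic datasets used by the downstream analyses.

Three genotype panels and one growth dataset, each with full ground
truth, written under results/data/:

* ``calibration`` — clean two-population Balding-Nichols panels at
  F = 0, 0.02 and 0.05 (estimator calibration);
* ``missingness`` — a four-population panel in which POP1/POP2 are one
  panmictic unit and POP3/POP4 are diverged background populations;
  55% of loci get 50-90% dropout in POP1 (the PER03-style pattern);
* ``undersplit`` — a four-population panel whose first two populations
  are a temporal pair (true theta 0) carrying merged-paralog loci in
  the first sample (the CHA03-style pattern), plus read depths;
* ``growth`` — length-at-age records drawn from the hierarchical model
  at its default truth (24 mm reference decline, 40 mm in the south).
"""

import json
from pathlib import Path

from radqc import genotype_io as gio
from radqc.synthetic_data import (
    GenoSimConfig,
    GrowthSimConfig,
    simulate_genotypes,
    simulate_growth,
)

SEED = 20260921
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for f in (0.0, 0.02, 0.05):
        cfg = GenoSimConfig(n_pops=2, n_per_pop=50, n_loci=5000,
                            target_fst=f, seed=SEED)
        matrix, _, truth = simulate_genotypes(cfg)
        tag = str(f).replace(".", "")
        gio.write_genepop(matrix, OUT / f"calibration_f{tag}.genepop")
        print(f"calibration F={f}: {matrix.n_individuals} ind x "
              f"{matrix.n_loci} loci")

    cfg = GenoSimConfig(
        n_pops=4, n_per_pop=30, n_loci=3000,
        target_fst=[0.0, 0.0, 0.08, 0.08],
        pop_dropout={0: (0.55, (0.5, 0.9))}, seed=SEED + 1,
    )
    matrix, _, truth = simulate_genotypes(cfg)
    gio.write_genepop(matrix, OUT / "missingness.genepop")
    (OUT / "missingness_truth.json").write_text(json.dumps(truth))
    print(f"missingness panel: {matrix.n_individuals} ind x {matrix.n_loci} loci")

    cfg = GenoSimConfig(
        n_pops=4, n_per_pop=40, n_loci=2000,
        target_fst=[0.0, 0.0, 0.04, 0.04],
        frac_undersplit=0.04, undersplit_pops=(0,),
        undersplit_latent_freq_range=(0.35, 0.95), seed=SEED + 2,
    )
    matrix, depths, truth = simulate_genotypes(cfg)
    gio.write_genepop(matrix, OUT / "undersplit.genepop")
    gio.write_depth_table(depths, OUT / "undersplit_depths.tsv")
    (OUT / "undersplit_truth.json").write_text(json.dumps(truth))
    print(f"undersplit panel: {matrix.n_individuals} ind x {matrix.n_loci} loci, "
          f"{sum(c == 'undersplit' for c in truth['classes'])} artifact loci")

    data, truth = simulate_growth(GrowthSimConfig(n_per_cell=125, seed=SEED + 3))
    gio.write_growth_table(data, OUT / "growth.csv")
    (OUT / "growth_truth.json").write_text(json.dumps(truth))
    print(f"growth data: {len(data)} records over {len(data.rivers)} rivers")


if __name__ == "__main__":
    main()
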