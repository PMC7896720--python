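#!/usr/bin/env python
"""Characterize per-locus F_ST distributions with subsample normalization.

On the fully filtered dataset (dataset 4 of the cascade), bins the
per-locus F_ST values of the temporal and control pairs, with and
without random subsampling to a common sample size of 30 — the
normalization that makes distributions comparable across pairs with
different sample sizes. Writes results/fst_distributions.tsv.
"""

from pathlib import Path

import pandas as pd

from radqc import genotype_io as gio
from radqc import pipeline, structure_analysis as sa

DATA = Path("results/data")
OUT = Path("results")
SEED = 20260921


def main() -> None:
    matrix = gio.read_genepop(DATA / "undersplit.genepop")
    d4, _ = pipeline.four_datasets(matrix, ("POP1", "POP2"))["d4_fis_0"]

    rows = []
    for pa, pb in (("POP1", "POP2"), ("POP3", "POP4")):
        for sub in (None, 30):
            dist = sa.fst_distribution(d4, pa, pb, subsample_n=sub, seed=SEED)
            rows.append(dist.to_row())
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "fst_distributions.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
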