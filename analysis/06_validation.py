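#!/usr/bin/env python
"""Validation computations: concordance between EST-count fold changes and
pseudo-qPCR measurements (noise-free and at the default noise level), and
the total-chlorophyll closed form on an absorbance series.

Writes results/validation.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from stagewave.io_formats import read_count_matrix
from stagewave.synthetic_data import generate_qpcr
from stagewave.validation_utils import chlorophyll_total, concordance, est_relative_expression

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main():
    counts = read_count_matrix(BASE / "synthetic" / "counts.tsv")
    lib0 = counts.libraries[0]
    genes = [c for c in counts.totals.sort_values(ascending=False).index
             if counts.df.loc[c, lib0] > 0][:14]
    est = est_relative_expression(counts, genes)

    rows = []
    for noise in (0.0, 0.25):
        qpcr, _ = generate_qpcr(counts, genes, noise_sd=noise, seed=SEED)
        merged = est.merge(qpcr, on=["gene_id", "age_dpp"])
        res = concordance(merged["fold"], merged["relative_quantity"])
        rows.append({"noise_sd": noise, **{k: res[k] for k in ("pearson_r", "r_squared", "n")}})
        print(f"noise_sd={noise}: R^2 = {res['r_squared']:.3f} over {res['n']} "
              f"gene/age comparisons")
    pd.DataFrame(rows).to_csv(BASE / "validation.tsv", sep="\t", index=False)

    # chlorophyll declining with age, per-gram basis
    a665 = np.array([0.42, 0.55, 0.38, 0.21, 0.18])
    a647 = np.array([0.20, 0.28, 0.19, 0.11, 0.09])
    total = chlorophyll_total(a665, a647, volume_ml=5.0, mass_g=1.0)
    for age, t in zip((0, 4, 8, 12, 16), total):
        print(f"chlorophyll at {age:>2} dpp: {t:6.2f} ug/g fresh weight")


if __name__ == "__main__":
    main()
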