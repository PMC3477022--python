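#!/usr/bin/env python
"""Discover developmental stage groups: PCA of the five libraries over
depth-normalized expression of the filtered contigs, contiguity-constrained
grouping into three stages, and the Venn partition of detection across
groups.

Writes results/stage_groups.tsv and results/venn.tsv.
"""

from pathlib import Path

import pandas as pd

from stagewave.abundance_filtering import filter_min_reads, tpt
from stagewave.io_formats import read_count_matrix
from stagewave.stage_grouping import group_ages, pca_libraries, venn_partition

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    counts = read_count_matrix(BASE / "synthetic" / "counts.tsv")
    kept, _ = filter_min_reads(counts, 30)
    T = tpt(counts)

    pca = pca_libraries(T, restrict_to=kept.contig_ids)
    print("variance fractions:", [round(float(v), 3) for v in pca.variance_fraction])
    print(f"PC1+PC2 explain {pca.variance_fraction[:2].sum():.1%} of library variance")

    scheme = group_ages(pca, n_groups=3)
    print("stage groups:", scheme.names)

    out = pca.scores.iloc[:, :2].copy()
    out["group"] = [next(n for n, g in zip(scheme.names, scheme.groups) if lib in g)
                    for lib in out.index]
    out.rename_axis("library").to_csv(BASE / "stage_groups.tsv", sep="\t")

    venn = venn_partition(kept, scheme, detect_min=1)
    pd.DataFrame(sorted(venn.items()), columns=["region", "n_contigs"]).to_csv(
        BASE / "venn.tsv", sep="\t", index=False)
    print("venn regions:", venn)
    uniq = {k: v for k, v in venn.items() if "&" not in k}
    print(f"fewest group-unique contigs: {min(uniq, key=uniq.get)}")


if __name__ == "__main__":
    main()
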