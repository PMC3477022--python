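#!/usr/bin/env python
"""Expression-shape clustering and functional enrichment: K-means over
per-age portion profiles (k=10), and GO normalized-frequency enrichment of
each stage group's tail set against the genome background, with bootstrap
SDs and hypergeometric p-values.

Writes results/clusters.tsv and results/go_enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from stagewave.abundance_filtering import filter_min_reads, tpt
from stagewave.age_enrichment import group_proportions, tail_sets
from stagewave.clustering_go import go_enrichment, kmeans_profiles
from stagewave.io_formats import read_count_matrix
from stagewave.stage_grouping import AgeGroupScheme
from stagewave.synthetic_data import SyntheticTruth, generate_go_map

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main():
    counts = read_count_matrix(BASE / "synthetic" / "counts.tsv")
    annotations = pd.read_csv(BASE / "synthetic" / "annotations.tsv", sep="\t",
                              dtype={"contig_id": str})
    truth = SyntheticTruth(pd.read_csv(BASE / "synthetic" / "truth.tsv", sep="\t",
                                       dtype={"contig_id": str}))
    kept, _ = filter_min_reads(counts, 30)
    T = tpt(counts)

    ages = sorted({a for a in counts.ages})
    per_age = AgeGroupScheme.from_ages([(a,) for a in ages], counts.libraries)
    age_prof = group_proportions(T, per_age, filtered_ids=kept.contig_ids)
    km = kmeans_profiles(age_prof, k=10, seed=SEED)
    km.labels.rename_axis("contig_id").to_frame().to_csv(BASE / "clusters.tsv", sep="\t")
    print(f"k-means: k={km.k}, inertia={km.inertia:.3f}")
    print("cluster centroids (per-age portions):")
    print(km.centroids.round(3).to_string())

    scheme = AgeGroupScheme.from_ages([(0, 4), (8,), (12, 16)], counts.libraries)
    prof = group_proportions(T, scheme, filtered_ids=kept.contig_ids)
    tails = tail_sets(prof, 0.025, totals=counts.totals)
    go_map, genome_freq = generate_go_map(annotations, truth, seed=SEED)

    frames = []
    for g, ids in tails.sets.items():
        with_go = [c for c in ids if c in go_map]
        enr = go_enrichment(with_go, go_map, genome_freq, seed=SEED)
        enr.insert(0, "group", g)
        frames.append(enr.reset_index())
        sig = enr[(enr["p_value"] < 0.05) & (enr["normalized_frequency"] > 1)]
        print(f"{g}: {len(with_go)} genes with GO; enriched (P<0.05): "
              f"{', '.join(f'{c} ({r.normalized_frequency:.2f}x)' for c, r in sig.iterrows())}")
    pd.concat(frames, ignore_index=True).to_csv(BASE / "go_enrichment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
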