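"""End-to-end orchestration: simulate or ingest counts, then annotate,
normalize, filter, group stages, compute stage-enriched sets, cluster, and
validate, writing every stage's table plus a run manifest.

All randomness flows from a single top-level seed; each stage derives its
own sub-seed by stable hashing of the stage name, so reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance_filtering import filter_min_reads, saturation_profile, summary_stats, tpt
from .age_enrichment import group_proportions, tail_sets, top_represented
from .clustering_go import go_enrichment, kmeans_profiles
from .io_formats import CountMatrix, read_blast_tab, read_count_matrix, read_go_map
from .homology_annotation import classify_tier
from .stage_grouping import group_ages, pca_libraries, venn_partition
from .synthetic_data import (
    SimulationConfig,
    generate_counts,
    generate_go_map,
    generate_qpcr,
)
from .validation_utils import concordance, est_relative_expression


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # or "ingest"
    outdir: str = "stagewave_run"
    seed: int = 0
    # simulate mode
    n_contigs: int = 5000
    library_depths: tuple[int, ...] = (226_000,) * 5
    # ingest mode inputs
    counts_path: str | None = None
    lengths_path: str | None = None
    arabidopsis_blast_path: str | None = None
    nr_blast_path: str | None = None
    go_map_path: str | None = None
    # thresholds
    min_reads: int = 30
    tail_quantile: float = 0.025
    share_threshold: float = 0.001
    e_threshold: float = 1e-5
    detect_min: int = 1
    n_groups: int = 3
    k: int = 10
    n_qpcr_genes: int = 14
    qpcr_noise_sd: float = 0.25


def stage_seed(top_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    return (int(top_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in fixed order; returns the manifest dictionary.

    Stage outputs are TSVs under ``config.outdir``; the manifest records the
    configuration, derived seeds and per-stage row counts. A stage failure
    propagates with the stage name prefixed, leaving earlier outputs intact.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": [],
    }

    def record(stage: str, **info):
        manifest["stages"].append({"name": stage, **info})

    stage = "input"
    try:
        if config.mode == "simulate":
            sim = SimulationConfig(
                n_contigs=config.n_contigs,
                library_depths=tuple(config.library_depths),
                seed=stage_seed(config.seed, "simulate"),
                qpcr_noise_sd=config.qpcr_noise_sd,
            )
            counts, lengths, annotations, truth = generate_counts(sim)
            go_map, genome_freq = generate_go_map(
                annotations, truth, seed=stage_seed(config.seed, "go_map")
            )
            counts.df.rename_axis("contig_id").to_csv(out / "counts.tsv", sep="\t", lineterminator="\n")
            lengths.rename_axis("contig_id").to_frame().to_csv(out / "lengths.tsv", sep="\t", lineterminator="\n")
            _write(annotations, out / "annotations.tsv")
            _write(truth.table, out / "truth.tsv")
        elif config.mode == "ingest":
            counts = read_count_matrix(config.counts_path)
            lengths = (
                pd.read_csv(config.lengths_path, sep="\t", index_col=0)["length_bp"]
                if config.lengths_path
                else None
            )
            if config.arabidopsis_blast_path and config.nr_blast_path:
                at = read_blast_tab(config.arabidopsis_blast_path)
                nr = read_blast_tab(config.nr_blast_path)
                recs = classify_tier(
                    at, nr, e_threshold=config.e_threshold, contig_ids=counts.contig_ids
                )
                annotations = pd.DataFrame([vars(r) for r in recs.values()])
                _write(annotations, out / "annotations.tsv")
            else:
                annotations = None
            go_map = read_go_map(config.go_map_path) if config.go_map_path else None
            genome_freq = None
            truth = None
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        record(stage, n_contigs=len(counts.contig_ids), depths=[int(d) for d in counts.depths])

        stage = "normalize"
        tpt_all = tpt(counts)
        record(stage, column_sums=[round(float(s), 6) for s in tpt_all.sum(axis=0)])

        stage = "filter"
        kept, dropped = filter_min_reads(counts, config.min_reads)
        record(stage, kept=len(kept.contig_ids), dropped=len(dropped.contig_ids))

        stage = "overview"
        stats = summary_stats(counts, lengths)
        if lengths is not None and annotations is not None:
            sat = saturation_profile(counts, lengths, annotations)
            _write(sat.drop(columns="empty"), out / "saturation.tsv")
        record(stage, **stats)

        stage = "stages"
        pca = pca_libraries(tpt_all, restrict_to=kept.contig_ids)
        scheme = group_ages(pca, n_groups=config.n_groups)
        pd.DataFrame(
            {
                "library": pca.scores.index,
                "PC1": pca.scores.iloc[:, 0],
                "PC2": pca.scores.iloc[:, 1] if pca.scores.shape[1] > 1 else 0.0,
                "group": [
                    next(n for n, g in zip(scheme.names, scheme.groups) if lib in g)
                    for lib in pca.scores.index
                ],
            }
        ).to_csv(out / "stage_groups.tsv", sep="\t", index=False, lineterminator="\n")
        venn = venn_partition(kept, scheme, detect_min=config.detect_min)
        pd.DataFrame(sorted(venn.items()), columns=["region", "n_contigs"]).to_csv(
            out / "venn.tsv", sep="\t", index=False, lineterminator="\n"
        )
        record(
            stage,
            groups=scheme.names,
            variance_fraction=[round(float(v), 6) for v in pca.variance_fraction[:2]],
        )

        stage = "enrich"
        profiles = group_proportions(tpt_all, scheme, filtered_ids=kept.contig_ids)
        tails = tail_sets(profiles, config.tail_quantile, totals=counts.totals)
        for g, ids in tails.sets.items():
            _write(
                profiles.loc[ids].rename_axis("contig_id").reset_index(),
                out / f"tail_{g.replace('+', '_')}.tsv",
            )
        tops = top_represented(kept, scheme, config.share_threshold)
        for g, ids in tops.exclusive.items():
            _write(
                tops.shares.loc[ids].rename_axis("contig_id").reset_index(),
                out / f"top_exclusive_{g.replace('+', '_')}.tsv",
            )
        record(
            stage,
            tail_sizes={g: len(v) for g, v in tails.sets.items()},
            top_counts={g: len(v) for g, v in tops.lists.items()},
            top_exclusive={g: len(v) for g, v in tops.exclusive.items()},
        )

        stage = "cluster"
        age_profiles = group_proportions(
            tpt_all,
            scheme=_per_age_scheme(counts),
            filtered_ids=kept.contig_ids,
        )
        km = kmeans_profiles(age_profiles, k=config.k, seed=stage_seed(config.seed, "cluster"))
        km.labels.rename_axis("contig_id").to_frame().to_csv(
            out / "clusters.tsv", sep="\t", lineterminator="\n"
        )
        record(stage, k=km.k, inertia=round(km.inertia, 6))

        stage = "go_enrichment"
        if go_map and genome_freq and annotations is not None:
            per_group = []
            for g, ids in tails.sets.items():
                with_go = [c for c in ids if c in go_map]
                if len(with_go) >= 10:
                    enr = go_enrichment(
                        with_go,
                        go_map,
                        genome_freq,
                        seed=stage_seed(config.seed, f"go:{g}"),
                    )
                    enr.insert(0, "group", g)
                    per_group.append(enr.reset_index())
            if per_group:
                _write(pd.concat(per_group, ignore_index=True), out / "go_enrichment.tsv")
                record(stage, groups=len(per_group))

        stage = "validate"
        if config.mode == "simulate":
            candidates = kept.totals.sort_values(ascending=False)
            genes = [
                c
                for c in candidates.index
                if counts.df.loc[c, counts.libraries[0]] > 0
            ][: config.n_qpcr_genes]
            qpcr, _ = generate_qpcr(
                counts,
                genes,
                noise_sd=config.qpcr_noise_sd,
                seed=stage_seed(config.seed, "qpcr"),
            )
            est = est_relative_expression(counts, genes)
            merged = est.merge(qpcr, on=["gene_id", "age_dpp"])
            conc = concordance(merged["fold"], merged["relative_quantity"])
            _write(merged, out / "validation.tsv")
            record(stage, n=conc["n"], r_squared=round(conc["r_squared"], 6))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _per_age_scheme(counts: CountMatrix):
    from .stage_grouping import AgeGroupScheme

    ages = sorted(counts.age_columns())
    return AgeGroupScheme.from_ages([(a,) for a in ages], counts.libraries)
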