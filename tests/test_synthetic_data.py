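import numpy as np
import pandas as pd
import pytest

from stagewave.abundance_filtering import filter_min_reads, tpt
from stagewave.age_enrichment import group_proportions
from stagewave.io_formats import CountMatrix
from stagewave.stage_grouping import AgeGroupScheme
from stagewave.synthetic_data import (
    AGES,
    DEFAULT_PROGRAMS,
    SimulationConfig,
    StageProgram,
    generate_counts,
    generate_go_map,
    generate_lengths,
    generate_qpcr,
)

DIVISION = next(p for p in DEFAULT_PROGRAMS if p.name == "division")


class TestGenerateCounts:
    def test_column_sums_equal_depths(self, default_sim):
        counts = default_sim["counts"]
        assert list(counts.depths) == list(default_sim["config"].library_depths)

    def test_single_contig_gets_every_read(self):
        cfg = SimulationConfig(n_contigs=1, library_depths=(100, 200, 300, 400, 500), seed=0)
        counts, _, _, _ = generate_counts(cfg, [DIVISION])
        assert list(counts.df.iloc[0]) == [100, 200, 300, 400, 500]

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(n_contigs=200, library_depths=(5000,) * 5, seed=42)
        a = generate_counts(cfg)
        b = generate_counts(cfg)
        assert a[0].df.equals(b[0].df)
        assert a[1].equals(b[1])
        assert a[2].equals(b[2])
        assert a[3].table.equals(b[3].table)

    def test_different_seeds_differ(self):
        base = SimulationConfig(n_contigs=200, library_depths=(5000,) * 5, seed=1)
        other = SimulationConfig(n_contigs=200, library_depths=(5000,) * 5, seed=2)
        assert not generate_counts(base)[0].df.equals(generate_counts(other)[0].df)

    def test_division_portion_matches_analytic_expectation(self, default_sim):
        """Observed 0+4 portion of division-program contigs tracks the
        program's analytic proportion at the study's desk scale."""
        counts, truth = default_sim["counts"], default_sim["truth"]
        kept, _ = filter_min_reads(counts, 30)
        scheme = AgeGroupScheme.from_ages([(0, 4), (8,), (12, 16)], counts.libraries)
        prof = group_proportions(tpt(counts), scheme, filtered_ids=kept.contig_ids)
        division_ids = truth.table.loc[truth.table["program"] == "division", "contig_id"]
        ids = [c for c in division_ids if c in prof.index]
        assert len(ids) > 10
        analytic = DIVISION.group_proportion((0, 4))
        assert prof.loc[ids, "0+4"].mean() == pytest.approx(analytic, abs=0.02)

    def test_uniform_program_concentrates_on_null(self):
        flat = StageProgram("flat", (1, 1, 1, 1, 1), (1, 0, 0, 0), 0.0)
        cfg = SimulationConfig(
            n_contigs=500, library_depths=(100_000,) * 5, program_mix=(1.0,), seed=9
        )
        counts, _, _, truth = generate_counts(cfg, [flat])
        kept, _ = filter_min_reads(counts, 30)
        scheme = AgeGroupScheme.from_ages([(a,) for a in AGES], counts.libraries)
        prof = group_proportions(tpt(counts), scheme, filtered_ids=kept.contig_ids)
        assert np.allclose(prof.mean(axis=0), 0.2, atol=0.01)

    def test_truth_proportions_sum_to_one(self, default_sim):
        props = default_sim["truth"].table[[f"p{a}" for a in AGES]]
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_zero_weight_library_is_an_error(self):
        dead = StageProgram("dead8", (1, 1, 0, 1, 1), (1, 0, 0, 0), 0.0)
        cfg = SimulationConfig(n_contigs=10, library_depths=(100,) * 5,
                               program_mix=(1.0,), seed=0)
        with pytest.raises(ValueError, match="8dpp"):
            generate_counts(cfg, [dead])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_contigs=0)
        with pytest.raises(ValueError):
            SimulationConfig(library_depths=(0,) * 5)
        with pytest.raises(ValueError):
            SimulationConfig(program_mix=(0.5, 0.4))
        with pytest.raises(ValueError):
            StageProgram("bad", (0, 0, 0, 0, 0), (1, 0, 0, 0), 0.0)


class TestGenerateLengths:
    def _cm_with_totals(self, totals):
        df = pd.DataFrame(
            {"0dpp": totals, "4dpp": 0, "8dpp": 0, "12dpp": 0, "16dpp": 0},
            index=[f"g{i}" for i in range(len(totals))],
        )
        return CountMatrix(df)

    def test_high_coverage_contigs_near_plateau(self):
        cm = self._cm_with_totals([1000] * 1000)
        lengths = generate_lengths(cm, seed=0)
        assert abs(lengths.mean() - 1400) / 1400 < 0.05

    def test_zero_noise_hits_curve_exactly(self):
        cm = self._cm_with_totals([2, 30, 1000])
        lengths = generate_lengths(cm, seed=0, noise_sd=0.0)
        r = np.array([2, 30, 1000], dtype=float)
        expect = 100 + 1300 * (1 - np.exp(-r / 8.0))
        assert np.allclose(lengths.to_numpy(), expect)

    def test_expected_length_monotone_in_reads(self):
        cm = self._cm_with_totals([2, 30])
        lengths = generate_lengths(cm, seed=0, noise_sd=0.0)
        assert lengths.iloc[0] < lengths.iloc[1]

    def test_lengths_positive(self, default_sim):
        assert (default_sim["lengths"] > 0).all()


class TestGenerateQpcr:
    def test_zero_noise_equals_tpt_ratios(self, default_sim):
        counts = default_sim["counts"]
        lib0 = counts.libraries[0]
        genes = [c for c in counts.totals.sort_values(ascending=False).index
                 if counts.df.loc[c, lib0] > 0][:5]
        qpcr, _ = generate_qpcr(counts, genes, noise_sd=0.0, seed=1)
        T = tpt(counts)
        for _, row in qpcr.iterrows():
            g, a = row["gene_id"], int(row["age_dpp"])
            expect = T.loc[g, f"{a}dpp"] / T.loc[g, "0dpp"]
            assert row["relative_quantity"] == pytest.approx(expect)

    def test_zero_baseline_skipped_with_warning(self):
        df = pd.DataFrame(
            {"0dpp": [0, 10], "4dpp": [5, 10], "8dpp": [5, 10],
             "12dpp": [5, 10], "16dpp": [5, 10]},
            index=["dead", "ok"],
        )
        with pytest.warns(UserWarning, match="dead"):
            qpcr, skipped = generate_qpcr(CountMatrix(df), ["dead", "ok"], 0.1, seed=0)
        assert skipped == ["dead"]
        assert set(qpcr["gene_id"]) == {"ok"}


class TestGoMap:
    def test_only_informative_arabidopsis_contigs_mapped(self, default_sim):
        go_map, genome = generate_go_map(default_sim["annotations"], default_sim["truth"], seed=0)
        ann = default_sim["annotations"].set_index("contig_id")
        for cid in list(go_map)[:200]:
            assert ann.loc[cid, "tier"] == "arabidopsis"
            assert not ann.loc[cid, "unknown_function"]
        assert all(0 < f < 1 for f in genome.values())

    def test_categories_within_genome_vocabulary(self, default_sim):
        go_map, genome = generate_go_map(default_sim["annotations"], default_sim["truth"], seed=0)
        vocab = set(genome)
        assert all(cats <= vocab for cats in go_map.values())
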