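"""Leave-one-out protocol: intervals, single-positive AUC, benchmark
bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from netprio import (
    BenchmarkConfig,
    GenePositions,
    auc_single_positive,
    build_linkage_interval,
    run_loo_benchmark,
)


@pytest.fixture
def toy_positions():
    frame = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [5, 15, 25, 35, 45],
            "end": [15, 25, 35, 45, 55],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
    )
    return GenePositions(frame)


class TestLinkageInterval:
    def test_nearest_midpoints_selected(self, toy_positions):
        # midpoints 10,20,30,40,50; target at 30, k=2 -> 20 and 40
        interval = build_linkage_interval(toy_positions, "g2", k=2)
        assert sorted(interval) == ["g1", "g2", "g3"]

    def test_target_always_included_and_size_k_plus_one(self, toy_positions):
        interval = build_linkage_interval(toy_positions, "g0", k=3)
        assert "g0" in interval and len(interval) == 4

    def test_seeds_excluded_before_selection(self, toy_positions):
        # with g1 removed, g3 (distance 10) is nearest; g0 and g4 tie at
        # 20 and the lexicographically smaller g0 wins
        interval = build_linkage_interval(
            toy_positions, "g2", k=2, seeds={"g1"}
        )
        assert sorted(interval) == ["g0", "g2", "g3"]
        wider = build_linkage_interval(
            toy_positions, "g2", k=2, seeds={"g1", "g0"}
        )
        assert sorted(wider) == ["g2", "g3", "g4"]

    def test_too_few_eligible_genes_is_an_error(self, toy_positions):
        with pytest.raises(ValueError, match="eligible"):
            build_linkage_interval(toy_positions, "g2", k=10)

    def test_unknown_target_rejected(self, toy_positions):
        with pytest.raises(KeyError):
            build_linkage_interval(toy_positions, "nope", k=2)

    def test_other_chromosomes_ignored(self):
        frame = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2", "chr1"],
                "start": [0, 100, 50, 200],
                "end": [10, 110, 60, 210],
            },
            index=pd.Index(["a", "b", "c", "d"], name="gene"),
        )
        interval = build_linkage_interval(GenePositions(frame), "a", k=2)
        assert "c" not in interval


def sweep_auc(rank, N):
    """Independent oracle: explicit threshold sweep of the one-positive ROC."""
    tpr = [0.0] + [1.0 if rank <= t else 0.0 for t in range(1, N + 1)]
    fpr = [0.0] + [(t - (1 if rank <= t else 0)) / (N - 1) for t in range(1, N + 1)]
    return float(np.trapezoid(tpr, fpr))


class TestAuc:
    def test_extremes(self):
        assert auc_single_positive(1, 100) == 1.0
        assert auc_single_positive(100, 100) == 0.0

    def test_closed_form_equals_threshold_sweep(self):
        for N in range(2, 201):
            for rank in range(1, N + 1):
                assert auc_single_positive(rank, N) == pytest.approx(
                    sweep_auc(rank, N), abs=1e-12
                )

    @pytest.mark.parametrize("rank,N", [(0, 10), (11, 10), (1, 1)])
    def test_out_of_range_rejected(self, rank, N):
        with pytest.raises(ValueError):
            auc_single_positive(rank, N)


def oracle_scorer(net, prior, candidates, target, rng):
    return {g: (1.0 if g == target else 0.0) for g in candidates}


def random_scorer(net, prior, candidates, target, rng):
    return {g: float(rng.random()) for g in candidates}


class TestBenchmark:
    def test_oracle_scorer_is_perfect(self, small_instance):
        res = run_loo_benchmark(
            small_instance.network,
            small_instance.associations,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(adjust="none", uniform="none"),
            rng=0,
            score_fn=oracle_scorer,
        )
        s = res.summary()
        assert s["overall"]["avg_rank"] == 1.0
        assert s["overall"]["auc"] == 1.0
        assert s["overall"]["top1_pct"] == 100.0

    def test_random_scorer_is_chance(self, small_instance):
        res = run_loo_benchmark(
            small_instance.network,
            small_instance.associations,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(adjust="none", uniform="none", reps=5),
            rng=1,
            score_fn=random_scorer,
        )
        s = res.summary()
        assert s["overall"]["avg_rank"] == pytest.approx(50.5, abs=8.0)
        assert s["overall"]["auc"] == pytest.approx(0.5, abs=0.08)

    def test_strata_partition_all_experiments(self, small_instance):
        res = run_loo_benchmark(
            small_instance.network,
            small_instance.associations,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(adjust="none", uniform="none"),
            rng=0,
            score_fn=random_scorer,
        )
        s = res.summary()
        assert s["low_degree"]["n"] + s["high_degree"]["n"] == s["overall"]["n"]

    def test_average_rank_is_mean_of_experiment_ranks(self, small_instance):
        res = run_loo_benchmark(
            small_instance.network,
            small_instance.associations,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(adjust="none", uniform="none"),
            rng=0,
            score_fn=random_scorer,
        )
        assert res.summary()["overall"]["avg_rank"] == pytest.approx(
            res.experiments["rank"].mean()
        )

    def test_small_diseases_skipped(self, small_instance):
        assocs = dict(small_instance.associations)
        assocs["TINY"] = set(list(next(iter(assocs.values())))[:2])
        res = run_loo_benchmark(
            small_instance.network,
            assocs,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(adjust="none", uniform="none"),
            rng=0,
            score_fn=oracle_scorer,
        )
        assert "TINY" in res.skipped
        assert "TINY" not in set(res.experiments["disease"])

    def test_real_pipeline_beats_chance(self, small_instance):
        """Raw diffusion ranks planted targets far better than random."""
        res = run_loo_benchmark(
            small_instance.network,
            small_instance.associations,
            small_instance.similarity,
            small_instance.positions,
            BenchmarkConfig(method="rwr", adjust="none", uniform="none"),
            rng=0,
        )
        assert res.summary()["overall"]["avg_rank"] < 30.0


def test_positions_bed_round_trip(tmp_path, toy_positions):
    path = tmp_path / "pos.bed"
    toy_positions.write_bed(path)
    back = GenePositions.read_bed(path)
    pd.testing.assert_frame_equal(
        back.frame.sort_index(),
        toy_positions.frame.sort_index(),
        check_dtype=False,
    )


def test_positions_validation():
    bad = pd.DataFrame(
        {"chrom": ["chr1"], "start": [10], "end": [5]},
        index=pd.Index(["g"], name="gene"),
    )
    with pytest.raises(ValueError):
        GenePositions(bad)
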