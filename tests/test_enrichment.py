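"""Enrichment-factor statistic and the benchmark harness."""

import math

import numpy as np
import pandas as pd
import pytest

from ufsrat import (
    LabeledLibrary,
    TargetSet,
    benchmark,
    benchmark_set,
    descriptor_scorer,
    enrichment_factor,
    load_library,
    save_library,
    usr_scorer,
)
from ufsrat.enrichment import permutation_pvalue, random_ranking_ef, rank_candidates


class TestEnrichmentFactor:
    def test_constructed_example(self):
        # 1000 candidates, 10 actives, 5 of them in the top 1% (10 compounds)
        actives = [f"a{i}" for i in range(10)]
        ranking = actives[:5] + [f"d{i}" for i in range(990)] + actives[5:]
        assert enrichment_factor(ranking, actives, 0.01) == pytest.approx(50.0)

    def test_uniform_interleaving_is_random_like(self):
        # one active every 100 compounds
        ranking = []
        actives = []
        for block in range(10):
            ranking += [f"d{block}_{i}" for i in range(99)]
            ranking.insert(block * 100 + 50, f"a{block}")
            actives.append(f"a{block}")
        ef = enrichment_factor(ranking, actives, 0.1)
        assert ef == pytest.approx(1.0, abs=0.5)

    def test_all_actives_last_is_zero(self):
        ranking = [f"d{i}" for i in range(990)] + [f"a{i}" for i in range(10)]
        assert enrichment_factor(ranking, [f"a{i}" for i in range(10)], 0.01) == 0.0

    def test_perfect_ranking_hits_ceiling(self):
        actives = [f"a{i}" for i in range(10)]
        ranking = actives + [f"d{i}" for i in range(990)]
        for f in (0.01, 0.02, 0.05):
            expected = min(1.0 / f, len(ranking) / len(actives))
            assert enrichment_factor(ranking, actives, f) == pytest.approx(expected)

    def test_ceiling_selection_never_empty(self):
        ranking = ["a", "b", "c"]
        assert enrichment_factor(ranking, ["a"], 0.001) == pytest.approx(1000.0)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            enrichment_factor(["a", "b"], ["a"], fraction)

    def test_empty_actives(self):
        with pytest.raises(ValueError, match="actives"):
            enrichment_factor(["a", "b"], [], 0.5)

    def test_actives_must_be_ranked(self):
        with pytest.raises(ValueError, match="appear"):
            enrichment_factor(["a", "b"], ["z"], 0.5)

    def test_scale_invariance_through_ranking(self):
        scores = {"a": 0.9, "b": 0.5, "c": 0.7}
        scaled = {k: 100 * v for k, v in scores.items()}
        assert rank_candidates(scores) == rank_candidates(scaled)

    def test_random_ranking_averages_to_one(self):
        efs = random_ranking_ef(1000, 10, 0.01, n_shuffles=1000,
                                rng=np.random.default_rng(123))
        se = efs.std(ddof=1) / math.sqrt(len(efs))
        assert abs(efs.mean() - 1.0) < 3 * se + 1e-9


def scripted_scorer(table):
    """A method whose ranking is fully dictated by a score table."""

    def _score(query, candidates):
        return {cid: table[cid] for cid, _ in candidates}

    return _score


def tiny_library():
    lib = benchmark_set(n_targets=2, n_actives=3, n_decoys=17, sigma=0.05, seed=42)
    return lib


class TestBenchmark:
    def test_perfect_method_hits_ef_ceiling(self):
        lib = tiny_library()
        tables = {}
        for t in lib.targets:
            tables.update({cid: (2.0 if cid in t.active_ids else 1.0) for cid in t.candidate_ids})
        report = benchmark([("perfect", scripted_scorer(tables))], lib, fractions=(0.05, 0.5))
        n = 20
        for f in (0.05, 0.5):
            # all actives lead the ranking, so EF saturates the statistic
            expected = (min(math.ceil(f * n), 3) / 3) / f
            got = report.means[report.means["fraction"] == f]["mean_ef"].iloc[0]
            assert got == pytest.approx(expected)
            assert got <= 1.0 / f + 1e-9

    def test_identical_methods_have_zero_wins(self):
        lib = tiny_library()
        tables = {}
        for t in lib.targets:
            tables.update({cid: hash(cid) % 97 for cid in t.candidate_ids})
        report = benchmark(
            [("one", scripted_scorer(tables)), ("two", scripted_scorer(tables))],
            lib,
            fractions=(0.1,),
        )
        assert (report.win_counts["wins_a"] == 0).all()
        assert (report.win_counts["wins_b"] == 0).all()

    def test_failing_method_excludes_target_from_means(self):
        lib = tiny_library()
        tables = {}
        for t in lib.targets:
            tables.update({cid: 1.0 for cid in t.candidate_ids})
        bad_target = lib.targets[0].name

        def flaky(query, candidates):
            if query.id.startswith(bad_target):
                raise RuntimeError("scoring failure")
            return {cid: 1.0 for cid, _ in candidates}

        report = benchmark(
            [("ok", scripted_scorer(tables)), ("flaky", flaky)], lib, fractions=(0.1,)
        )
        assert report.failed_targets == [bad_target]
        assert set(report.per_target["target"]) == {lib.targets[1].name}

    def test_means_equal_mean_of_per_target_values(self):
        lib = tiny_library()
        report = benchmark(
            [("usr", usr_scorer()), ("ufsrat", descriptor_scorer())],
            lib,
            fractions=(0.05, 0.1),
        )
        recomputed = (
            report.per_target.groupby(["method", "fraction"])["ef"].mean().reset_index()
        )
        merged = recomputed.merge(report.means, on=["method", "fraction"])
        assert merged["ef"].values == pytest.approx(merged["mean_ef"].values)

    def test_typed_descriptors_enrich_jittered_actives(self):
        lib = benchmark_set(n_targets=4, n_actives=5, n_decoys=95, sigma=0.05, seed=7)
        report = benchmark([("ufsrat", descriptor_scorer())], lib, fractions=(0.05,))
        assert report.means["mean_ef"].iloc[0] > 5.0

    def test_permutation_test_flags_real_signal(self):
        actives = [f"a{i}" for i in range(5)]
        ranking = actives + [f"d{i}" for i in range(95)]
        p = permutation_pvalue(ranking, actives, 0.05, n_permutations=199,
                               rng=np.random.default_rng(5))
        assert p < 0.05
        shuffled = list(np.random.default_rng(6).permutation(ranking))
        p_null = permutation_pvalue(shuffled, actives, 0.05, n_permutations=199,
                                    rng=np.random.default_rng(7))
        assert p_null > 0.05

    def test_report_serialization(self, tmp_path):
        lib = tiny_library()
        report = benchmark([("usr", usr_scorer())], lib, fractions=(0.1,))
        paths = report.to_tsv(tmp_path / "report")
        assert all(p.exists() for p in paths)
        assert "Mean enrichment" in report.pretty()


class TestLibraryLayout:
    def test_save_load_round_trip(self, tmp_path):
        lib = tiny_library()
        save_library(lib, tmp_path / "bench")
        loaded = load_library(tmp_path / "bench")
        assert len(loaded.targets) == len(lib.targets)
        for orig, back in zip(lib.targets, loaded.targets):
            assert back.name == orig.name
            assert back.active_ids == orig.active_ids
            assert back.decoy_ids == orig.decoy_ids
            assert back.query.id == orig.query.id
            assert set(back.molecules) == set(orig.molecules)

    def test_target_validation(self):
        lib = tiny_library()
        t = lib.targets[0]
        with pytest.raises(ValueError, match="overlap"):
            TargetSet(
                name="bad",
                query=t.query,
                active_ids=t.active_ids,
                decoy_ids=t.active_ids,
                molecules=t.molecules,
            )
        with pytest.raises(ValueError, match="active"):
            TargetSet(
                name="bad",
                query=t.query,
                active_ids=frozenset(),
                decoy_ids=t.decoy_ids,
                molecules=t.molecules,
            )
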