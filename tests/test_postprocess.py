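"""Anchor filtering, accuracy estimation and SUM-rule consensus ranking."""

import itertools

import numpy as np
import pytest

from oxascreen import screening_postprocess as pp
from oxascreen.conservation_profiler import ISOFORM_CODES


def record(cid, iso, rmsd=1.0, affinity=0.0, fitness=0.5, binding=0.5, energy=0.0):
    return pp.DockingRecord(cid, iso, rmsd, affinity, fitness, binding, energy)


def records_for(cid, rmsds):
    return [record(cid, iso, rmsd=r) for iso, r in zip(ISOFORM_CODES, rmsds)]


class TestAnchorConsistencyFilter:
    def test_all_within_cutoff_passes(self):
        recs = records_for("c1", [1.41, 1.42, 1.5, 1.9, 1.2, 0.8, 1.99])
        assert pp.anchor_consistency_filter(recs) == {"c1"}

    def test_single_outlier_fails(self):
        recs = records_for("c1", [1.0] * 6 + [2.5])
        assert pp.anchor_consistency_filter(recs) == set()

    def test_boundary_inclusive(self):
        recs = records_for("c1", [2.0] * 7)
        assert pp.anchor_consistency_filter(recs) == {"c1"}

    def test_missing_isoform_fails(self):
        recs = records_for("c1", [1.0] * 6)  # only six isoforms covered
        assert pp.anchor_consistency_filter(recs) == set()

    def test_empty_isoform_set_rejected(self):
        with pytest.raises(ValueError):
            pp.anchor_consistency_filter([], isoforms=())

    def test_bundled_top_compounds_all_pass(self):
        recs = pp.load_top_compound_scores()
        passing = pp.anchor_consistency_filter(recs, isoforms=("Ec", "Sp"))
        assert len(passing) == 5


class TestDockingAccuracy:
    def test_printed_screen_counts_give_76_percent(self):
        f = 1_246_716 / 8_898_942
        p = pp.docking_accuracy(f, 7)
        assert round(100 * p) == 76

    def test_full_pass_fraction(self):
        assert pp.docking_accuracy(1.0, 5) == 1.0

    def test_inverse_construction(self):
        assert pp.docking_accuracy(0.5**7, 7) == pytest.approx(0.5)

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, f):
        with pytest.raises(ValueError):
            pp.docking_accuracy(f, 7)


class TestRankByScore:
    def test_lower_is_better_ordering(self):
        recs = [
            record("a", "Ec", affinity=3.0),
            record("b", "Ec", affinity=1.0),
            record("c", "Ec", affinity=2.0),
        ]
        ranked = pp.rank_by_score(recs, "affinity")
        assert [ranked.rank_values[c] for c in ("a", "b", "c")] == [3.0, 1.0, 2.0]
        assert ranked.ids == ("b", "c", "a")

    def test_all_ties_get_average_rank(self):
        recs = [record(c, "Ec", affinity=1.0) for c in "abcd"]
        ranked = pp.rank_by_score(recs, "affinity")
        assert all(v == 2.5 for v in ranked.rank_values.values())

    def test_double_ranking_idempotent(self):
        rng = np.random.default_rng(5)
        recs = [
            record(f"c{i}", "Ec", affinity=float(v))
            for i, v in enumerate(rng.normal(size=50))
        ]
        once = pp.rank_by_score(recs, "affinity")
        rerank = [
            record(cid, "Ec", affinity=once.rank_values[cid]) for cid in once.ids
        ]
        twice = pp.rank_by_score(rerank, "affinity")
        assert twice.ids == once.ids
        assert twice.rank_values == once.rank_values

    def test_unknown_score_rejected(self):
        with pytest.raises(KeyError):
            pp.rank_by_score([record("a", "Ec")], "charisma")

    def test_duplicate_compound_rejected(self):
        with pytest.raises(ValueError):
            pp.rank_by_score([record("a", "Ec"), record("a", "Ec")], "affinity")


class TestFuseScoresSum:
    def test_single_list_identity(self):
        recs = [record(c, "Ec", affinity=v) for c, v in zip("abc", (2.0, 1.0, 3.0))]
        single = pp.rank_by_score(recs, "affinity")
        fused = pp.fuse_scores_sum([single])
        assert fused.ids == single.ids

    def test_opposite_lists_tie_broken_by_id(self):
        fwd = [record(c, "Ec", affinity=v) for c, v in zip("abc", (1.0, 2.0, 3.0))]
        rev = [record(c, "Ec", affinity=v) for c, v in zip("abc", (3.0, 2.0, 1.0))]
        fused = pp.fuse_scores_sum(
            [pp.rank_by_score(fwd, "affinity"), pp.rank_by_score(rev, "affinity")]
        )
        assert set(fused.sums.values()) == {4.0}
        assert fused.ids == ("a", "b", "c")

    def test_mismatched_compound_sets_rejected(self):
        a = pp.rank_by_score([record("a", "Ec")], "affinity")
        b = pp.rank_by_score([record("b", "Ec")], "affinity")
        with pytest.raises(ValueError):
            pp.fuse_scores_sum([a, b])

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        recs = [
            record(f"c{i:02d}", "Ec", affinity=float(v), fitness=float(u), energy=float(w))
            for i, (v, u, w) in enumerate(
                zip(values, rng.random(40), rng.normal(size=40))
            )
        ]
        transformed = [
            pp.DockingRecord(
                r.compound_id, r.isoform, r.anchor_rmsd,
                float(np.exp(r.affinity)), r.fitness**3, r.binding,
                float(np.exp(r.energy)),
            )
            for r in recs
        ]
        f1 = pp.fuse_isoform(recs)
        f2 = pp.fuse_isoform(transformed)
        assert f1.ids == f2.ids
        assert f1.rank_values == f2.rank_values


class TestGroupConsensus:
    def _fused(self, records_by_isoform):
        return {
            iso: pp.fuse_isoform(recs) for iso, recs in records_by_isoform.items()
        }

    def test_single_isoform_group_passthrough(self):
        recs = [record(c, "Ec", affinity=v) for c, v in zip("abc", (2.0, 1.0, 3.0))]
        fused = self._fused({"Ec": recs})
        consensus = pp.group_consensus(fused, "gram_negative")
        assert consensus.ids == fused["Ec"].ids

    def test_unanimous_top_compound(self):
        rng = np.random.default_rng(2)
        by_iso = {}
        for iso in ISOFORM_CODES:
            recs = [record("best", iso, affinity=-10.0)] + [
                record(f"c{i}", iso, affinity=float(v))
                for i, v in enumerate(rng.normal(size=20))
            ]
            by_iso[iso] = recs
        consensus = pp.group_consensus(self._fused(by_iso), "all")
        assert consensus.ids[0] == "best"

    def test_matches_bruteforce_rank_sum(self):
        rng = np.random.default_rng(3)
        ids = [f"c{i:03d}" for i in range(100)]
        by_iso = {
            iso: [record(c, iso, affinity=float(rng.normal())) for c in ids]
            for iso in ("Ec", "Hi", "Pa", "Mc")
        }
        fused = self._fused(by_iso)
        consensus = pp.group_consensus(fused, "gram_negative")
        brute = {
            c: sum(fused[iso].rank_values[c] for iso in ("Ec", "Hi", "Pa", "Mc"))
            for c in ids
        }
        assert consensus.ids == tuple(sorted(ids, key=lambda c: (brute[c], c)))

    def test_all_group_rank_sum_identity(self):
        rng = np.random.default_rng(4)
        ids = [f"c{i:03d}" for i in range(30)]
        by_iso = {
            iso: [record(c, iso, affinity=float(rng.normal())) for c in ids]
            for iso in ISOFORM_CODES
        }
        fused = self._fused(by_iso)
        neg = pp.group_consensus(fused, "gram_negative")
        pos = pp.group_consensus(fused, "gram_positive")
        both = pp.group_consensus(fused, "all")
        for c in ids:
            assert both.sums[c] == pytest.approx(neg.sums[c] + pos.sums[c])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pp.group_consensus({}, "gram_negative")
        with pytest.raises(ValueError):
            pp.group_consensus({"Ec": None}, "nonsense")


class TestRankCorrelation:
    def _ranked(self, ids, scores):
        recs = [record(c, "Ec", affinity=float(s)) for c, s in zip(ids, scores)]
        return pp.rank_by_score(recs, "affinity")

    def test_identical_lists(self):
        a = self._ranked("abcd", (1, 2, 3, 4))
        assert pp.rank_correlation(a, a) == pytest.approx(1.0)

    def test_reversed_lists(self):
        a = self._ranked("abcd", (1, 2, 3, 4))
        b = self._ranked("abcd", (4, 3, 2, 1))
        assert pp.rank_correlation(a, b) == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        ids = [f"c{i}" for i in range(30)]
        a = self._ranked(ids, rng.normal(size=30))
        b = self._ranked(ids, rng.normal(size=30))
        assert pp.rank_correlation(a, b) == pytest.approx(pp.rank_correlation(b, a))

    def test_too_small_rejected(self):
        a = self._ranked("a", (1.0,))
        with pytest.raises(ValueError):
            pp.rank_correlation(a, a)


class TestCountPosesWithin:
    def test_benchmark_table_counts(self):
        df = pp.load_crossdock_benchmark()
        assert len(df) == 14
        assert pp.count_poses_within(df.esimdock_rmsd) == 8
        assert pp.count_poses_within(df.vina_rmsd) == 4

    def test_empty(self):
        assert pp.count_poses_within([]) == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pp.count_poses_within([-0.5])


class TestRecordIO:
    def test_roundtrip(self, tmp_path):
        recs = [record("c1", "Ec", 1.2, -0.5, 0.9, 0.8, 12.0)]
        path = tmp_path / "records.tsv"
        pp.write_docking_records(path, recs)
        assert pp.read_docking_records(path) == recs

    def test_out_of_range_scores_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "compound_id\tisoform\tanchor_rmsd\taffinity\tfitness\tbinding\tenergy\n"
            "c1\tEc\t1.0\t0.0\t1.7\t0.5\t0.0\n"
        )
        with pytest.raises(ValueError):
            pp.read_docking_records(path)

    def test_ranked_list_output_format(self, tmp_path):
        recs = [record(c, "Ec", affinity=v) for c, v in zip("ab", (2.0, 1.0))]
        ranked = pp.rank_by_score(recs, "affinity")
        path = tmp_path / "ranked.tsv"
        pp.write_ranked_list(path, ranked)
        lines = path.read_text().splitlines()
        assert lines[0] == "rank\trelative_rank\tcompound_id\tfused_sum"
        assert lines[1].split("\t")[2] == "b"
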