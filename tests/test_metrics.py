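"""Repertoire summary statistics: usage, lengths, sharing, clonality, isotypes."""

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tibrep import metrics
from tibrep.exceptions import AnalysisError
from tibrep.simulate import RepertoireSimConfig, simulate_repertoire

from conftest import make_clone, make_repertoire


def counts_clonality(counts):
    """Independent oracle: 1 - H/ln S computed directly from the formula."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    h = -sum(pi * math.log(pi) for pi in p)
    return 1.0 - h / math.log(len(counts))


class TestAbundanceAndUsage:
    def test_total_abundance_sums_counts(self, simple_repertoire):
        assert metrics.total_abundance(simple_repertoire) == 10

    def test_total_abundance_matches_accumulation_oracle(self, rng):
        counts = rng.integers(1, 500, size=1000)
        rep = make_repertoire(
            [make_clone(f"TGT{'GCA' * (i % 7 + 1)}TGG", count=int(c), v=f"IGHV{i}")
             for i, c in enumerate(counts)]
        )
        total = 0
        for c in counts:  # independent accumulation
            total += int(c)
        assert metrics.total_abundance(rep) == total

    def test_empty_repertoire_errors(self):
        with pytest.raises(AnalysisError, match="no clones"):
            metrics.total_abundance(make_repertoire([]))

    def test_v_usage_fractions(self):
        rep = make_repertoire(
            [
                make_clone("TGTGCAAGATGG", v="IGHV3-23*01", count=6),
                make_clone("TGTGCCAGATGG", v="IGHV1-18*01", count=3),
                make_clone("TGTTTTAGATGG", v="IGHV3-23*02", count=3),
            ]
        )
        usage = metrics.v_usage(rep)
        assert usage.entries.to_dict() == pytest.approx(
            {"IGHV3-23": 0.75, "IGHV1-18": 0.25}
        )

    def test_single_clone_usage_is_one(self):
        usage = metrics.v_usage(make_repertoire([make_clone()]))
        assert usage.entries.to_dict() == {"IGHV3-23": 1.0}

    def test_ambiguous_clones_excluded_from_both_sides(self):
        ambiguous = make_clone("TGTGCAAGATGG", count=100)
        ambiguous = ambiguous.__class__(
            ambiguous.cdr3_nt, ambiguous.cdr3_aa,
            ("IGHV3-23*01", "IGHV1-18*01"), ambiguous.j_call, (), 100,
        )
        rep = make_repertoire([ambiguous, make_clone("TGTGCCAGATGG", count=5)])
        assert metrics.v_usage(rep).entries.to_dict() == {"IGHV3-23": 1.0}

    def test_planted_usage_recovered_within_tv_bound(self):
        cfg = RepertoireSimConfig(
            n_clones=100_000, shm_prob=0.0, csr_pair_probs={}, seed=7
        )
        rep, ledger = simulate_repertoire(cfg)
        usage = metrics.v_usage(rep).entries
        planted = ledger["planted_v_usage"]
        tv = 0.5 * sum(
            abs(usage.get(g, 0.0) - p) for g, p in planted.items()
        )
        assert tv < 0.02


class TestRearrangementMatrix:
    def test_fraction_cells(self):
        rep = make_repertoire(
            [
                make_clone("TGTGCAAGATGG", v="IGHV3-23*01", j="IGHJ4*01", count=6),
                make_clone("TGTGCCAGATGG", v="IGHV1-2*01", j="IGHJ6*01", count=2),
            ]
        )
        mat = metrics.vj_rearrangement(rep)
        assert mat.loc["IGHV3", "IGHJ4"] == pytest.approx(0.75)
        assert mat.loc["IGHV1", "IGHJ6"] == pytest.approx(0.25)
        assert mat.values.sum() == pytest.approx(1.0)

    def test_single_clone_is_unit_cell(self):
        mat = metrics.vj_rearrangement(make_repertoire([make_clone()]))
        assert mat.values.sum() == pytest.approx(1.0)
        assert mat.loc["IGHV3", "IGHJ4"] == 1.0

    def test_marginals_match_subgroup_usage(self, rng):
        vs = ["IGHV1-18*01", "IGHV3-23*01", "IGHV4-39*01"]
        js = ["IGHJ4*01", "IGHJ6*01"]
        clones = [
            make_clone(
                f"TGT{'GCA' * (i % 5 + 1)}TGG",
                v=vs[rng.integers(len(vs))],
                j=js[rng.integers(len(js))],
                count=int(rng.integers(1, 30)),
            )
            for i in range(60)
        ]
        rep = make_repertoire(clones)
        mat = metrics.vj_rearrangement(rep)
        v_sub = metrics.v_usage(rep, level="subgroup").entries
        j_gene = metrics.j_usage(rep).entries
        for sub in mat.index:
            assert mat.loc[sub].sum() == pytest.approx(v_sub[sub])
        for j in mat.columns:
            assert mat[j].sum() == pytest.approx(j_gene[j])


class TestCDR3Lengths:
    def test_weighted_histogram(self):
        rep = make_repertoire(
            [
                make_clone("TGT" + "GCA" * 11 + "TGG", count=3),  # 13 aa
                make_clone("TGT" + "GCC" * 11 + "TGG", count=3),  # 13 aa
                make_clone("TGT" + "GCA" * 13 + "TGG", count=3),  # 15 aa
            ]
        )
        hist = metrics.cdr3_length_distribution(rep, unit="aa")
        assert hist.to_dict() == pytest.approx({13: 2 / 3, 15: 1 / 3})
        assert hist.sum() == pytest.approx(1.0)

    def test_degenerate_single_length(self):
        rep = make_repertoire([make_clone(count=9)])
        assert metrics.cdr3_length_distribution(rep).to_dict() == {4: 1.0}

    def test_nt_lengths_triple_aa_for_in_frame(self, simple_repertoire):
        aa = metrics.cdr3_length_distribution(simple_repertoire, unit="aa")
        nt = metrics.cdr3_length_distribution(simple_repertoire, unit="nt")
        assert {3 * k for k in aa.index} == set(nt.index)


class TestSharingAndJaccard:
    def _reps(self, keys_a, keys_b):
        def rep(keys, sid):
            return make_repertoire(
                [
                    make_clone("TGT" + "GCA" * (i + 2) + "TGG", cdr3_aa=k, count=3)
                    for i, k in enumerate(keys)
                ],
                sample_id=sid,
            )
        return rep(keys_a, "A"), rep(keys_b, "B")

    def test_overlap_case(self):
        a, b = self._reps(["CARA", "CARB", "CARC"], ["CARB", "CARC", "CARD"])
        shared = metrics.shared_clones(a, b)
        assert shared.shared == {"CARB", "CARC"}
        assert shared.fraction_of_union == pytest.approx(0.5)
        assert metrics.jaccard_index(a, b) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        a, b = self._reps(["CARA", "CARB"], ["CARA", "CARB"])
        assert metrics.jaccard_index(a, b) == 1.0
        assert metrics.shared_clones(a, b).fraction_of_union == 1.0
        c, d = self._reps(["CARA"], ["CARB"])
        assert metrics.jaccard_index(c, d) == 0.0
        assert metrics.shared_clones(c, d).fraction_of_union == 0.0

    @given(
        keys_a=st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8),
        keys_b=st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8),
    )
    def test_jaccard_symmetric(self, keys_a, keys_b):
        a, b = self._reps([f"CAR{k}" for k in keys_a], [f"CAR{k}" for k in keys_b])
        assert metrics.jaccard_index(a, b) == pytest.approx(metrics.jaccard_index(b, a))


class TestClonality:
    def test_uniform_is_zero_single_is_one(self):
        uniform = make_repertoire(
            [make_clone("TGT" + "GCA" * (i + 1) + "TGG", count=4) for i in range(5)]
        )
        assert metrics.clonality(uniform) == pytest.approx(0.0, abs=1e-12)
        assert metrics.clonality(make_repertoire([make_clone(count=17)])) == 1.0

    def test_formula_oracle(self):
        rep = make_repertoire(
            [make_clone("TGT" + "GCA" * (i + 1) + "TGG", count=c)
             for i, c in enumerate([5, 3, 2])]
        )
        expected = 1 - (
            -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
        ) / math.log(3)
        assert metrics.clonality(rep) == pytest.approx(expected)

    @given(counts=st.lists(st.integers(1, 50), min_size=2, max_size=6), scale=st.integers(2, 9))
    def test_invariant_under_count_rescaling(self, counts, scale):
        def rep(cs):
            return make_repertoire(
                [make_clone("TGT" + "GCA" * (i + 1) + "TGG", count=c)
                 for i, c in enumerate(cs)]
            )
        assert metrics.clonality(rep(counts)) == pytest.approx(
            metrics.clonality(rep([scale * c for c in counts]))
        )

    def test_concentration_never_decreases_clonality(self):
        """Moving a count from a smaller clone onto the largest one."""
        for a, b, c in combinations_with_replacement(range(1, 11), 3):
            base = sorted([a, b, c], reverse=True)
            if base[1] < 2:
                continue
            moved = [base[0] + 1, base[1] - 1, base[2]]
            assert counts_clonality(moved) >= counts_clonality(base) - 1e-12
            rep = make_repertoire(
                [make_clone("TGT" + "GCA" * (i + 1) + "TGG", count=x)
                 for i, x in enumerate(base)]
            )
            assert metrics.clonality(rep) == pytest.approx(counts_clonality(base))


class TestIsotypeProfile:
    def test_single_subclass_counts_class_and_subclass(self):
        rep = make_repertoire([make_clone(c="IGHG2")], total_reads=1000)
        prof = metrics.isotype_profile(rep)
        assert prof.class_counts["IGHG"] == 1
        assert prof.subclass_counts["IGHG2"] == 1

    def test_multi_subclass_counts_class_only(self):
        clone = make_clone()
        clone = clone.__class__(
            clone.cdr3_nt, clone.cdr3_aa, clone.v_call, clone.j_call,
            ("IGHG2", "IGHG4"), 5,
        )
        prof = metrics.isotype_profile(make_repertoire([clone], total_reads=1000))
        assert prof.class_counts["IGHG"] == 1
        assert prof.subclass_counts.sum() == 0

    def test_cpm_value_and_linearity(self):
        clones = [
            make_clone("TGT" + "GCA" * (i + 1) + "TGG", c="IGHG1", count=3)
            for i in range(200)
        ]
        prof = metrics.isotype_profile(
            make_repertoire(clones, total_reads=50_000_000)
        )
        assert prof.cpm["IGHG1"] == pytest.approx(4.0)
        half_depth = metrics.isotype_profile(
            make_repertoire(clones, total_reads=25_000_000)
        )
        assert half_depth.cpm["IGHG1"] == pytest.approx(8.0)

    def test_missing_depth_errors_for_cpm_only(self):
        prof = metrics.isotype_profile(make_repertoire([make_clone(c="IGHG1")]))
        assert prof.class_counts["IGHG"] == 1
        assert prof.cpm is None
        with pytest.raises(AnalysisError, match="CPM"):
            prof.require_cpm()
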