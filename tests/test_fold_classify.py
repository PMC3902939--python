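import itertools
import random

import pytest

from selexevo.classify import (
    DASE_PROGENITOR_SCAFFOLD,
    DASE_SCAFFOLD,
    LOWER_BULGE_SLICE,
    UPPER_BULGE_SLICE,
    classify_dase,
    classify_pool,
    dase_descriptor,
    delta_delta_g,
)
from selexevo.fold import ConstraintInfeasibleError, NussinovEngine
from selexevo.pool_io_qc import PoolTable

from _oracles import brute_force_constrained, brute_force_mfe


def _mut(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1:]


class TestNussinovEngine:
    def test_exhaustive_agreement_short(self):
        """DP minimum equals exhaustive enumeration over every nested
        structure, for all RNA strings up to length 5."""
        eng = NussinovEngine()
        for n in range(0, 6):
            for tup in itertools.product("ACGU", repeat=n):
                seq = "".join(tup)
                assert eng.fold(seq).energy == brute_force_mfe(seq)

    def test_exhaustive_agreement_sampled_to_14(self):
        eng = NussinovEngine()
        rng = random.Random(23)
        for _ in range(120):
            n = rng.randint(6, 14)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            res = eng.fold(seq)
            assert res.energy == brute_force_mfe(seq), seq
            # returned structure is consistent with its energy
            assert sum(
                eng.pair_energy(seq[i], seq[j]) for i, j in res.pairs
            ) == res.energy

    def test_constrained_at_least_unconstrained(self):
        eng = NussinovEngine()
        rng = random.Random(31)
        checked = 0
        while checked < 40:
            n = rng.randint(10, 14)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            mfe = eng.fold(seq)
            if not mfe.pairs:
                continue
            forced = [sorted(mfe.pairs)[0]]
            res = eng.fold_constrained(seq, forced)
            assert res.energy >= mfe.energy
            oracle = brute_force_constrained(seq, forced)
            assert res.energy == oracle
            checked += 1

    def test_infeasible_constraints_raise(self):
        eng = NussinovEngine()
        with pytest.raises(ConstraintInfeasibleError):
            eng.fold_constrained("GGGGAAAACCCC", [(0, 1)])  # hairpin too tight
        with pytest.raises(ConstraintInfeasibleError):
            eng.fold_constrained("GGGGAAAACCCC", [(0, 4)])  # G-A not pairable
        with pytest.raises(ConstraintInfeasibleError):
            eng.fold_constrained("GGGGAAAACCCC", [(0, 8), (2, 11)])  # crossing


# The nine construction fixtures: category follows directly from which
# rule the construction violates.
OPT_UGCCG = _mut(DASE_SCAFFOLD, UPPER_BULGE_SLICE.stop - 1, "G")
SUBOPT_UPPER = _mut(DASE_SCAFFOLD, UPPER_BULGE_SLICE.start, "A")  # AGCCA pocket
UNSTABLE_H2 = _mut(DASE_SCAFFOLD, 10, "A")
UNSTABLE_H1 = _mut(DASE_SCAFFOLD, 36, "G")  # helix I 3' arm
BOTH_DEFECTS = _mut(DASE_PROGENITOR_SCAFFOLD, 10, "A")
H3_CLOSING_MISMATCH = _mut(DASE_SCAFFOLD, 16, "A")  # innermost pair of helix III

FIXTURES = [
    (DASE_SCAFFOLD, "typical_optimal"),
    (OPT_UGCCG, "typical_optimal"),
    (H3_CLOSING_MISMATCH, "typical_optimal"),  # closing-pair exemption
    (DASE_PROGENITOR_SCAFFOLD, "typical_suboptimal_bulge"),
    (SUBOPT_UPPER, "typical_suboptimal_bulge"),
    (UNSTABLE_H2, "typical_unstable_helices"),
    (UNSTABLE_H1, "typical_unstable_helices"),
    (BOTH_DEFECTS, "typical_suboptimal_and_unstable"),
    ("A" * 40, "not_typical"),
]


class TestClassifyDase:
    @pytest.mark.parametrize("seq,expected", FIXTURES)
    def test_construction_fixtures(self, seq, expected):
        call = classify_dase(seq)
        assert call.category == expected

    def test_optimal_call_reports_pocket(self):
        call = classify_dase(DASE_SCAFFOLD)
        assert call.upper_bulge == "UGCCA"
        assert call.lower_bulge == "AAUACU"
        assert all(v == 0 for v in call.helix_mismatch_count.values())

    def test_progenitor_reports_gauacu(self):
        call = classify_dase(DASE_PROGENITOR_SCAFFOLD)
        assert call.lower_bulge == "GAUACU"

    def test_not_typical_has_no_bulges(self):
        call = classify_dase("A" * 40)
        assert call.upper_bulge is None and call.lower_bulge is None

    def test_engine_annotation_never_changes_category(self):
        eng = NussinovEngine()
        for seq, expected in FIXTURES:
            with_engine = classify_dase(seq, engine=eng)
            assert with_engine.category == expected
            if expected != "not_typical":
                assert with_engine.energetically_favored in (True, False)

    def test_scaffold_typical_fold_is_energetically_favored(self):
        call = classify_dase(DASE_SCAFFOLD, engine=NussinovEngine())
        assert call.energetically_favored is True
        assert call.delta_delta_g == 0.0


class TestClassifyPool:
    def test_read_weighted_fractions(self):
        pool = PoolTable("p", {DASE_SCAFFOLD: 3, "A" * 40: 1})
        calls, fracs = classify_pool(pool)
        by_cat = dict(zip(fracs["category"], fracs["frac_reads"]))
        assert by_cat["typical_optimal"] == pytest.approx(0.75)
        assert by_cat["not_typical"] == pytest.approx(0.25)
        by_seq = dict(zip(fracs["category"], fracs["frac_sequences"]))
        assert by_seq["typical_optimal"] == pytest.approx(0.5)

    def test_fractions_partition_to_one(self):
        pool = PoolTable(
            "p",
            {DASE_SCAFFOLD: 5, DASE_PROGENITOR_SCAFFOLD: 3, UNSTABLE_H2: 2, "A" * 40: 1},
        )
        calls, fracs = classify_pool(pool)
        assert fracs["frac_reads"].sum() == pytest.approx(1.0)
        assert fracs["frac_sequences"].sum() == pytest.approx(1.0)
        assert len(calls) == 4

    def test_planted_category_mix_recovered_exactly(self):
        pool = PoolTable(
            "p", {DASE_SCAFFOLD: 7, DASE_PROGENITOR_SCAFFOLD: 2, "A" * 40: 1}
        )
        _, fracs = classify_pool(pool)
        by_cat = dict(zip(fracs["category"], fracs["n_reads"]))
        assert by_cat["typical_optimal"] == 7
        assert by_cat["typical_suboptimal_bulge"] == 2
        assert by_cat["not_typical"] == 1

    def test_empty_pool_empty_table(self):
        calls, fracs = classify_pool(PoolTable("p", {}))
        assert len(calls) == 0
        assert fracs["frac_reads"].sum() == 0


class TestDeltaDeltaG:
    def test_scaffold_mfe_is_typical_fold(self):
        assert delta_delta_g(DASE_SCAFFOLD, engine=NussinovEngine()) == 0.0

    def test_without_engine_not_evaluated(self):
        assert delta_delta_g(DASE_SCAFFOLD) == "not_evaluated"

    def test_toy_hairpin_matches_exhaustive_oracle(self):
        """Constrained-minus-unconstrained gap on a toy hairpin equals the
        value from exhaustive structure enumeration."""
        from selexevo.descriptor import parse_descriptor, match_descriptor

        eng = NussinovEngine()
        d = parse_descriptor("h1(2:3,0) s1(N{3:5}) h1'")
        rng = random.Random(41)
        checked = 0
        while checked < 25:
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(9, 13)))
            hits = match_descriptor(seq, d, mode="first")
            if not hits:
                continue
            forced = hits[0].helix_pairs()
            try:
                got = eng.fold_constrained(seq, forced).energy - eng.fold(seq).energy
            except ConstraintInfeasibleError:
                continue
            oracle = brute_force_constrained(seq, forced) - brute_force_mfe(seq)
            assert got == oracle
            assert got >= 0
            checked += 1

    def test_nonmatching_sequence_errors(self):
        with pytest.raises(ValueError):
            delta_delta_g("A" * 40, engine=NussinovEngine())
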