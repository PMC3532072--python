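"""MI variants: elementary values, corrections, tables, oracle equivalence."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from micontact import (
    PatchTriplets,
    apc,
    build_mask,
    cps,
    enumerate_patch_triplets,
    mi,
    mi3d,
    mi3d_table,
    mi_table,
    mic_table,
    mip3d_table,
    mip_table,
    reduce_alphabet,
    score_table,
    standardize_scores,
)
from micontact.errors import (
    DegenerateStandardizationError,
    NoSurvivingPairsError,
    ZeroMeanError,
)
from micontact.msa import AA20
from micontact.scores import apc3d

from conftest import make_msa, random_paired_msa
from oracles import (
    inter_mi_oracle,
    mi3d_oracle,
    mi3d_triples_oracle,
    mi_oracle,
    mic_oracle,
    mip3d_oracle,
    mip_oracle,
    standardize_oracle,
)

columns = st.lists(st.sampled_from("ACDEFG"), min_size=3, max_size=25)


class TestMI:
    def test_perfect_covariation_20_states(self):
        col_j = list(AA20)
        col_k = list(AA20[5:] + AA20[:5])  # a bijection of J
        assert mi(col_j, col_k) == pytest.approx(math.log(20))
        assert round(mi(col_j, col_k), 4) == 2.9957

    def test_product_distribution_is_zero(self):
        # all four combinations of {A,C} x {D,E} equally often
        assert mi("AACC", "DEDE") == 0.0

    def test_four_row_table_matches_oracle(self):
        col_j, col_k = "AAAC", "DDEE"
        expected = mi_oracle(col_j, col_k)  # 0.21576… nats
        assert mi(col_j, col_k) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2157615543, abs=1e-9)

    @given(columns, columns)
    def test_symmetry_nonneg_and_bound(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        v = mi(a, b)
        assert v == pytest.approx(mi(b, a), abs=1e-12)
        assert v >= 0.0
        from micontact import column_entropy
        assert v <= min(column_entropy(a), column_entropy(b)) + 1e-12
        assert v <= math.log(20) + 1e-12


class TestAPC:
    def test_all_equal_mi_gives_constant(self):
        raw = {(0, 2): 0.3, (0, 3): 0.3, (1, 2): 0.3, (1, 3): 0.3}
        for key in raw:
            assert apc(raw, *key) == pytest.approx(0.3)

    def test_hand_worked_2x2(self):
        raw = {("J1", "K1"): 0.4, ("J1", "K2"): 0.2,
               ("J2", "K1"): 0.2, ("J2", "K2"): 0.2}
        # row mean 0.3, column mean 0.3, overall 0.25
        assert apc(raw, "J1", "K1") == pytest.approx(0.36)

    def test_single_pair_returns_its_own_mi(self):
        assert apc({(0, 1): 0.7}, 0, 1) == pytest.approx(0.7)

    def test_apc_is_nonnegative(self):
        raw = {(0, 2): 0.1, (0, 3): 0.5, (1, 2): 0.2, (1, 3): 0.05}
        for key in raw:
            assert apc(raw, *key) >= 0.0


class TestCPS:
    def test_all_equal_mi_gives_square(self):
        vals = {frozenset(p): 0.2 for p in
                [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}
        assert cps(vals, 0, 1, [0, 1, 2, 3]) == pytest.approx(0.04)

    def test_zero_profile_gives_zero(self):
        vals = {frozenset(p): 0.0 for p in [(0, 2), (0, 3), (1, 2), (1, 3)]}
        vals[frozenset((0, 1))] = 0.5
        vals[frozenset((2, 3))] = 0.4
        assert cps(vals, 0, 1, [0, 1, 2, 3]) == 0.0

    def test_four_column_hand_sum(self):
        vals = {frozenset((0, 2)): 0.1, frozenset((1, 2)): 0.2,
                frozenset((0, 3)): 0.3, frozenset((1, 3)): 0.4,
                frozenset((0, 1)): 0.9, frozenset((2, 3)): 0.9}
        expected = (0.1 * 0.2 + 0.3 * 0.4) / 2  # L in {2, 3}
        assert cps(vals, 0, 1, [0, 1, 2, 3]) == pytest.approx(expected)

    def test_no_admissible_third_column_raises(self):
        with pytest.raises(NoSurvivingPairsError):
            cps({frozenset((0, 1)): 0.1}, 0, 1, [0, 1])


class TestMI3D:
    def test_independent_uniform_columns(self):
        # all 8 combinations of three binary columns equally often
        j = "AAAACCCC"
        k = "AACCAACC"
        l = "ACACACAC"
        assert mi3d(j, k, l) == 0.0

    def test_perfectly_covarying_triple(self):
        j = list(AA20[:5]) * 2
        assert mi3d(j, j, j) == pytest.approx(2 * math.log(5))

    def test_six_row_partial_coupling_matches_oracle(self):
        j, k, l = "AACCAD", "DDEEDD", "FFGGFF"
        assert mi3d(j, k, l) == pytest.approx(mi3d_oracle(j, k, l), abs=1e-12)

    @given(columns, columns, columns)
    def test_nonnegative_and_oracle(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        v = mi3d(a, b, c)
        assert v >= 0.0
        assert v == pytest.approx(mi3d_oracle(a, b, c), abs=1e-12)


class TestStandardizeScores:
    def test_sample_sd_convention(self):
        std, mean, sd = standardize_scores({"a": 1.0, "b": 2.0, "c": 3.0})
        assert std == pytest.approx({"a": -1.0, "b": 0.0, "c": 1.0})
        assert (mean, sd) == (2.0, 1.0)

    def test_all_equal_raises(self):
        with pytest.raises(DegenerateStandardizationError):
            standardize_scores({"a": 1.0, "b": 1.0})

    def test_affine_invariance(self):
        raw = {"a": 0.1, "b": 0.5, "c": 0.9, "d": 0.3}
        std1, *_ = standardize_scores(raw)
        std2, *_ = standardize_scores({k: 7 * v - 2 for k, v in raw.items()})
        for k in raw:
            assert std1[k] == pytest.approx(std2[k], abs=1e-12)


class TestTables:
    def test_fully_conserved_domain_raises(self):
        msa = make_msa(["AADE", "AADD", "AAEE", "AAED"], [0, 1], [2, 3])
        with pytest.raises(NoSurvivingPairsError):
            mi_table(msa, build_mask(msa))

    def test_standardized_mean_zero_sd_one(self, standard_case):
        table = mi_table(standard_case["msa"], standard_case["mask"])
        vals = np.array(list(table.standardized.values()))
        assert abs(vals.mean()) < 1e-9
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_all_pairs_inter_domain_and_eligible(self, standard_case):
        msa, mask = standard_case["msa"], standard_case["mask"]
        table = mi_table(msa, mask)
        d1, d2 = set(msa.domain1_cols), set(msa.domain2_cols)
        for j, k in table.entries:
            assert j in d1 and k in d2
            assert mask.eligible[j] and mask.eligible[k]

    def test_mip_below_mi_when_apc_positive(self, standard_case):
        msa, mask = standard_case["msa"], standard_case["mask"]
        t_mi = mi_table(msa, mask)
        t_mip = mip_table(msa, mask)
        assert set(t_mi.entries) == set(t_mip.entries)
        for key in t_mip.entries:  # APC >= 0 for nonneg MI values
            assert t_mip.entries[key] <= t_mi.entries[key] + 1e-12

    def test_mic_raw_values_may_be_negative(self, standard_case):
        t = mic_table(standard_case["msa"], standard_case["mask"])
        assert min(t.entries.values()) < 0.0

    def test_zero_mi_pairs_are_excluded_not_scored(self):
        # column 2 is a balanced product layout against both domain-1
        # columns (exact MI 0); column 3 covaries with both
        rows = ["ADDD", "ADED", "AEDE", "AEEE",
                "CDDD", "CDED", "CEDE", "CEED"]
        msa = make_msa(rows, [0, 1], [2, 3])
        table = mi_table(msa, build_mask(msa))
        assert table.excluded.get((0, 2)) == "zero_mi"
        assert table.excluded.get((1, 2)) == "zero_mi"
        assert set(table.entries) == {(0, 3), (1, 3)}

    def test_planted_pair_tops_all_pairwise_variants(self, standard_case):
        msa, mask = standard_case["msa"], standard_case["mask"]
        for builder in (mi_table, mip_table, mic_table):
            table = builder(msa, mask)
            top = max(table.standardized, key=table.standardized.get)
            assert top == (2, 25)  # strongest planted coupling

    def test_cps_scope_switch_changes_values(self, standard_case):
        msa, mask = standard_case["msa"], standard_case["mask"]
        t_all = mic_table(msa, mask, cps_l_scope="all")
        t_opp = mic_table(msa, mask, cps_l_scope="opposite_only")
        diffs = [abs(t_all.entries[k] - t_opp.entries[k]) for k in t_all.entries]
        assert max(diffs) > 0.0


class TestPatchTriplets:
    def test_no_close_pair_gives_empty(self):
        msa = make_msa(["ACDE", "AMDD", "CCDE"], [0, 1], [2, 3])
        t = enumerate_patch_triplets(msa, build_mask(msa), {(2, 3): 9.0})
        assert t.triples == ()

    def test_counting_one_close_pair(self, standard_case):
        msa, mask = standard_case["msa"], standard_case["mask"]
        t = enumerate_patch_triplets(msa, mask, {(30, 31): 4.0})
        m = len(mask.eligible_cols(msa.domain1_cols))
        assert len(t.triples) == m
        assert all((k, l) == (30, 31) for _, k, l in t.triples)

    def test_exact_cutoff_excluded(self):
        msa = make_msa(["ACDE", "AMDD", "CCDE"], [0, 1], [2, 3])
        t = enumerate_patch_triplets(msa, build_mask(msa), {(2, 3): 4.5})
        assert t.triples == ()

    def test_patch_in_domain1_supports_reverse_direction(self):
        msa = make_msa(["ACDE", "AMDD", "CCDE", "CMEE"], [0, 1], [2, 3])
        t = enumerate_patch_triplets(msa, build_mask(msa), {(0, 1): 4.0})
        assert all(msa.domain_of(j) == 2 for j, _, _ in t.triples)


class TestTripleTables:
    def test_single_surviving_triple_identity(self):
        # APC3D with a single triple: all means coincide at c, correction
        # c*c*c/c = c^2, so MIp3D = c - c^2
        raw = {(0, 2, 3): 0.4}
        assert apc3d(raw, 0, 2, 3) == pytest.approx(0.16)

    def test_all_equal_triples(self):
        raw = {(0, 2, 3): 0.4, (1, 2, 3): 0.4}
        for key in raw:
            assert apc3d(raw, *key) == pytest.approx(0.16)

    def test_planted_triple_recovery(self):
        from micontact import SyntheticSpec, generate_annotations, generate_msa
        from micontact.structure import column_distances
        spec = SyntheticSpec(
            n_sequences=500, len1=20, len2=20, seed=11, alphabet_size=6,
            coupled_triples=((7, 30, 31, 0.5),),
            contact_cols=(7, 30),
            patch_pairs=((30, 31), (22, 23), (25, 26), (33, 34)),
        )
        msa = generate_msa(spec)
        _, dmap, _ = generate_annotations(spec, msa)
        mask = build_mask(msa)
        triples = enumerate_patch_triplets(msa, mask, column_distances(dmap, msa))
        for builder in (mi3d_table, mip3d_table):
            table = builder(msa, mask, triples)
            top = max(table.standardized, key=table.standardized.get)
            assert top == (7, 30, 31)


def small_msas():
    """Deterministic battery of small random alignments for oracle checks."""
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(12):
        n_seq = int(rng.integers(4, 7))      # <= 6 sequences
        len1 = int(rng.integers(2, 3))
        len2 = int(rng.integers(2, 4))       # <= 5 columns total
        out.append(random_paired_msa(rng, n_seq, len1, len2, alphabet="ACD"))
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("idx", range(12))
    def test_pairwise_variants_match_bruteforce(self, idx):
        msa = small_msas()[idx]
        mask = build_mask(msa)
        oracle_raw = inter_mi_oracle(msa)
        if len(oracle_raw) < 2:
            pytest.skip("degenerate draw: fewer than two surviving pairs")
        for builder, oracle in ((mi_table, lambda m: inter_mi_oracle(m)),
                                (mip_table, mip_oracle),
                                (mic_table, mic_oracle)):
            try:
                table = builder(msa, mask)
            except (NoSurvivingPairsError, ZeroMeanError,
                    DegenerateStandardizationError):
                continue  # degenerate draw for this variant
            expected = oracle(msa)
            assert set(table.entries) == set(expected)
            for key, v in expected.items():
                assert table.entries[key] == pytest.approx(v, abs=1e-12)
            try:
                expected_std = standardize_oracle(expected)
            except (ZeroDivisionError, statistics.StatisticsError):
                continue
            for key, v in expected_std.items():
                assert table.standardized[key] == pytest.approx(v, abs=1e-10)

    @pytest.mark.parametrize("idx", range(6))
    def test_triple_variants_match_bruteforce(self, idx):
        msa = small_msas()[idx]
        mask = build_mask(msa)
        d2 = mask.eligible_cols(msa.domain2_cols)
        d1 = mask.eligible_cols(msa.domain1_cols)
        if len(d2) < 2 or not d1:
            pytest.skip("no patch pair available")
        triples = PatchTriplets(tuple((j, d2[0], d2[1]) for j in d1))
        expected = mi3d_triples_oracle(msa, triples.triples)
        if len(expected) < 2:
            pytest.skip("fewer than two surviving triples")
        try:
            t3 = mi3d_table(msa, mask, triples)
            tp = mip3d_table(msa, mask, triples)
        except (ZeroMeanError, DegenerateStandardizationError):
            pytest.skip("degenerate draw for triple standardisation")
        assert set(t3.entries) == set(expected)
        for key, v in expected.items():
            assert t3.entries[key] == pytest.approx(v, abs=1e-12)
        for key, v in mip3d_oracle(msa, triples.triples).items():
            assert tp.entries[key] == pytest.approx(v, abs=1e-12)

    def test_reduced_alphabet_equals_merged_symbols(self, standard_case):
        # scoring the reduced alignment is definitionally full-alphabet
        # scoring after symbol merging
        msa = reduce_alphabet(standard_case["msa"])
        mask = build_mask(msa)
        table = mi_table(msa, mask)
        for (j, k), v in list(table.entries.items())[:25]:
            assert v == pytest.approx(mi_oracle(msa.column(j), msa.column(k)),
                                      abs=1e-12)
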