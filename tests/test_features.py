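"""Feature extractors: hand-computed examples, oracle agreement, invariants."""

from __future__ import annotations

import numpy as np
import pytest

import oracles
from conftest import random_pssm
from dbpforest import (
    DegenerateInputError,
    ProteinSequence,
    PSSMMatrix,
    ValidationError,
    aac_pssm,
    aadp_pssm,
    dpc_pssm,
    extract_features,
    fuse,
    pssm_composition,
    reduce_pssm,
    rpssm,
)
from dbpforest.features import DEFAULT_REDUCTION, ReductionScheme


def make_pssm(residues: str, scores) -> PSSMMatrix:
    return PSSMMatrix(ProteinSequence("h", residues), np.asarray(scores, dtype=int))


EXTRACTORS = {
    "aac": (aac_pssm, 20),
    "dpc": (dpc_pssm, 400),
    "aadp": (aadp_pssm, 420),
    "composition": (pssm_composition, 400),
    "rpssm": (rpssm, 110),
}


@pytest.mark.parametrize("name", EXTRACTORS)
def test_block_dimensions(pssm, name):
    func, dim = EXTRACTORS[name]
    assert len(func(pssm)) == dim


def test_fused_dimension_is_930(pssm):
    assert len(extract_features(pssm)) == 930


def test_reduced_matrix_has_10_columns(pssm):
    assert reduce_pssm(pssm).shape == (pssm.length, 10)


class TestAAC:
    def test_constant_rows_give_back_the_row(self):
        v = np.arange(20) - 7
        m = make_pssm("ACD", np.tile(v, (3, 1)))
        assert np.allclose(aac_pssm(m).values, v)

    def test_zero_matrix(self):
        m = make_pssm("AC", np.zeros((2, 20)))
        assert np.all(aac_pssm(m).values == 0)

    def test_column_a_mean(self):
        scores = np.zeros((2, 20))
        scores[:, 0] = (2, 4)
        m = make_pssm("AC", scores)
        out = aac_pssm(m).values
        assert out[0] == 3 and np.all(out[1:] == 0)

    def test_row_doubling_invariance(self, pssm):
        doubled = PSSMMatrix(
            ProteinSequence("d", pssm.sequence.residues * 2),
            np.vstack([pssm.scores, pssm.scores]),
        )
        assert np.allclose(aac_pssm(doubled).values, aac_pssm(pssm).values)


class TestDPC:
    def test_two_row_constant_case(self):
        m = make_pssm("AC", np.vstack([np.ones(20), 2 * np.ones(20)]))
        assert np.allclose(dpc_pssm(m).values, 2.0)

    def test_zero_matrix(self):
        m = make_pssm("AC", np.zeros((2, 20)))
        assert np.all(dpc_pssm(m).values == 0)

    def test_matches_double_loop_oracle(self):
        m = random_pssm(3, length=30)
        expected = oracles.dpc_oracle(m.scores.tolist())
        assert np.allclose(dpc_pssm(m).values, expected, atol=1e-10)


class TestAADP:
    def test_first_20_equal_aac(self, pssm):
        assert np.allclose(aadp_pssm(pssm).values[:20], aac_pssm(pssm).values)

    def test_zero_matrix_gives_420_zeros(self):
        m = make_pssm("AC", np.zeros((2, 20)))
        out = aadp_pssm(m)
        assert len(out) == 420 and np.all(out.values == 0)

    def test_name_prefixes(self, pssm):
        names = aadp_pssm(pssm).names
        assert names[0].startswith("AAC:") and names[20].startswith("DPC:")


class TestComposition:
    def test_zero_matrix_maps_to_zeros(self):
        m = make_pssm("AC", np.zeros((2, 20)))
        assert np.all(pssm_composition(m).values == 0)

    def test_range_and_endpoints(self, pssm):
        out = pssm_composition(pssm).values
        assert out.min() == -1.0 and out.max() == 1.0

    def test_grouping_matches_oracle_before_scaling(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(-8, 13, size=(3, 20))
        m = make_pssm("AAC", scores)
        expected = oracles.composition_unscaled_oracle(scores.tolist(), "AAC")
        # rows: A = (row1+row2)/3, C = row3/3, others zero
        assert np.allclose(expected[0], (scores[0] + scores[1]) / 3)
        assert np.allclose(expected[4], scores[2] / 3)
        assert np.allclose(
            pssm_composition(m).values,
            oracles.composition_oracle(scores.tolist(), "AAC"),
            atol=1e-12,
        )

    def test_x_residue_counts_in_length_but_no_group(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(-8, 13, size=(3, 20))
        m = make_pssm("AXC", scores)
        expected = oracles.composition_oracle(scores.tolist(), "AXC")
        assert np.allclose(pssm_composition(m).values, expected, atol=1e-12)


class TestReduceAndRPSSM:
    def test_singleton_group_passthrough(self, pssm):
        reduced = reduce_pssm(pssm)
        g_col = DEFAULT_REDUCTION.groups.index("G")
        from dbpforest.pssm_io import AA_INDEX

        assert np.allclose(reduced[:, g_col], pssm.scores[:, AA_INDEX["G"]])

    def test_pair_group_is_mean(self):
        scores = np.zeros((2, 20))
        from dbpforest.pssm_io import AA_INDEX

        scores[:, AA_INDEX["M"]] = 2
        scores[:, AA_INDEX["L"]] = 4
        m = make_pssm("AC", scores)
        ml_col = DEFAULT_REDUCTION.groups.index("ML")
        assert np.allclose(reduce_pssm(m)[:, ml_col], 3)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            ReductionScheme(groups=("FYW", "ML", "IV", "ATS", "NH", "QED", "RK", "C", "G", "PA"))

    def test_constant_matrix_gives_all_zero_rpssm(self):
        m = make_pssm("ACD", np.full((3, 20), 5))
        assert np.all(rpssm(m).values == 0)

    def test_variance_of_1_2_3_is_two_thirds(self):
        # column A is a singleton in a custom scheme so the reduced column is 1,2,3
        scheme = ReductionScheme(
            groups=("A", "R", "N", "D", "C", "Q", "E", "G", "H", "ILKMFPSTVWY")
        )
        scores = np.zeros((3, 20))
        scores[:, 0] = (1, 2, 3)
        m = make_pssm("ACD", scores)
        out = rpssm(m, scheme)
        assert out.values[0] == pytest.approx(2.0 / 3.0)

    def test_rpssm_nonnegative(self, pssm):
        assert np.all(rpssm(pssm).values >= 0)

    def test_sum_form_flag_differs(self, pssm):
        diff = rpssm(pssm, difference=True).values
        summ = rpssm(pssm, difference=False).values
        assert np.allclose(diff[:10], summ[:10])  # variances unaffected
        assert not np.allclose(diff[10:], summ[10:])


class TestFuse:
    def test_dimension_and_prefix_order(self, pssm):
        fused = extract_features(pssm)
        assert len(fused) == 930
        assert np.allclose(fused.values[:420], aadp_pssm(pssm).values)
        assert np.allclose(fused.values[420:820], pssm_composition(pssm).values)
        assert np.allclose(fused.values[820:], rpssm(pssm).values)

    def test_argument_order_irrelevant(self, pssm):
        parts = [aadp_pssm(pssm), pssm_composition(pssm), rpssm(pssm)]
        a = fuse(parts)
        b = fuse(parts[::-1])
        assert a.names == b.names and np.array_equal(a.values, b.values)

    def test_mismatched_sample_ids_rejected(self, pssm):
        other = random_pssm(99, length=10)
        with pytest.raises(ValidationError, match="sample ids"):
            fuse([aadp_pssm(pssm), pssm_composition(other), rpssm(other)])

    def test_missing_block_rejected(self, pssm):
        with pytest.raises(ValidationError):
            fuse([aadp_pssm(pssm), rpssm(pssm)])


@pytest.mark.parametrize("seed", range(50))
def test_all_extractors_agree_with_oracles(seed):
    """Vectorised extractors equal explicit-loop references on random PSSMs."""
    m = random_pssm(seed)
    scores = m.scores.tolist()
    groups = DEFAULT_REDUCTION.groups
    assert np.allclose(aac_pssm(m).values, oracles.aac_oracle(scores), atol=1e-10)
    assert np.allclose(dpc_pssm(m).values, oracles.dpc_oracle(scores), atol=1e-10)
    assert np.allclose(
        pssm_composition(m).values,
        oracles.composition_oracle(scores, m.sequence.residues),
        atol=1e-10,
    )
    assert np.allclose(
        rpssm(m).values, oracles.rpssm_oracle(scores, groups), atol=1e-10
    )


def test_extractors_are_pure_functions_of_matrix(tmp_path, pssm):
    """The same matrix parsed from disk yields identical features."""
    from dbpforest import parse_pssm, write_pssm

    write_pssm(pssm, tmp_path / "m.pssm")
    reparsed = parse_pssm(tmp_path / "m.pssm")
    assert np.array_equal(extract_features(reparsed).values, extract_features(pssm).values)


def test_sigmoid_flag_bounds_aac():
    m = random_pssm(11, length=20)
    out = aac_pssm(m, sigmoid=True).values
    assert np.all((out > 0) & (out < 1))
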