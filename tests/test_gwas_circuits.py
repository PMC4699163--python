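"""MAF and chi-square block circuits against the cleartext fixed-point oracles."""

import random

import numpy as np
import pytest

from fedgwas import circuit as C
from fedgwas import gwas_circuits as G
from fedgwas import oracles as O
from fedgwas.encoding import CountWord, PackedBlock
from tests.conftest import make_meta

FPP = 16


def eval_one(circ, meta, xa, xb):
    """Evaluate a 1-genotype block circuit on per-party (case, control) counts."""
    va = G.block_input_value(PackedBlock(0, (CountWord(*xa),)), meta)
    vb = G.block_input_value(PackedBlock(0, (CountWord(*xb),)), meta)
    return C.evaluate_plain(circ, va, vb)


def batch_inputs(meta, tables):
    """Bit matrices for many (xa_case, xa_ctrl, xb_case, xb_ctrl) tuples."""
    w_case, w_ctrl = G.input_field_widths(meta)
    n_bits = w_case + w_ctrl

    def bits(case, ctrl):
        v = case | (ctrl << w_case)
        return [(v >> i) & 1 for i in range(n_bits)]

    A = np.array([bits(t[0], t[1]) for t in tables], bool)
    B = np.array([bits(t[2], t[3]) for t in tables], bool)
    return A, B


class TestMafCircuit:
    def test_worked_example_mantissa(self, worked_meta):
        circ = G.build_maf_circuit(1, worked_meta, FPP)
        out = eval_one(circ, worked_meta, (5, 5), (1, 1))
        assert out["maf_case/0"] == out["maf_control/0"] == 26214
        assert abs(26214 / 2**16 - 0.4) < 2**-16

    def test_tie_is_exactly_half(self):
        meta = make_meta(12, 12)
        circ = G.build_maf_circuit(1, meta, FPP)
        out = eval_one(circ, meta, (3, 3), (3, 3))
        assert out["maf_case/0"] == 1 << (FPP - 1)

    def test_monomorphic_is_zero(self):
        meta = make_meta(10, 10)
        circ = G.build_maf_circuit(1, meta, FPP)
        out = eval_one(circ, meta, (0, 10), (0, 0))
        assert out["maf_case/0"] == 0  # no copies of the low allele at all
        assert out["maf_control/0"] == 0  # all copies are the low allele

    def test_matches_oracle_and_minor_symmetry(self):
        rng = random.Random(7)
        meta = make_meta(34, 26)
        circ = G.build_maf_circuit(1, meta, FPP)
        for _ in range(150):
            ac = rng.randint(0, 17)
            bc = rng.randint(0, 34 - ac)
            al = rng.randint(0, 13)
            bl = rng.randint(0, 26 - al)
            out = eval_one(circ, meta, (ac, al), (bc, bl))
            mc, frac_c = O.cleartext_maf(ac + bc, 34, FPP)
            ml, _ = O.cleartext_maf(al + bl, 26, FPP)
            assert out["maf_case/0"] == mc.mantissa
            assert out["maf_control/0"] == ml.mantissa
            # minor-allele symmetry and range
            assert O.cleartext_maf(34 - ac - bc, 34, FPP)[0].mantissa == mc.mantissa
            assert 0 <= frac_c <= 0.5
            assert mc.mantissa <= 1 << (FPP - 1)

    def test_borrow_wires_never_fire(self):
        meta = make_meta(20, 20)
        circ = G.build_maf_circuit(2, meta, FPP, expose_borrows=True)
        rng = random.Random(8)
        for _ in range(40):
            words_a = tuple(CountWord(rng.randint(0, 10), rng.randint(0, 10)) for _ in range(2))
            words_b = tuple(CountWord(rng.randint(0, 10), rng.randint(0, 10)) for _ in range(2))
            out = C.evaluate_plain(
                circ,
                G.block_input_value(PackedBlock(0, words_a), meta),
                G.block_input_value(PackedBlock(0, words_b), meta),
            )
            assert all(v == 0 for k, v in out.items() if k.startswith("borrow"))


class TestChi2Circuit:
    def test_proportional_table_is_zero(self):
        meta = make_meta(40, 40)
        circ = G.build_chi2_circuit(1, meta, FPP)
        out = eval_one(circ, meta, (30, 30), (0, 0))  # case 30/10 == control 30/10
        assert out["chi2/0"] == 0 and out["chi2_degenerate/0"] == 0

    def test_disjoint_table_is_twenty(self):
        meta = make_meta(10, 10)
        circ = G.build_chi2_circuit(1, meta, FPP)
        out = eval_one(circ, meta, (10, 0), (0, 0))
        assert out["chi2/0"] == 20 << FPP  # exact: all expected counts are 5
        assert abs(out["chi2/0"] / 2**FPP - 20.0) <= 4 * 2**-12

    def test_degenerate_column_flagged_zero(self):
        meta = make_meta(10, 10)
        circ = G.build_chi2_circuit(1, meta, FPP)
        out = eval_one(circ, meta, (10, 10), (0, 0))  # low allele fixed everywhere
        assert out["chi2/0"] == 0 and out["chi2_degenerate/0"] == 1

    def test_matches_oracle_on_random_tables_batch(self):
        meta = make_meta(34, 26)
        circ = G.build_chi2_circuit(1, meta, FPP)
        rng = random.Random(9)
        tables = []
        for _ in range(400):
            ac = rng.randint(0, 17); bc = rng.randint(0, 34 - ac)
            al = rng.randint(0, 13); bl = rng.randint(0, 26 - al)
            tables.append((ac, al, bc, bl))
        A, B = batch_inputs(meta, tables)
        out = C.evaluate_plain_batch(circ, A, B)
        for i, (ac, al, bc, bl) in enumerate(tables):
            obs = (ac + bc, 34 - ac - bc, al + bl, 26 - al - bl)
            ref = O.cleartext_chi2(obs, (34, 26), FPP)
            assert out["chi2/0"][i] == ref.value.mantissa, (i, obs)
            assert bool(out["chi2_degenerate/0"][i]) == ref.degenerate

    def test_unsigned_safety_borrows_zero(self):
        meta = make_meta(18, 14)
        circ = G.build_chi2_circuit(1, meta, FPP, expose_borrows=True)
        rng = random.Random(10)
        tables = [
            (rng.randint(0, 9), rng.randint(0, 7), rng.randint(0, 9), rng.randint(0, 7))
            for _ in range(200)
        ]
        A, B = batch_inputs(meta, tables)
        out = C.evaluate_plain_batch(circ, A, B)
        for k, v in out.items():
            if k.startswith("borrow"):
                assert not v.any(), k

    def test_invariance_under_label_and_row_swap(self):
        meta = make_meta(24, 24)  # equal totals so rows can swap
        circ = G.build_chi2_circuit(1, meta, FPP)
        rng = random.Random(11)
        for _ in range(50):
            ac, al = rng.randint(0, 24), rng.randint(0, 24)
            base = eval_one(circ, meta, (ac, al), (0, 0))
            swapped_alleles = eval_one(circ, meta, (24 - ac, 24 - al), (0, 0))
            swapped_rows = eval_one(circ, meta, (al, ac), (0, 0))
            assert base["chi2/0"] == swapped_alleles["chi2/0"] == swapped_rows["chi2/0"]

    def test_fpp_too_small_for_study_rejected(self):
        with pytest.raises(G.GwasCircuitError, match="fpp"):
            G.build_chi2_circuit(1, make_meta(400, 2), fpp=2)


class TestExpectedCounts:
    def test_uniform_table(self):
        # marginals rows (20,20), cols (20,20), N=40 -> every expected count 10
        assert G.expected_count_mantissas((10, 10, 10, 10), FPP) == [10 << FPP] * 4

    def test_integer_exact_table(self):
        # rows (10,10), cols (16,4): exp = 8, 2, 8, 2
        obs = (8, 2, 8, 2)
        assert G.expected_count_mantissas(obs, FPP) == [8 << FPP, 2 << FPP, 8 << FPP, 2 << FPP]

    def test_expected_sum_is_grand_total(self):
        rng = random.Random(12)
        for _ in range(200):
            obs = tuple(rng.randint(0, 200) for _ in range(4))
            if sum(obs) == 0:
                continue
            exps = G.expected_count_mantissas(obs, FPP)
            assert abs(sum(exps) - (sum(obs) << FPP)) <= 4


class TestInputBinding:
    def test_count_above_total_rejected(self):
        meta = make_meta(6, 6)
        blk = PackedBlock(0, (CountWord(9, 0),))  # 9 > total 6 -> needs 4 bits
        with pytest.raises(G.GwasCircuitError):
            G.block_input_value(blk, meta)

    def test_zero_genotypes_rejected(self):
        with pytest.raises(G.GwasCircuitError):
            G.build_maf_circuit(0, make_meta(4, 4))

    def test_per_genotype_subcircuits_independent(self):
        """Outputs per genotype depend only on that genotype's inputs."""
        meta = make_meta(10, 10, n_loci=3)
        circ = G.build_maf_circuit(3, meta, FPP)
        words1 = (CountWord(2, 3), CountWord(4, 5), CountWord(1, 0))
        words2 = (CountWord(2, 3), CountWord(0, 1), CountWord(1, 0))
        zeros = PackedBlock(0, (CountWord(0, 0),) * 3)
        vz = G.block_input_value(zeros, meta)
        o1 = C.evaluate_plain(circ, G.block_input_value(PackedBlock(0, words1), meta), vz)
        o2 = C.evaluate_plain(circ, G.block_input_value(PackedBlock(0, words2), meta), vz)
        assert o1["maf_case/0"] == o2["maf_case/0"]
        assert o1["maf_case/2"] == o2["maf_case/2"]
        assert o1["maf_case/1"] != o2["maf_case/1"]
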