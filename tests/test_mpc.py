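"""Garbling, oblivious transfer, sessions, transports, and the parallel runner."""

import logging
import random
import socket
import threading

import pytest

from fedgwas import circuit as C
from fedgwas import gwas_circuits as G
from fedgwas.encoding import CountWord, PackedBlock
from fedgwas.mpc.garble import (
    GarbledCircuit,
    GarbledEvalError,
    RandomSource,
    evaluate_garbled,
    garble,
)
from fedgwas.mpc.ot import OTError, OTReceiver, OTSender, ot_transfer_local
from fedgwas.mpc.session import (
    BlockSessionError,
    HandshakeError,
    run_parallel_simulated,
    run_session,
    simulate_session,
)
from fedgwas.mpc.transport import (
    LoopbackTransport,
    TcpTransport,
    TransportError,
    loopback_pair,
)
from tests.conftest import make_meta

logging.disable(logging.WARNING)


def and_circuit():
    c = C.Circuit()
    a = c.new_input_word("A", 1)
    b = c.new_input_word("B", 1)
    c.add_output("o", C.WordRef([c.and_(a.wires[0], b.wires[0])]))
    return c.finalize()


def random_circuit(rng: random.Random, n_gates: int = 150) -> C.Circuit:
    c = C.Circuit()
    a = c.new_input_word("A", 4)
    b = c.new_input_word("B", 4)
    wires = list(a.wires) + list(b.wires)
    for _ in range(n_gates):
        pick = rng.randrange(5)
        if pick == 0:
            wires.append(c.const(rng.randint(0, 1)))
        elif pick == 1:
            wires.append(c.not_(rng.choice(wires)))
        else:
            kind = C.AND if pick == 2 else C.XOR
            wires.append(c.gate(kind, rng.choice(wires), rng.choice(wires)))
    c.add_output("o", C.WordRef(wires[-8:]))
    return c.finalize()


def garbled_run(g, circ, va, vb):
    la = g.generator_input_labels([(va >> i) & 1 for i in range(len(circ.inputs_a))])
    lb = b"".join(
        pair[(vb >> i) & 1] for i, pair in enumerate(g.evaluator_label_pairs())
    )
    return g.decode_outputs(evaluate_garbled(g.gc, la, lb))


class TestGarble:
    def test_and_gate_truth_table(self):
        circ = and_circuit()
        g = garble(circ, 42)
        for x in (0, 1):
            for y in (0, 1):
                assert garbled_run(g, circ, x, y)["o"] == (x & y)

    def test_same_seed_same_bytes(self):
        circ = and_circuit()
        g1, g2 = garble(circ, 7), garble(circ, 7)
        assert g1.gc.tables == g2.gc.tables
        assert (g1.label0, g1.label1) == (g2.label0, g2.label1)
        assert garble(circ, 8).gc.tables != g1.gc.tables

    def test_tampered_ciphertext_detected(self):
        circ = and_circuit()
        g = garble(circ, 1)
        bad = bytes(x ^ 0xA5 for x in g.gc.tables)
        with pytest.raises(GarbledEvalError, match="authentication"):
            evaluate_garbled(
                GarbledCircuit(circ, bad, g.gc.const_labels),
                g.generator_input_labels([1]),
                g.evaluator_label_pairs()[0][1],
            )

    def test_wrong_label_blob_size(self):
        circ = and_circuit()
        g = garble(circ, 1)
        with pytest.raises(GarbledEvalError, match="size"):
            evaluate_garbled(g.gc, b"short", g.evaluator_label_pairs()[0][0])

    def test_random_circuits_garbled_equals_plain(self):
        rng = random.Random(5)
        for t in range(25):
            circ = random_circuit(rng)
            g = garble(circ, t)
            for _ in range(4):
                va, vb = rng.randrange(16), rng.randrange(16)
                assert garbled_run(g, circ, va, vb) == C.evaluate_plain(circ, va, vb)


class TestOT:
    def test_both_choice_bits(self):
        m0, m1 = b"label-zero-....." , b"label-one-......"
        for b in (0, 1):
            got = ot_transfer_local([(m0, m1)], [b], RandomSource(3), RandomSource(4))
            assert got == [m1 if b else m0]

    def test_word_of_16_labels_delivered(self):
        rng = random.Random(6)
        pairs = [(rng.randbytes(16), rng.randbytes(16)) for _ in range(16)]
        choices = [rng.randint(0, 1) for _ in range(16)]
        got = ot_transfer_local(pairs, choices, RandomSource(1), RandomSource(2))
        assert got == [pairs[i][choices[i]] for i in range(16)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(OTError, match="length"):
            OTSender([(b"ab", b"abc")], RandomSource(0))

    def test_malformed_group_element_rejected(self):
        sender = OTSender([(b"x" * 16, b"y" * 16)], RandomSource(0))
        with pytest.raises(OTError, match="malformed"):
            sender.respond([0])

    def test_receiver_choice_count_enforced(self):
        sender = OTSender([(b"x" * 16, b"y" * 16)], RandomSource(0))
        with pytest.raises(OTError, match="public keys"):
            sender.respond([])


def worked_setup(worked_meta):
    circ = G.build_maf_circuit(1, worked_meta, 16)
    va = G.block_input_value(PackedBlock(0, (CountWord(5, 5),)), worked_meta)
    vb = G.block_input_value(PackedBlock(0, (CountWord(1, 1),)), worked_meta)
    return circ, va, vb


class TestSession:
    def test_worked_example_both_parties_get_04(self, worked_meta):
        circ, va, vb = worked_setup(worked_meta)
        gen, ev = simulate_session(circ, va, vb, seed=11, context=b"maf-test")
        assert gen.outputs == ev.outputs == C.evaluate_plain(circ, va, vb)
        assert round(gen.outputs["maf_case/0"] / 2**16, 1) == 0.4

    def test_chi2_disjoint_table_through_protocol(self):
        meta = make_meta(10, 10)
        circ = G.build_chi2_circuit(1, meta, 16)
        va = G.block_input_value(PackedBlock(0, (CountWord(10, 0),)), meta)
        vb = G.block_input_value(PackedBlock(0, (CountWord(0, 0),)), meta)
        gen, _ = simulate_session(circ, va, vb, seed=2, context=b"chi2-test")
        assert gen.outputs["chi2/0"] == 20 << 16

    def test_transcript_shape_independent_of_private_counts(self, worked_meta):
        circ, va, vb = worked_setup(worked_meta)
        va2 = G.block_input_value(PackedBlock(0, (CountWord(2, 9),)), worked_meta)
        g1, e1 = simulate_session(circ, va, vb, seed=1, context=b"t")
        g2, e2 = simulate_session(circ, va2, vb, seed=99, context=b"t")
        assert g1.transcript.shape() == g2.transcript.shape()
        assert e1.transcript.shape() == e2.transcript.shape()

    def test_transcripts_reproducible_for_fixed_seed(self, worked_meta):
        circ, va, vb = worked_setup(worked_meta)
        g1, _ = simulate_session(circ, va, vb, seed=5, context=b"t")
        g2, _ = simulate_session(circ, va, vb, seed=5, context=b"t")
        assert g1.transcript.shape() == g2.transcript.shape()
        assert g1.outputs == g2.outputs

    def test_context_mismatch_aborts(self, worked_meta):
        circ, va, vb = worked_setup(worked_meta)
        t_gen, t_eval = loopback_pair(timeout=10)
        err = {}

        def eval_side():
            try:
                run_session("evaluator", circ, vb, t_eval, 1, context=b"ctx-B")
            except HandshakeError as e:
                err["eval"] = e

        th = threading.Thread(target=eval_side, daemon=True)
        th.start()
        with pytest.raises(HandshakeError, match="context differs"):
            run_session("generator", circ, va, t_gen, 1, context=b"ctx-A")
        th.join(5)
        assert isinstance(err.get("eval"), HandshakeError)

    def test_missing_peer_times_out(self, worked_meta):
        circ, va, _ = worked_setup(worked_meta)
        lonely = LoopbackTransport(__import__("queue").Queue(), __import__("queue").Queue(), timeout=0.2)
        with pytest.raises(TransportError, match="timeout"):
            run_session("generator", circ, va, lonely, 1, context=b"t")

    def test_chi2_transcript_larger_than_maf(self):
        meta = make_meta(10, 10, n_loci=2)
        words = (CountWord(3, 4), CountWord(5, 1))
        blk = PackedBlock(0, words)
        va = G.block_input_value(blk, meta)
        maf_c = G.build_maf_circuit(2, meta, 16)
        chi_c = G.build_chi2_circuit(2, meta, 16)
        g_maf, _ = simulate_session(maf_c, va, va, seed=3, context=b"m")
        g_chi, _ = simulate_session(chi_c, va, va, seed=3, context=b"c")
        assert g_chi.transcript.total_bytes > g_maf.transcript.total_bytes


class TestParallel:
    def setup_blocks(self, n_blocks=3):
        meta = make_meta(10, 10, n_loci=n_blocks)
        circ = G.build_maf_circuit(1, meta, 16)
        rng = random.Random(0)
        ins_a, ins_b = [], []
        for _ in range(n_blocks):
            a = CountWord(rng.randint(0, 5), rng.randint(0, 5))
            b = CountWord(rng.randint(0, 5), rng.randint(0, 5))
            ins_a.append(G.block_input_value(PackedBlock(0, (a,)), meta))
            ins_b.append(G.block_input_value(PackedBlock(0, (b,)), meta))
        return [circ] * n_blocks, ins_a, ins_b

    def test_worker_count_does_not_change_results(self):
        circs, ins_a, ins_b = self.setup_blocks()
        r1 = run_parallel_simulated(circs, ins_a, ins_b, workers=1, seed=9)
        r2 = run_parallel_simulated(circs, ins_a, ins_b, workers=2, seed=9)
        assert [g.outputs for g, _ in r1] == [g.outputs for g, _ in r2]

    def test_failing_block_is_named(self):
        circs, ins_a, ins_b = self.setup_blocks(5)
        circs = list(circs)
        circs[3] = None  # block 3 cannot build a session
        with pytest.raises(BlockSessionError, match="block 3") as exc:
            run_parallel_simulated(circs, ins_a, ins_b, workers=2, seed=0)
        assert exc.value.block_index == 3


class TestTcpTransport:
    def test_session_over_real_sockets(self, worked_meta):
        circ, va, vb = worked_setup(worked_meta)
        with socket.socket() as probe:
            probe.bind(("127.0.0.1", 0))
            port = probe.getsockname()[1]
        results = {}

        def server():
            t = TcpTransport.listen_once("127.0.0.1", port, timeout=20)
            try:
                results["eval"] = run_session("evaluator", circ, vb, t, 2, context=b"tcp")
            finally:
                t.close()

        th = threading.Thread(target=server, daemon=True)
        th.start()
        import time

        t = None
        for _ in range(50):  # wait for the listener
            try:
                t = TcpTransport.connect("127.0.0.1", port, timeout=20)
                break
            except TransportError:
                time.sleep(0.05)
        assert t is not None
        try:
            gen = run_session("generator", circ, va, t, 1, context=b"tcp")
        finally:
            t.close()
        th.join(20)
        assert gen.outputs["maf_case/0"] == 26214
        assert results["eval"].outputs == gen.outputs

    def test_connect_refused(self):
        with pytest.raises(TransportError, match="cannot reach"):
            TcpTransport.connect("127.0.0.1", 1, timeout=1)
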