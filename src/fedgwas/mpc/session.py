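"""The two-party protocol session and the multi-block parallel runner.

Roles follow the classic garbled-circuit split: the *generator* builds and
garbles the block circuit and acts as OT sender for the evaluator's input
labels; the *evaluator* runs the garbled circuit and returns the active output
labels to the generator, who alone holds the label pairs needed to decode.
The generator then shares the cleartext statistics, so both institutions end
the session with the results.

Both parties must agree on the public context (metadata digest, statistic,
fixed-point precision, block plan) before any secret-dependent message; the
handshake aborts on any mismatch.  Every message is recorded in a
:class:`SessionTranscript`; with seeded randomness transcripts are
byte-reproducible, and their shape (message types and sizes) depends only on
the circuit shape, never on the private counts.
"""

from __future__ import annotations

import hashlib
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from threading import Thread

from ..circuit import Circuit
from .garble import LABEL_BYTES, Garbling, GarbledCircuit, RandomSource, evaluate_garbled, garble
from .ot import ELEM_BYTES, OTReceiver, OTSender
from .transport import LoopbackTransport, loopback_pair

log = logging.getLogger(__name__)

PROTOCOL_VERSION = 1

MSG_HELLO = 1
MSG_TABLES = 2
MSG_CONSTS = 3
MSG_GEN_INPUTS = 4
MSG_OT_SETUP = 5
MSG_OT_PK = 6
MSG_OT_RESP = 7
MSG_OUT_LABELS = 8
MSG_OUT_PLAIN = 9

MSG_NAMES = {
    MSG_HELLO: "hello",
    MSG_TABLES: "garbled_tables",
    MSG_CONSTS: "const_labels",
    MSG_GEN_INPUTS: "generator_input_labels",
    MSG_OT_SETUP: "ot_setup",
    MSG_OT_PK: "ot_public_keys",
    MSG_OT_RESP: "ot_response",
    MSG_OUT_LABELS: "output_labels",
    MSG_OUT_PLAIN: "output_plaintext",
}


class HandshakeError(RuntimeError):
    pass


class BlockSessionError(RuntimeError):
    def __init__(self, block_index: int, cause: BaseException):
        super().__init__(f"block {block_index} session failed: {cause}")
        self.block_index = block_index
        self.cause = cause


@dataclass
class SessionTranscript:
    role: str
    messages: list[tuple[str, str, int]] = field(default_factory=list)
    elapsed_s: float = 0.0

    def record(self, direction: str, msg_type: int, n_bytes: int) -> None:
        self.messages.append((direction, MSG_NAMES.get(msg_type, str(msg_type)), n_bytes))

    @property
    def bytes_sent(self) -> int:
        return sum(n for d, _, n in self.messages if d == "send")

    @property
    def bytes_received(self) -> int:
        return sum(n for d, _, n in self.messages if d == "recv")

    @property
    def total_bytes(self) -> int:
        return self.bytes_sent + self.bytes_received

    def shape(self) -> list[tuple[str, str, int]]:
        """The leakage surface: message order, types, and sizes only."""
        return list(self.messages)


@dataclass
class SessionResult:
    outputs: dict[str, int]
    transcript: SessionTranscript


class _Recorder:
    def __init__(self, transport, transcript: SessionTranscript):
        self._t = transport
        self._tr = transcript

    def send(self, msg_type: int, payload: bytes) -> None:
        self._tr.record("send", msg_type, len(payload))
        self._t.send(msg_type, payload)

    def expect(self, msg_type: int) -> bytes:
        got, payload = self._t.recv()
        self._tr.record("recv", got, len(payload))
        if got != msg_type:
            raise HandshakeError(
                f"expected {MSG_NAMES.get(msg_type)}, peer sent {MSG_NAMES.get(got, got)}"
            )
        return payload


def session_context_digest(context: bytes) -> bytes:
    return hashlib.sha256(context).digest()


def _hello(rec: _Recorder, context: bytes) -> None:
    payload = bytes([PROTOCOL_VERSION]) + session_context_digest(context)
    rec.send(MSG_HELLO, payload)
    peer = rec.expect(MSG_HELLO)
    if peer[0] != PROTOCOL_VERSION:
        raise HandshakeError(
            f"protocol version mismatch: ours {PROTOCOL_VERSION}, peer {peer[0]}"
        )
    if peer[1:] != payload[1:]:
        raise HandshakeError(
            "public study context differs between parties "
            "(metadata, statistic, fpp or block plan mismatch)"
        )


def _bits(value: int, n: int) -> list[int]:
    return [(value >> i) & 1 for i in range(n)]


def _pack_outputs(circ: Circuit, outputs: dict[str, int]) -> bytes:
    """Fixed-width output encoding so the message size is value-independent."""
    buf = bytearray()
    for name, (wires, _scale) in circ.outputs.items():
        nb = (len(wires) + 7) // 8
        buf += outputs[name].to_bytes(nb, "big")
    return bytes(buf)


def _unpack_outputs(circ: Circuit, payload: bytes) -> dict[str, int]:
    out = {}
    pos = 0
    for name, (wires, _scale) in circ.outputs.items():
        nb = (len(wires) + 7) // 8
        out[name] = int.from_bytes(payload[pos : pos + nb], "big")
        pos += nb
    if pos != len(payload):
        raise HandshakeError("output payload size mismatch")
    return out


def run_session(
    role: str,
    circ: Circuit,
    input_value: int,
    transport,
    seed: int | None = None,
    context: bytes = b"",
) -> SessionResult:
    """Run one block's protocol end to end for one role.

    `input_value` packs this party's manifest-ordered input bits (bit i feeds
    the i-th manifest wire of its own manifest).  Both parties receive the
    decoded outputs.
    """
    transcript = SessionTranscript(role)
    rec = _Recorder(transport, transcript)
    rng = RandomSource(seed)
    t0 = time.monotonic()
    _hello(rec, context)

    if role == "generator":
        garbling = garble(circ, rng)
        gc = garbling.gc
        rec.send(MSG_TABLES, gc.tables)
        rec.send(MSG_CONSTS, gc.const_labels)
        rec.send(
            MSG_GEN_INPUTS,
            garbling.generator_input_labels(_bits(input_value, len(circ.inputs_a))),
        )
        sender = OTSender(garbling.evaluator_label_pairs(), rng)
        c, u = sender.setup()
        rec.send(MSG_OT_SETUP, c.to_bytes(ELEM_BYTES, "big") + u.to_bytes(ELEM_BYTES, "big"))
        pk_payload = rec.expect(MSG_OT_PK)
        n_ot = len(circ.inputs_b)
        pk0s = [
            int.from_bytes(pk_payload[i * ELEM_BYTES : (i + 1) * ELEM_BYTES], "big")
            for i in range(n_ot)
        ]
        resp = sender.respond(pk0s)
        rec.send(
            MSG_OT_RESP,
            b"".join(
                v0.to_bytes(LABEL_BYTES, "big") + v1.to_bytes(LABEL_BYTES, "big")
                for v0, v1 in resp
            ),
        )
        out_labels = rec.expect(MSG_OUT_LABELS)
        outputs = garbling.decode_outputs(out_labels)
        rec.send(MSG_OUT_PLAIN, _pack_outputs(circ, outputs))
    elif role == "evaluator":
        tables = rec.expect(MSG_TABLES)
        consts = rec.expect(MSG_CONSTS)
        gen_inputs = rec.expect(MSG_GEN_INPUTS)
        choices = _bits(input_value, len(circ.inputs_b))
        receiver = OTReceiver(choices, rng)
        setup = rec.expect(MSG_OT_SETUP)
        c = int.from_bytes(setup[:ELEM_BYTES], "big")
        u = int.from_bytes(setup[ELEM_BYTES:], "big")
        pk0s = receiver.pk0s(c, u)
        rec.send(MSG_OT_PK, b"".join(pk.to_bytes(ELEM_BYTES, "big") for pk in pk0s))
        resp_payload = rec.expect(MSG_OT_RESP)
        resp = [
            (
                int.from_bytes(resp_payload[i * 2 * LABEL_BYTES : i * 2 * LABEL_BYTES + LABEL_BYTES], "big"),
                int.from_bytes(resp_payload[i * 2 * LABEL_BYTES + LABEL_BYTES : (i + 1) * 2 * LABEL_BYTES], "big"),
            )
            for i in range(len(choices))
        ]
        my_labels = b"".join(receiver.decrypt(resp))
        gc = GarbledCircuit(circ, tables, consts)
        out_labels = evaluate_garbled(gc, gen_inputs, my_labels)
        rec.send(MSG_OUT_LABELS, out_labels)
        outputs = _unpack_outputs(circ, rec.expect(MSG_OUT_PLAIN))
    else:
        raise ValueError(f"unknown role {role!r}")

    transcript.elapsed_s = time.monotonic() - t0
    log.info(
        "session done: role=%s gates=%d sent=%dB recv=%dB %.2fs",
        role, circ.n_gates, transcript.bytes_sent, transcript.bytes_received,
        transcript.elapsed_s,
    )
    return SessionResult(outputs, transcript)


def block_seeds(master_seed: int | None, block_index: int) -> tuple[int | None, int | None]:
    """Stable per-block, per-role seeds (independent of scheduling order)."""
    if master_seed is None:
        return None, None
    def h(tag: str) -> int:
        d = hashlib.sha256(f"{master_seed}/{block_index}/{tag}".encode()).digest()
        return int.from_bytes(d[:7], "big")
    return h("generator"), h("evaluator")


def simulate_session(
    circ: Circuit,
    input_a: int,
    input_b: int,
    seed: int | None = None,
    context: bytes = b"",
    timeout: float = 600.0,
) -> tuple[SessionResult, SessionResult]:
    """Both roles over an in-process loopback; returns (generator, evaluator)."""
    t_gen, t_eval = loopback_pair(timeout)
    seed_gen, seed_eval = (seed, None if seed is None else seed + 1)
    box: dict = {}

    def eval_side():
        try:
            box["eval"] = run_session("evaluator", circ, input_b, t_eval, seed_eval, context)
        except BaseException as e:  # propagated by the caller
            box["error"] = e

    th = Thread(target=eval_side, daemon=True)
    th.start()
    try:
        gen_result = run_session("generator", circ, input_a, t_gen, seed_gen, context)
    except BaseException:
        # do not wait out the evaluator's transport timeout: it is a daemon
        # thread and the generator's failure is the root cause (unless the
        # evaluator already recorded its own)
        th.join(timeout=2.0)
        if "error" in box:
            raise box["error"] from None
        raise
    th.join(timeout=timeout)
    if "error" in box:
        raise box["error"]
    if not th.is_alive() and "eval" not in box:
        raise RuntimeError("evaluator thread ended without a result")
    return gen_result, box["eval"]


def run_parallel_simulated(
    circuits: list[Circuit],
    inputs_a: list[int],
    inputs_b: list[int],
    workers: int = 1,
    seed: int | None = None,
    context_fn=None,
) -> list[tuple[SessionResult, SessionResult]]:
    """One independent simulated session per block, at most `workers` at a time.

    Results are returned in block order regardless of completion order; the
    first failing block aborts the whole run with its index.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if not (len(circuits) == len(inputs_a) == len(inputs_b)):
        raise ValueError("blocks/inputs length mismatch")

    def one(i: int):
        sg, _ = block_seeds(seed, i)
        ctx = context_fn(i) if context_fn else f"block/{i}".encode()
        try:
            return simulate_session(circuits[i], inputs_a[i], inputs_b[i], sg, ctx)
        except BaseException as e:
            raise BlockSessionError(i, e) from e

    if workers == 1:
        return [one(i) for i in range(len(circuits))]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = [pool.submit(one, i) for i in range(len(circuits))]
        return [f.result() for f in futures]


def default_workers() -> int:
    """The 2-processes-per-core rule of thumb for enqueued block sessions."""
    import os

    return 2 * (os.cpu_count() or 1)
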