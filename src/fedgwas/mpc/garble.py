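"""Classic Yao garbling with point-and-permute.

Every wire carries a pair of 128-bit labels; the label's low bit of its last
byte is the public "point" bit, and the two labels of a pair always have
opposite point bits.  Each binary gate (AND, XOR — no free-XOR or half-gate
optimisation, correctness and auditability first) becomes four ciphertexts
ordered by the input labels' point bits:

    ct[2*ta + tb] = SHA-256(label_a ‖ label_b ‖ gate_id) XOR (out_label ‖ 0^16)

The 16 zero bytes authenticate decryption: with the wrong key pair the padding
check fails and evaluation aborts loudly.  NOT gates are free (the output wire
reuses the input pair, swapped) and CONST gates simply publish the active
label for their public value.
"""

from __future__ import annotations

import hashlib
import logging
import os
import random
from dataclasses import dataclass

from ..circuit import AND, CONST, NOT, XOR, Circuit, CircuitError

log = logging.getLogger(__name__)

LABEL_BYTES = 16
CT_BYTES = 32  # sha256 digest size; label ‖ zero padding
ZERO_PAD = bytes(LABEL_BYTES)


class GarbledEvalError(RuntimeError):
    """No garbled-table row authenticated: corrupted circuit or wrong labels."""


class RandomSource:
    """Protocol randomness: OS entropy by default, seedable for reproducibility.

    A seeded source is NOT cryptographically secure — it exists so tests and
    audits can reproduce byte-identical transcripts — and says so once.
    """

    def __init__(self, seed: int | None = None):
        self.seed = seed
        if seed is None:
            self._rand = None
        else:
            log.warning(
                "RandomSource seeded (seed=%d): transcripts are reproducible "
                "but NOT cryptographically secure; use only for tests/audits",
                seed,
            )
            self._rand = random.Random(seed)

    def bytes(self, n: int) -> bytes:
        return os.urandom(n) if self._rand is None else self._rand.randbytes(n)

    def randint_bits(self, bits: int) -> int:
        return int.from_bytes(self.bytes((bits + 7) // 8), "big") | 1


@dataclass
class GarbledCircuit:
    """What crosses the wire: encrypted tables plus public-constant labels.

    The circuit topology itself is public — both parties rebuild it from the
    shared metadata — so it is carried by reference, not re-serialized.
    """

    circuit: Circuit
    tables: bytes  # 4 * 32 bytes per binary gate, in gate order
    const_labels: bytes  # 16 bytes per CONST gate, in gate order

    def table_bytes(self) -> int:
        return len(self.tables) + len(self.const_labels)


@dataclass
class Garbling:
    """Generator-side secret state: the full label pairs for every wire."""

    gc: GarbledCircuit
    label0: bytes
    label1: bytes

    def _pair(self, wire: int) -> tuple[bytes, bytes]:
        o = wire * LABEL_BYTES
        return self.label0[o : o + LABEL_BYTES], self.label1[o : o + LABEL_BYTES]

    def generator_input_labels(self, bits) -> bytes:
        """Active labels for the generator's own input bits, manifest order."""
        return self._active(self.gc.circuit.inputs_a, bits)

    def evaluator_label_pairs(self) -> list[tuple[bytes, bytes]]:
        """Both labels per evaluator input wire (the OT sender's messages)."""
        return [self._pair(w) for w in self.gc.circuit.inputs_b]

    def _active(self, wires, bits) -> bytes:
        bits = _as_bits(bits, len(wires))
        src = (self.label0, self.label1)
        out = bytearray()
        for w, b in zip(wires, bits):
            o = w * LABEL_BYTES
            out += src[b][o : o + LABEL_BYTES]
        return bytes(out)

    def decode_outputs(self, active_output_labels: bytes) -> dict[str, int]:
        """Map returned active output labels back to cleartext output words."""
        circ = self.gc.circuit
        wires = [w for _, (ws, _) in circ.outputs.items() for w in ws]
        if len(active_output_labels) != LABEL_BYTES * len(wires):
            raise GarbledEvalError("output label blob has wrong size")
        bits = []
        for i, w in enumerate(wires):
            lab = active_output_labels[i * LABEL_BYTES : (i + 1) * LABEL_BYTES]
            l0, l1 = self._pair(w)
            if lab == l0:
                bits.append(0)
            elif lab == l1:
                bits.append(1)
            else:
                raise GarbledEvalError(f"unrecognized output label on wire {w}")
        out = {}
        pos = 0
        for name, (ws, _scale) in circ.outputs.items():
            v = 0
            for i in range(len(ws)):
                v |= bits[pos] << i
                pos += 1
            out[name] = v
        return out


def _as_bits(value, n: int) -> list[int]:
    if isinstance(value, int):
        return [(value >> i) & 1 for i in range(n)]
    bits = [1 if b else 0 for b in value]
    if len(bits) != n:
        raise CircuitError(f"expected {n} bits, got {len(bits)}")
    return bits


def garble(circ: Circuit, rng: RandomSource | int | None = None) -> Garbling:
    """Garble a finalized circuit; deterministic given a seeded source."""
    if not circ.finalized:
        raise CircuitError("circuit must be finalized before garbling")
    if not isinstance(rng, RandomSource):
        rng = RandomSource(rng)
    n = circ.n_wires
    lb = LABEL_BYTES
    # bulk label material; force opposite point bits within each pair
    raw = bytearray(rng.bytes(2 * lb * n))
    label0 = raw[: lb * n]
    label1 = raw[lb * n :]
    for w in range(n):
        p = lb * w + lb - 1
        label1[p] = (label1[p] & 0xFE) | ((label0[p] & 1) ^ 1)

    sha = hashlib.sha256
    tables = bytearray()
    consts = bytearray()
    zero = ZERO_PAD
    kinds, in1, in2, outs = circ.kinds, circ.in1, circ.in2, circ.out
    for g in range(len(kinds)):
        k = kinds[g]
        o = outs[g]
        if k == NOT:
            a = in1[g]
            ao, oo = lb * a, lb * o
            label0[oo : oo + lb] = label1[ao : ao + lb]
            label1[oo : oo + lb] = label0[ao : ao + lb]
            continue
        if k == CONST:
            oo = lb * o
            active = label1[oo : oo + lb] if in1[g] else label0[oo : oo + lb]
            consts += active
            continue
        a, b = in1[g], in2[g]
        ao, bo, oo = lb * a, lb * b, lb * o
        la = (label0[ao : ao + lb], label1[ao : ao + lb])
        lbp = (label0[bo : bo + lb], label1[bo : bo + lb])
        lo = (label0[oo : oo + lb] + zero, label1[oo : oo + lb] + zero)
        pa = la[0][-1] & 1
        pb = lbp[0][-1] & 1
        gid = g.to_bytes(4, "big")
        rows = [b""] * 4
        for ta in (0, 1):
            va = ta ^ pa
            ka = la[va]
            for tb in (0, 1):
                vb = tb ^ pb
                v = (va & vb) if k == AND else (va ^ vb)
                mask = sha(ka + lbp[vb] + gid).digest()
                rows[2 * ta + tb] = (
                    int.from_bytes(mask, "big") ^ int.from_bytes(lo[v], "big")
                ).to_bytes(CT_BYTES, "big")
        tables += b"".join(rows)
    gc = GarbledCircuit(circ, bytes(tables), bytes(consts))
    return Garbling(gc, bytes(label0), bytes(label1))


def evaluate_garbled(
    gc: GarbledCircuit, generator_labels: bytes, evaluator_labels: bytes
) -> bytes:
    """Evaluate with one active label per input wire; returns active output labels.

    For every binary gate exactly one table row (picked by the two point bits)
    must decrypt to a label with intact zero padding; anything else raises
    :class:`GarbledEvalError` and aborts the session.
    """
    circ = gc.circuit
    lb = LABEL_BYTES
    if len(generator_labels) != lb * len(circ.inputs_a):
        raise GarbledEvalError("generator label blob has wrong size")
    if len(evaluator_labels) != lb * len(circ.inputs_b):
        raise GarbledEvalError("evaluator label blob has wrong size")
    active = bytearray(lb * circ.n_wires)
    for i, w in enumerate(circ.inputs_a):
        active[lb * w : lb * w + lb] = generator_labels[lb * i : lb * i + lb]
    for i, w in enumerate(circ.inputs_b):
        active[lb * w : lb * w + lb] = evaluator_labels[lb * i : lb * i + lb]

    sha = hashlib.sha256
    tables = gc.tables
    consts = gc.const_labels
    kinds, in1, in2, outs = circ.kinds, circ.in1, circ.in2, circ.out
    t_idx = 0
    c_idx = 0
    for g in range(len(kinds)):
        k = kinds[g]
        o = outs[g]
        oo = lb * o
        if k == NOT:
            ao = lb * in1[g]
            active[oo : oo + lb] = active[ao : ao + lb]
            continue
        if k == CONST:
            active[oo : oo + lb] = consts[c_idx : c_idx + lb]
            c_idx += lb
            continue
        ao, bo = lb * in1[g], lb * in2[g]
        la = bytes(active[ao : ao + lb])
        lbb = bytes(active[bo : bo + lb])
        row = 2 * (la[-1] & 1) + (lbb[-1] & 1)
        base = t_idx + CT_BYTES * row
        ct = tables[base : base + CT_BYTES]
        t_idx += 4 * CT_BYTES
        mask = sha(la + lbb + g.to_bytes(4, "big")).digest()
        plain = (
            int.from_bytes(ct, "big") ^ int.from_bytes(mask, "big")
        ).to_bytes(CT_BYTES, "big")
        if plain[lb:] != ZERO_PAD:
            raise GarbledEvalError(f"gate {g}: garbled row failed authentication")
        active[oo : oo + lb] = plain[:lb]

    out = bytearray()
    for _, (wires, _scale) in circ.outputs.items():
        for w in wires:
            out += active[lb * w : lb * w + lb]
    return bytes(out)
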