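"""Boolean-circuit intermediate representation and unsigned arithmetic builders.

The two-party statistics are compiled to a flat gate list over single-assignment
wires.  The gate basis is {AND, XOR, NOT, CONST}; OR is desugared at build time.
Multi-bit unsigned integers are handled as :class:`WordRef` bundles of wires,
least-significant bit first.  All arithmetic is unsigned: the target runtime has
no signed types, so builders either widen (add, mul) or expose the borrow wire
(sub) so callers can prove non-negativity.

:func:`evaluate_plain` is the cleartext reference evaluator; the garbled
protocol in :mod:`fedgwas.mpc` must agree with it bit for bit.
"""

from __future__ import annotations

from array import array
from typing import Sequence

import numpy as np

AND = 0
XOR = 1
NOT = 2
CONST = 3

KIND_NAMES = {AND: "AND", XOR: "XOR", NOT: "NOT", CONST: "CONST"}
KIND_IDS = {v: k for k, v in KIND_NAMES.items()}


class CircuitError(ValueError):
    """Raised on structurally invalid circuit construction or use."""


class WordRef:
    """An unsigned integer as an ordered bundle of wire ids, LSB first."""

    __slots__ = ("wires",)

    def __init__(self, wires: Sequence[int]):
        wires = tuple(wires)
        if len(set(wires)) != len(wires):
            raise CircuitError("duplicate wires in word")
        self.wires = wires

    @property
    def width(self) -> int:
        return len(self.wires)

    def __len__(self) -> int:
        return len(self.wires)

    def __iter__(self):
        return iter(self.wires)

    def __getitem__(self, i):
        w = self.wires[i]
        return WordRef(w) if isinstance(i, slice) else w

    def __repr__(self):  # pragma: no cover - debug aid
        return f"WordRef(width={len(self.wires)})"


class Circuit:
    """A topologically ordered gate list with per-party input manifests.

    Wires are integer ids assigned in creation order; every gate writes a fresh
    wire, so the gate list is topologically sorted by construction and
    :meth:`finalize` re-checks the invariant.  Output wires are grouped into
    named words carrying a fixed-point scale (0 for plain integers).
    """

    def __init__(self) -> None:
        self.kinds = bytearray()
        self.in1 = array("L")
        self.in2 = array("L")
        self.out = array("L")
        self.n_wires = 0
        self.inputs_a: list[int] = []
        self.inputs_b: list[int] = []
        self.outputs: dict[str, tuple[tuple[int, ...], int]] = {}
        self.finalized = False

    # -- construction ------------------------------------------------------

    def _new_wire(self) -> int:
        w = self.n_wires
        self.n_wires = w + 1
        return w

    def new_input_word(self, party: str, width: int) -> WordRef:
        """Allocate `width` fresh input wires for party 'A' or 'B'."""
        if self.finalized:
            raise CircuitError("circuit already finalized")
        manifest = {"A": self.inputs_a, "B": self.inputs_b}[party]
        wires = [self._new_wire() for _ in range(width)]
        manifest.extend(wires)
        return WordRef(wires)

    def gate(self, kind: int, a: int, b: int = 0) -> int:
        if self.finalized:
            raise CircuitError("circuit already finalized")
        o = self.n_wires
        self.n_wires = o + 1
        self.kinds.append(kind)
        self.in1.append(a)
        self.in2.append(b)
        self.out.append(o)
        return o

    def const(self, bit: int) -> int:
        """A fresh constant wire carrying the public bit value."""
        return self.gate(CONST, 1 if bit else 0)

    def add_output(self, name: str, word: WordRef, scale: int = 0) -> None:
        if name in self.outputs:
            raise CircuitError(f"duplicate output name {name!r}")
        self.outputs[name] = (word.wires, scale)

    def finalize(self) -> "Circuit":
        """Validate topology and freeze the circuit."""
        seen = bytearray(self.n_wires)
        for w in self.inputs_a:
            seen[w] = 1
        for w in self.inputs_b:
            if seen[w]:
                raise CircuitError(f"wire {w} assigned twice")
            seen[w] = 1
        for k, a, b, o in zip(self.kinds, self.in1, self.in2, self.out):
            if k != CONST:
                if not seen[a] or (k != NOT and not seen[b]):
                    raise CircuitError(f"gate output wire {o} uses unset input")
            if seen[o]:
                raise CircuitError(f"wire {o} assigned twice")
            seen[o] = 1
        for name, (wires, _) in self.outputs.items():
            for w in wires:
                if w >= self.n_wires or not seen[w]:
                    raise CircuitError(f"output {name!r} references unset wire {w}")
        self.finalized = True
        return self

    @property
    def n_gates(self) -> int:
        return len(self.kinds)

    def n_table_gates(self) -> int:
        """Gates that need a garbled table (binary AND/XOR)."""
        return sum(1 for k in self.kinds if k in (AND, XOR))

    # -- logic helpers -----------------------------------------------------

    def not_(self, a: int) -> int:
        return self.gate(NOT, a)

    def and_(self, a: int, b: int) -> int:
        return self.gate(AND, a, b)

    def xor_(self, a: int, b: int) -> int:
        return self.gate(XOR, a, b)

    def or_(self, a: int, b: int) -> int:
        # a|b == (a^b)^(a&b); avoids NOT chains.
        return self.xor_(self.xor_(a, b), self.and_(a, b))


# ---------------------------------------------------------------------------
# word-level builders


def const_word(circ: Circuit, value: int, width: int) -> WordRef:
    """Embed a public unsigned constant as `width` CONST wires."""
    if value < 0 or value >= (1 << width):
        raise CircuitError(f"constant {value} does not fit in {width} bits")
    return WordRef([circ.const((value >> i) & 1) for i in range(width)])


def _add_words(circ: Circuit, a: Sequence[int], b: Sequence[int]) -> list[int]:
    """Ripple-carry a+b over possibly unequal widths; result is max(w)+1 bits."""
    if len(a) < len(b):
        a, b = b, a
    out: list[int] = []
    carry: int | None = None
    for i, ai in enumerate(a):
        if i < len(b):
            bi = b[i]
            if carry is None:
                out.append(circ.xor_(ai, bi))
                carry = circ.and_(ai, bi)
            else:
                t = circ.xor_(ai, bi)
                out.append(circ.xor_(t, carry))
                carry = circ.xor_(circ.and_(ai, bi), circ.and_(t, carry))
        else:
            if carry is None:
                out.append(ai)
            else:
                out.append(circ.xor_(ai, carry))
                carry = circ.and_(ai, carry)
    out.append(circ.const(0) if carry is None else carry)
    return out


def add(circ: Circuit, a: WordRef, b: WordRef) -> WordRef:
    """(a + b) as a (w+1)-bit word, carry-out retained as the top bit."""
    if len(a) != len(b):
        raise CircuitError(f"add width mismatch: {len(a)} vs {len(b)}")
    return WordRef(_add_words(circ, a.wires, b.wires))


def _sub_words(
    circ: Circuit, a: Sequence[int], b: Sequence[int]
) -> tuple[list[int], int]:
    """a − b with full borrow chain; either side may be narrower (zero-extended).

    The output has max(len(a), len(b)) bits; when the borrow-out is 1 the
    difference bits wrap modulo 2^width as usual.
    """
    out: list[int] = []
    borrow: int | None = None
    for i in range(max(len(a), len(b))):
        ai = a[i] if i < len(a) else None
        bi = b[i] if i < len(b) else None
        if ai is not None and bi is not None:
            if borrow is None:
                out.append(circ.xor_(ai, bi))
                borrow = circ.and_(circ.not_(ai), bi)
            else:
                t = circ.xor_(ai, bi)
                out.append(circ.xor_(t, borrow))
                # borrow' = (~a & b) | (borrow & ~(a^b)); terms are disjoint.
                u = circ.and_(circ.not_(ai), bi)
                v = circ.and_(borrow, circ.not_(t))
                borrow = circ.xor_(u, v)
        elif bi is None:  # subtrahend exhausted
            if borrow is None:
                out.append(ai)
            else:
                out.append(circ.xor_(ai, borrow))
                borrow = circ.and_(circ.not_(ai), borrow)
        else:  # minuend exhausted: 0 − b − borrow
            if borrow is None:
                out.append(bi)
                borrow = bi
            else:
                out.append(circ.xor_(bi, borrow))
                borrow = circ.or_(bi, borrow)
    return out, (circ.const(0) if borrow is None else borrow)


def sub_nonneg(circ: Circuit, a: WordRef, b: WordRef) -> tuple[WordRef, int]:
    """a − b (same width) plus the exposed borrow-out wire.

    Callers must guarantee a ≥ b structurally; the borrow wire lets tests
    assert the guarantee actually holds on evaluated inputs.
    """
    if len(a) != len(b):
        raise CircuitError(f"sub width mismatch: {len(a)} vs {len(b)}")
    out, borrow = _sub_words(circ, a.wires, b.wires)
    return WordRef(out), borrow


def mul(circ: Circuit, a: WordRef, b: WordRef) -> WordRef:
    """Shift-and-add product at full (wa+wb)-bit width, no truncation."""
    wa, wb = len(a), len(b)
    acc: list[int] = [circ.and_(bi, ai) for bi in b.wires[:1] for ai in a.wires]
    if not acc:
        raise CircuitError("empty multiplicand")
    for i in range(1, wb):
        pp = [circ.and_(b.wires[i], ai) for ai in a.wires]
        hi = _add_words(circ, acc[i:], pp)
        acc = acc[:i] + hi
    # acc width is wa + wb (last ripple appended a carry); pad if b is 1 bit.
    while len(acc) < wa + wb:
        acc.append(circ.const(0))
    return WordRef(acc[: wa + wb])


def mul_const(circ: Circuit, a: WordRef, c: int) -> WordRef:
    """a × public constant c, as shifted additions over c's set bits."""
    if c < 0:
        raise CircuitError("constant must be unsigned")
    width = len(a) + max(c.bit_length(), 1)
    if c == 0:
        return const_word(circ, 0, width)
    acc: list[int] | None = None
    for i in range(c.bit_length()):
        if (c >> i) & 1:
            shifted = list(a.wires)
            if acc is None:
                acc = shifted
                base = i
            else:
                # align: acc currently holds value/2^base
                off = i - base
                while len(acc) < off:
                    acc.append(circ.const(0))
                if len(acc) == off:
                    # disjoint placement; alias wires (double NOT is free to
                    # garble) so the output word has no duplicate wire ids
                    hi = [circ.not_(circ.not_(w)) for w in shifted]
                else:
                    hi = _add_words(circ, acc[off:], shifted)
                acc = acc[:off] + hi
    lead = [circ.const(0) for _ in range(base)]
    word = lead + acc
    while len(word) < width:
        word.append(circ.const(0))
    return WordRef(word[:width])


def shift_left_const(circ: Circuit, a: WordRef, k: int) -> WordRef:
    """a · 2^k, widening by k zero bits."""
    if k < 0:
        raise CircuitError("negative shift")
    return WordRef([circ.const(0) for _ in range(k)] + list(a.wires))


def less_than(circ: Circuit, a: WordRef, b: WordRef) -> int:
    """Single wire carrying [a < b] (unsigned), via the borrow of a − b."""
    if len(a) != len(b):
        raise CircuitError(f"compare width mismatch: {len(a)} vs {len(b)}")
    borrow: int | None = None
    for ai, bi in zip(a.wires, b.wires):
        u = circ.and_(circ.not_(ai), bi)
        if borrow is None:
            borrow = u
        else:
            v = circ.and_(borrow, circ.not_(circ.xor_(ai, bi)))
            borrow = circ.xor_(u, v)
    return borrow


def select(circ: Circuit, cond: int, a: WordRef, b: WordRef) -> WordRef:
    """cond ? a : b, bitwise multiplexer over equal widths."""
    if len(a) != len(b):
        raise CircuitError(f"select width mismatch: {len(a)} vs {len(b)}")
    out = []
    for ai, bi in zip(a.wires, b.wires):
        t = circ.xor_(ai, bi)
        out.append(circ.xor_(circ.and_(cond, t), bi))
    return WordRef(out)


def is_zero(circ: Circuit, a: WordRef) -> int:
    """Single wire carrying [a == 0]."""
    acc = a.wires[0]
    for w in a.wires[1:]:
        acc = circ.or_(acc, w)
    return circ.not_(acc)


def divmod_(circ: Circuit, num: WordRef, den: WordRef) -> tuple[WordRef, WordRef]:
    """Restoring division: num = q·den + r with 0 ≤ r < den.

    q has num's width, r has den's width.  Division by zero is total but
    sentinel-valued: q = all ones and r = num mod 2^len(den); GWAS circuits
    never reach it (denominators are public totals or expected counts that
    the callers prove nonzero).
    """
    wd = len(den)
    rem: list[int] = []
    qbits_msb_first: list[int] = []
    for bit in reversed(num.wires):
        rem = [bit] + rem  # rem := 2·rem + bit
        if len(rem) > wd + 1:
            raise CircuitError("remainder overflow")  # pragma: no cover
        diff, borrow = _sub_words(circ, rem, den.wires)
        q = circ.not_(borrow)
        keep = min(len(rem), wd)
        sel = select(circ, borrow, WordRef(rem[:keep]), WordRef(diff[:keep]))
        rem = list(sel.wires)
        qbits_msb_first.append(q)
    q_word = WordRef(list(reversed(qbits_msb_first)))
    while len(rem) < wd:
        rem.append(circ.const(0))
    return q_word, WordRef(rem[:wd])


# ---------------------------------------------------------------------------
# evaluation


def _bits_from(value, n: int) -> list[int]:
    if isinstance(value, int):
        if value < 0 or value >= (1 << n) and n > 0:
            raise CircuitError(f"input {value} does not fit in {n} bits")
        return [(value >> i) & 1 for i in range(n)]
    bits = list(value)
    if len(bits) != n:
        raise CircuitError(f"expected {n} input bits, got {len(bits)}")
    return [1 if b else 0 for b in bits]


def evaluate_plain(circ: Circuit, inputs_a, inputs_b) -> dict[str, int]:
    """Gate-by-gate cleartext evaluation; the protocol correctness oracle.

    Inputs are given per party either as unsigned integers (bit i of the
    integer feeds the i-th manifest wire) or as bit sequences.  Returns each
    named output word as an unsigned integer (fixed-point mantissa when the
    output carries a scale).
    """
    if not circ.finalized:
        raise CircuitError("circuit must be finalized before evaluation")
    vals = bytearray(circ.n_wires)
    for w, b in zip(circ.inputs_a, _bits_from(inputs_a, len(circ.inputs_a))):
        vals[w] = b
    for w, b in zip(circ.inputs_b, _bits_from(inputs_b, len(circ.inputs_b))):
        vals[w] = b
    for k, a, b, o in zip(circ.kinds, circ.in1, circ.in2, circ.out):
        if k == AND:
            vals[o] = vals[a] & vals[b]
        elif k == XOR:
            vals[o] = vals[a] ^ vals[b]
        elif k == NOT:
            vals[o] = 1 - vals[a]
        else:  # CONST
            vals[o] = a
    out = {}
    for name, (wires, _scale) in circ.outputs.items():
        v = 0
        for i, w in enumerate(wires):
            v |= vals[w] << i
        out[name] = v
    return out


def evaluate_plain_batch(
    circ: Circuit, inputs_a: np.ndarray, inputs_b: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised plain evaluation of many input vectors at once.

    `inputs_a` / `inputs_b` are boolean arrays of shape (n_cases, n_bits).
    Returns each output as an object array of Python ints (words can exceed
    64 bits).
    """
    if not circ.finalized:
        raise CircuitError("circuit must be finalized before evaluation")
    n = inputs_a.shape[0]
    if inputs_b.shape[0] != n:
        raise CircuitError("batch size mismatch between parties")
    vals = np.zeros((circ.n_wires, n), dtype=bool)
    vals[circ.inputs_a] = np.asarray(inputs_a, dtype=bool).T
    vals[circ.inputs_b] = np.asarray(inputs_b, dtype=bool).T
    for k, a, b, o in zip(circ.kinds, circ.in1, circ.in2, circ.out):
        if k == AND:
            np.logical_and(vals[a], vals[b], out=vals[o])
        elif k == XOR:
            np.logical_xor(vals[a], vals[b], out=vals[o])
        elif k == NOT:
            np.logical_not(vals[a], out=vals[o])
        else:
            vals[o] = bool(a)
    out = {}
    for name, (wires, _scale) in circ.outputs.items():
        acc = np.zeros(n, dtype=object)
        for i, w in enumerate(wires):
            acc += vals[w].astype(object) << i
        out[name] = acc
    return out


# ---------------------------------------------------------------------------
# serialization (line-oriented text, diffable)


def to_text(circ: Circuit) -> str:
    lines = ["fedgwas-circuit v1", f"wires {circ.n_wires}"]
    lines.append("inputs_a " + " ".join(map(str, circ.inputs_a)))
    lines.append("inputs_b " + " ".join(map(str, circ.inputs_b)))
    for name, (wires, scale) in circ.outputs.items():
        lines.append(f"output {name} {scale} " + " ".join(map(str, wires)))
    for k, a, b, o in zip(circ.kinds, circ.in1, circ.in2, circ.out):
        lines.append(f"{KIND_NAMES[k]} {a} {b} {o}")
    return "\n".join(lines) + "\n"


def from_text(text: str) -> Circuit:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "fedgwas-circuit v1":
        raise CircuitError("unrecognized circuit header")
    circ = Circuit()
    outputs = []
    gate_lines = []
    n_wires = 0
    for ln in lines[1:]:
        parts = ln.split()
        if parts[0] == "wires":
            n_wires = int(parts[1])
        elif parts[0] == "inputs_a":
            circ.inputs_a = [int(x) for x in parts[1:]]
        elif parts[0] == "inputs_b":
            circ.inputs_b = [int(x) for x in parts[1:]]
        elif parts[0] == "output":
            outputs.append((parts[1], int(parts[2]), tuple(int(x) for x in parts[3:])))
        elif parts[0] in KIND_IDS:
            gate_lines.append((KIND_IDS[parts[0]], int(parts[1]), int(parts[2]), int(parts[3])))
        else:
            raise CircuitError(f"unrecognized line: {ln!r}")
    for k, a, b, o in gate_lines:
        circ.kinds.append(k)
        circ.in1.append(a)
        circ.in2.append(b)
        circ.out.append(o)
    circ.n_wires = n_wires
    for name, scale, wires in outputs:
        circ.outputs[name] = (wires, scale)
    return circ.finalize()
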