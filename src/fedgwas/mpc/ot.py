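"""Semi-honest 1-out-of-2 oblivious transfer, Naor-Pinkas style.

Group: the 2048-bit MODP group of RFC 3526 (group 14), generator 2, with
256-bit exponents.  Per batch the sender publishes a random group element C
(discrete log unknown to the receiver) and a single blinding element u = g^r;
for choice bit b the receiver sets PK_b = g^k and PK_{1-b} = C / PK_b and
reveals PK_0, so the sender can encrypt m_j under H(PK_j^r) while the receiver
can only unblind its chosen message via u^k.  Reusing one r across a batch is
sound against honest-but-curious parties (each unchosen key still requires
C^r, a CDH instance); the malicious model is explicitly out of scope.

One OT transfers one 16-byte wire label per evaluator input bit.
"""

from __future__ import annotations

import hashlib

from .garble import LABEL_BYTES, RandomSource

# RFC 3526, 2048-bit MODP group (id 14)
MODP_2048 = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)
GENERATOR = 2
EXPONENT_BITS = 256
ELEM_BYTES = (MODP_2048.bit_length() + 7) // 8


class OTError(RuntimeError):
    pass


def _h(elem: int, index: int, bit: int, n_bytes: int) -> int:
    d = hashlib.sha256(
        elem.to_bytes(ELEM_BYTES, "big")
        + index.to_bytes(4, "big")
        + bytes([bit])
    ).digest()[:n_bytes]
    return int.from_bytes(d, "big")


def _check_elem(x: int) -> int:
    if not 1 <= x < MODP_2048:
        raise OTError("malformed group element")
    return x


class OTSender:
    """Holds the two messages of each transfer; never learns the choices."""

    def __init__(self, message_pairs: list[tuple[bytes, bytes]], rng: RandomSource):
        for m0, m1 in message_pairs:
            if len(m0) != len(m1):
                raise OTError("message pair lengths differ")
            if len(m0) > 32:
                raise OTError("messages longer than the hash output")
        self.pairs = message_pairs
        p = MODP_2048
        self._c = pow(GENERATOR, rng.randint_bits(EXPONENT_BITS), p)
        r = rng.randint_bits(EXPONENT_BITS)
        self._u = pow(GENERATOR, r, p)
        self._c_r = pow(self._c, r, p)
        self._r = r

    def setup(self) -> tuple[int, int]:
        """(C, u = g^r): broadcast once per batch."""
        return self._c, self._u

    def respond(self, pk0s: list[int]) -> list[tuple[int, int]]:
        """Encrypt both messages of every pair against the received PK_0 list."""
        if len(pk0s) != len(self.pairs):
            raise OTError(f"expected {len(self.pairs)} public keys, got {len(pk0s)}")
        p = MODP_2048
        out = []
        for i, (pk0, (m0, m1)) in enumerate(zip(pk0s, self.pairs)):
            pk0_r = pow(_check_elem(pk0), self._r, p)
            pk1_r = self._c_r * pow(pk0_r, -1, p) % p
            n = len(m0)
            v0 = _h(pk0_r, i, 0, n) ^ int.from_bytes(m0, "big")
            v1 = _h(pk1_r, i, 1, n) ^ int.from_bytes(m1, "big")
            out.append((v0, v1))
        return out


class OTReceiver:
    """Obtains exactly message[choice] per transfer; choices stay hidden."""

    def __init__(self, choices: list[int], rng: RandomSource):
        self.choices = [1 if c else 0 for c in choices]
        self._rng = rng
        self._ks: list[int] = []

    def pk0s(self, c: int, u: int) -> list[int]:
        p = MODP_2048
        _check_elem(c)
        self._u = _check_elem(u)
        out = []
        for b in self.choices:
            k = self._rng.randint_bits(EXPONENT_BITS)
            self._ks.append(k)
            pk_b = pow(GENERATOR, k, p)
            pk0 = pk_b if b == 0 else c * pow(pk_b, -1, p) % p
            out.append(pk0)
        return out

    def decrypt(self, responses: list[tuple[int, int]], n_bytes: int = LABEL_BYTES) -> list[bytes]:
        if len(responses) != len(self.choices):
            raise OTError("response count mismatch")
        p = MODP_2048
        out = []
        for i, (b, k, (v0, v1)) in enumerate(zip(self.choices, self._ks, responses)):
            key = pow(self._u, k, p)
            v = v1 if b else v0
            m = _h(key, i, b, n_bytes) ^ v
            out.append(m.to_bytes(n_bytes, "big"))
        return out


def ot_transfer_local(
    message_pairs: list[tuple[bytes, bytes]],
    choices: list[int],
    rng_sender: RandomSource,
    rng_receiver: RandomSource,
) -> list[bytes]:
    """Run the whole batched protocol in-process (tests and simulate mode)."""
    sender = OTSender(message_pairs, rng_sender)
    receiver = OTReceiver(choices, rng_receiver)
    c, u = sender.setup()
    resp = sender.respond(receiver.pk0s(c, u))
    return receiver.decrypt(resp, len(message_pairs[0][0]) if message_pairs else LABEL_BYTES)
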