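"""Bit-packing of private counts into hex input blocks, and fixed-point decode.

The secure runtime consumes hexadecimal input files of at most 8,000 bits.
One genotype costs a 32-bit word per party: the high-order 16 bits carry the
case group's low-allele count, the low-order 16 bits the control group's, so a
block holds at most 8000/32 = 250 genotypes.  Only the lexicographically-low
allele's count travels; the high count is reconstructed in-circuit as
TOTAL − low, TOTAL being a public per-study constant.

Fixed-point outputs are unsigned mantissas with an implicit 2^-FPP scale
(FPP = 16 by default); :func:`decode_fixed_point` renders them as exact,
losslessly re-parseable decimal strings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction

from .snp_io import AlleleCountTable, StudyMetadata, StudyError

BLOCK_BITS = 8_000
WORD_BITS = 32
FIELD_BITS = 16
GENOTYPES_PER_BLOCK = BLOCK_BITS // WORD_BITS  # 250
DEFAULT_FPP = 16

# the <=2^15-participant assumption: per-party, per-group counts stay below
# 2^15 copies so each 16-bit field never approaches overflow
MAX_FIELD = 1 << 15


class EncodingError(ValueError):
    """Count overflow, malformed hex, or metadata/count inconsistency."""


@dataclass(frozen=True)
class CountWord:
    """One genotype's 32-bit input word for one party."""

    case_low: int
    control_low: int

    def __post_init__(self):
        for name, v in (("case", self.case_low), ("control", self.control_low)):
            if not 0 <= v < MAX_FIELD:
                raise EncodingError(
                    f"{name} count {v} outside [0, 2^15): "
                    "more than 2^15 participants is unsupported"
                )

    @property
    def value(self) -> int:
        return (self.case_low << FIELD_BITS) | self.control_low


@dataclass(frozen=True)
class PackedBlock:
    """Up to 250 genotypes' count words; one 8,000-bit hex input unit."""

    index: int
    words: tuple[CountWord, ...]

    def __post_init__(self):
        if not 0 < len(self.words) <= GENOTYPES_PER_BLOCK:
            raise EncodingError(
                f"block {self.index}: {len(self.words)} genotypes exceeds "
                f"{GENOTYPES_PER_BLOCK}"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.words)

    @property
    def bit_length(self) -> int:
        return WORD_BITS * len(self.words)

    def to_hex(self) -> str:
        """Lowercase hex; first genotype in the leftmost 8 characters."""
        return "".join(f"{w.value:08x}" for w in self.words)


def unpack_block(hex_text: str, index: int = 0) -> PackedBlock:
    """Inverse of :meth:`PackedBlock.to_hex`; case-insensitive on read."""
    text = hex_text.strip()
    if not re.fullmatch(r"[0-9a-fA-F]+", text or " "):
        raise EncodingError("block is not valid hexadecimal")
    if len(text) % (WORD_BITS // 4) != 0:
        raise EncodingError(
            f"hex length {len(text)} is not a multiple of {WORD_BITS // 4}"
        )
    if len(text) * 4 > BLOCK_BITS:
        raise EncodingError(f"block exceeds {BLOCK_BITS} bits")
    words = []
    for i in range(0, len(text), 8):
        v = int(text[i : i + 8], 16)
        words.append(CountWord(v >> FIELD_BITS, v & (MAX_FIELD * 2 - 1)))
    return PackedBlock(index, tuple(words))


def unpack_counts(block: PackedBlock) -> list[tuple[int, int]]:
    """Per genotype (case_low_count, control_low_count)."""
    return [(w.case_low, w.control_low) for w in block.words]


@dataclass(frozen=True)
class BlockPlan:
    """How a study's genotypes are partitioned into fixed-size input blocks."""

    n_genotypes: int
    padded_n: int

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.padded_n / GENOTYPES_PER_BLOCK)

    @property
    def block_sizes(self) -> list[int]:
        full, last = divmod(self.padded_n, GENOTYPES_PER_BLOCK)
        return [GENOTYPES_PER_BLOCK] * full + ([last] if last else [])


def padded_block_plan(n_genotypes: int, pad_to: int | None = None) -> BlockPlan:
    """Block layout, optionally padded to a fixed public upper bound.

    Padding to the least upper bound of all of an institution's datasets makes
    every run consume the same circuit and the same time, hiding the true
    genotype count; the padding words are zero-count placeholders whose
    outputs are discarded.
    """
    if n_genotypes <= 0:
        raise EncodingError("study has no genotypes")
    if pad_to is not None and pad_to < n_genotypes:
        raise EncodingError(
            f"padding bound {pad_to} is below the actual genotype count {n_genotypes}"
        )
    return BlockPlan(n_genotypes, pad_to if pad_to is not None else n_genotypes)


def pack_counts(
    case_counts: AlleleCountTable,
    control_counts: AlleleCountTable,
    meta: StudyMetadata,
    pad_to: int | None = None,
    block_genotypes: int = GENOTYPES_PER_BLOCK,
) -> list[PackedBlock]:
    """Pack one institution's private low-allele counts into input blocks.

    Word order follows the metadata locus order exactly, within and across
    blocks.  `block_genotypes` may be lowered (never raised) for testing or
    memory control.
    """
    if not 0 < block_genotypes <= GENOTYPES_PER_BLOCK:
        raise EncodingError(
            f"block capacity must be in [1, {GENOTYPES_PER_BLOCK}]"
        )
    words = []
    for locus in meta.loci:
        if locus not in case_counts.counts or locus not in control_counts.counts:
            raise EncodingError(f"locus {locus!r} in metadata but not in counts")
        low = meta.low_allele(locus)
        words.append(
            CountWord(case_counts.count(locus, low), control_counts.count(locus, low))
        )
    n_pad = (pad_to - len(words)) if pad_to is not None else 0
    if n_pad < 0:
        raise EncodingError("padding bound below genotype count")
    words.extend(CountWord(0, 0) for _ in range(n_pad))
    blocks = []
    for i in range(0, len(words), block_genotypes):
        blocks.append(PackedBlock(i // block_genotypes, tuple(words[i : i + block_genotypes])))
    return blocks


# ---------------------------------------------------------------------------
# fixed point


@dataclass(frozen=True)
class FixedPointValue:
    """Unsigned mantissa with implicit scale 2^-fpp."""

    mantissa: int
    fpp: int = DEFAULT_FPP

    def __post_init__(self):
        if self.mantissa < 0 or self.fpp < 0:
            raise EncodingError("fixed-point values are unsigned")

    def as_fraction(self) -> Fraction:
        return Fraction(self.mantissa, 1 << self.fpp)

    def __float__(self) -> float:
        return self.mantissa / (1 << self.fpp)

    def decode(self) -> str:
        return decode_fixed_point(self.mantissa, self.fpp)


def decode_fixed_point(mantissa: int, fpp: int) -> str:
    """Exact decimal rendering of mantissa / 2^fpp, trailing zeros trimmed.

    2^-fpp has a finite decimal expansion, so the rendering is lossless:
    re-parsing and re-encoding at the same fpp returns the mantissa exactly.
    """
    if mantissa < 0 or fpp < 0:
        raise EncodingError("fixed-point values are unsigned")
    whole, frac = divmod(mantissa, 1 << fpp)
    if frac == 0:
        return str(whole)
    digits = str(frac * 5**fpp).rjust(fpp, "0").rstrip("0")
    return f"{whole}.{digits}"


def encode_fixed_point(text: str, fpp: int) -> int:
    """Parse a decimal string back to its mantissa (inverse of decode).

    Exact only for values representable at scale 2^-fpp (which all decoded
    outputs are); otherwise rounds toward zero.
    """
    frac = Fraction(text)
    if frac < 0:
        raise EncodingError("fixed-point values are unsigned")
    return int(frac * (1 << fpp))
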