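"""Per-block MAF and chi-square boolean circuits over the packed count words.

Each genotype is an independent sub-circuit (no cross-genotype wires, which is
what makes block-level parallelism sound).  Per genotype and group, the two
parties' private low-allele counts x and y are aggregated in-circuit:

    lowCt  = x + y
    highCt = TOTAL - lowCt          (TOTAL is a public compile-time constant)
    minCt  = min(lowCt, highCt)
    MAF    = floor(minCt * 2^fpp / TOTAL)

The chi-square circuit aggregates the full 2x2 allele-count table the same
way, forms fixed-point expected counts exp[j] = floor(row_j * col_j * 2^fpp
/ N), and accumulates floor((obsFP^2 + expFP^2 - 2*obsFP*expFP) / expFP) per
cell — the squared difference is expanded so that every intermediate stays
unsigned (obsFP^2 + expFP^2 >= 2*obsFP*expFP by AM-GM).  Products are kept at
full width; only the final quotient carries scale fpp.

Input words are truncated to bit_length(group total) wires per field: the
totals are public, counts never exceed them, and the narrower words roughly
halve both the circuit and the oblivious-transfer work.
"""

from __future__ import annotations

from .circuit import (
    Circuit,
    WordRef,
    _add_words,
    add,
    const_word,
    divmod_,
    is_zero,
    less_than,
    mul,
    mul_const,
    select,
    shift_left_const,
    sub_nonneg,
)
from .encoding import DEFAULT_FPP, GENOTYPES_PER_BLOCK, PackedBlock
from .snp_io import StudyMetadata

# re-exported reference implementation of the expected-count formula
from .oracles import expected_count_mantissas  # noqa: F401


class GwasCircuitError(ValueError):
    pass


def input_field_widths(meta: StudyMetadata) -> tuple[int, int]:
    """(case, control) input field widths in wires: bit_length of each total."""
    return meta.total_case.bit_length(), meta.total_control.bit_length()


def block_input_value(block: PackedBlock, meta: StudyMetadata) -> int:
    """One party's manifest-ordered input bits for a block, as an integer.

    Manifest layout per genotype: case field (LSB first), then control field.
    Bit i of the returned integer feeds the i-th manifest wire.
    """
    w_case, w_ctrl = input_field_widths(meta)
    val = 0
    pos = 0
    for word in block.words:
        if word.case_low >= (1 << w_case) or word.control_low >= (1 << w_ctrl):
            raise GwasCircuitError(
                "count exceeds the public group total; cannot bind to circuit"
            )
        val |= word.case_low << pos
        pos += w_case
        val |= word.control_low << pos
        pos += w_ctrl
    return val


def _check_meta(n_genotypes: int, meta: StudyMetadata) -> None:
    if not 0 < n_genotypes <= GENOTYPES_PER_BLOCK:
        raise GwasCircuitError(
            f"genotypes per block must be in [1, {GENOTYPES_PER_BLOCK}]"
        )
    if meta.total_case <= 0 or meta.total_control <= 0:
        raise GwasCircuitError("group totals must be positive")


def _genotype_inputs(circ: Circuit, meta: StudyMetadata):
    w_case, w_ctrl = input_field_widths(meta)
    xa_case = circ.new_input_word("A", w_case)
    xa_ctrl = circ.new_input_word("A", w_ctrl)
    xb_case = circ.new_input_word("B", w_case)
    xb_ctrl = circ.new_input_word("B", w_ctrl)
    return (xa_case, xb_case), (xa_ctrl, xb_ctrl)


def build_maf_circuit(
    n_genotypes: int,
    meta: StudyMetadata,
    fpp: int = DEFAULT_FPP,
    expose_borrows: bool = False,
) -> Circuit:
    """Block circuit emitting maf_case/<i> and maf_control/<i> mantissas.

    Output mantissas are fpp bits wide: a minor-allele frequency is at most
    1/2, so floor(minCt * 2^fpp / TOTAL) <= 2^(fpp-1).
    """
    _check_meta(n_genotypes, meta)
    if fpp < 1:
        raise GwasCircuitError("fpp must be >= 1")
    circ = Circuit()
    for i in range(n_genotypes):
        case_xy, ctrl_xy = _genotype_inputs(circ, meta)
        for group, (x, y), total in (
            ("case", case_xy, meta.total_case),
            ("control", ctrl_xy, meta.total_control),
        ):
            low_ct = add(circ, x, y)  # width w+1
            total_w = const_word(circ, total, len(low_ct))
            high_ct, borrow = sub_nonneg(circ, total_w, low_ct)
            if expose_borrows:
                circ.add_output(f"borrow_{group}/{i}", WordRef([borrow]))
            lt = less_than(circ, low_ct, high_ct)
            min_ct = select(circ, lt, low_ct, high_ct)
            dividend = shift_left_const(circ, min_ct, fpp)
            q, _r = divmod_(circ, dividend, total_w)
            circ.add_output(f"maf_{group}/{i}", q[:fpp], scale=fpp)
    return circ.finalize()


def build_chi2_circuit(
    n_genotypes: int,
    meta: StudyMetadata,
    fpp: int = DEFAULT_FPP,
    expose_borrows: bool = False,
) -> Circuit:
    """Block circuit emitting chi2/<i> mantissas plus chi2_degenerate/<i> flags.

    A genotype whose pooled table has an empty allele column is degenerate:
    it carries no association signal, so the statistic is forced to 0 and the
    flag raised (rather than emitting the division-by-zero sentinel).
    """
    _check_meta(n_genotypes, meta)
    if fpp < 1:
        raise GwasCircuitError("fpp must be >= 1")
    n_total = meta.total_case + meta.total_control
    if (min(meta.total_case, meta.total_control) << fpp) < n_total:
        raise GwasCircuitError(
            f"fpp={fpp} cannot resolve expected counts for N={n_total}"
        )
    circ = Circuit()
    rows = (meta.total_case, meta.total_control)
    for i in range(n_genotypes):
        case_xy, ctrl_xy = _genotype_inputs(circ, meta)
        obs = []
        borrows = []
        for (x, y), total in ((case_xy, rows[0]), (ctrl_xy, rows[1])):
            low = add(circ, x, y)
            high, b = sub_nonneg(circ, const_word(circ, total, len(low)), low)
            obs.extend([low, high])
            borrows.append(b)
        col_low = WordRef(_add_words(circ, obs[0].wires, obs[2].wires))
        col_high = WordRef(_add_words(circ, obs[1].wires, obs[3].wires))
        cols = (col_low, col_high)
        n_word = const_word(circ, n_total, n_total.bit_length())

        terms = []
        for j, ob in enumerate(obs):
            row_c = rows[j // 2]
            col = cols[j % 2]
            prod = mul_const(circ, col, row_c)
            exp_q, _ = divmod_(circ, shift_left_const(circ, prod, fpp), n_word)
            exp_fp = exp_q[: row_c.bit_length() + fpp]  # exp[j] <= row_j
            obs_fp = shift_left_const(circ, ob, fpp)
            w = max(len(exp_fp), len(obs_fp))
            a = _pad(circ, obs_fp, w)
            e = _pad(circ, exp_fp, w)
            p1 = mul(circ, a, a)
            p2 = mul(circ, e, e)
            p3 = shift_left_const(circ, mul(circ, a, e), 1)  # 2*obsFP*expFP
            s = add(circ, p1, p2)
            num, b = sub_nonneg(circ, s, _pad(circ, p3, len(s)))
            borrows.append(b)
            term_q, _ = divmod_(circ, num, e)
            terms.append(term_q)

        acc = terms[0].wires
        for t in terms[1:]:
            acc = _add_words(circ, acc, t.wires)
        chi2 = WordRef(acc)
        deg = circ.or_(is_zero(circ, col_low), is_zero(circ, col_high))
        masked = select(circ, deg, const_word(circ, 0, len(chi2)), chi2)
        circ.add_output(f"chi2/{i}", masked, scale=fpp)
        circ.add_output(f"chi2_degenerate/{i}", WordRef([deg]))
        if expose_borrows:
            for k, b in enumerate(borrows):
                circ.add_output(f"borrow_{k}/{i}", WordRef([b]))
    return circ.finalize()


def _pad(circ: Circuit, word: WordRef, width: int) -> WordRef:
    if len(word) > width:
        raise GwasCircuitError("cannot pad downward")
    if len(word) == width:
        return word
    return WordRef(list(word.wires) + [circ.const(0) for _ in range(width - len(word))])
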