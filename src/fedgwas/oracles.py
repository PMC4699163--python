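"""Cleartext reference implementations of the two statistics.

Two layers of oracle live here:

* exact fixed-point mirrors (:func:`cleartext_maf`, :func:`cleartext_chi2`)
  that replicate the circuits' unsigned integer arithmetic decision for
  decision — same floor points, same widths — so circuit evaluation can be
  checked bit for bit;
* real-arithmetic references (:func:`float_chi2`, exact rationals) for
  quantifying the fixed-point truncation error.

The chi-square here is the allelic 2x2 test statistic without continuity
correction: rows are case/control groups, columns the two alleles, expected
counts the standard row_total * col_total / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .encoding import DEFAULT_FPP, FixedPointValue


class OracleError(ValueError):
    pass


def cleartext_maf(
    low_count: int, total: int, fpp: int = DEFAULT_FPP
) -> tuple[FixedPointValue, Fraction]:
    """Minor allele frequency of one group: fixed-point mantissa and exact rational.

    The minor count is min(low, total - low); the mantissa is
    floor(min * 2^fpp / total), exactly what the circuit computes.
    """
    if total <= 0:
        raise OracleError("group total must be positive")
    if not 0 <= low_count <= total:
        raise OracleError(f"low-allele count {low_count} outside [0, {total}]")
    minor = min(low_count, total - low_count)
    mantissa = (minor << fpp) // total
    return FixedPointValue(mantissa, fpp), Fraction(minor, total)


def expected_count_mantissas(
    obs: tuple[int, int, int, int], fpp: int = DEFAULT_FPP
) -> list[int]:
    """Fixed-point expected counts exp[j] = floor(row * col * 2^fpp / N).

    obs = (case_low, case_high, control_low, control_high) allele copies.
    """
    row = (obs[0] + obs[1], obs[2] + obs[3])
    col = (obs[0] + obs[2], obs[1] + obs[3])
    n = sum(obs)
    if n == 0:
        raise OracleError("empty contingency table")
    return [
        (row[0] * col[0] << fpp) // n,
        (row[0] * col[1] << fpp) // n,
        (row[1] * col[0] << fpp) // n,
        (row[1] * col[1] << fpp) // n,
    ]


@dataclass(frozen=True)
class Chi2Result:
    value: FixedPointValue
    degenerate: bool  # a pooled allele column was empty; statistic reported 0


def cleartext_chi2(
    obs: tuple[int, int, int, int],
    totals: tuple[int, int],
    fpp: int = DEFAULT_FPP,
) -> Chi2Result:
    """Fixed-point chi-square mirroring the circuit's arithmetic exactly.

    Per cell, with obsFP = obs * 2^fpp and expFP the floored fixed-point
    expected count, the term is floor((obsFP^2 + expFP^2 - 2 obsFP expFP) /
    expFP); the AM-GM inequality keeps the unsigned numerator non-negative.
    A monomorphic pooled column makes the table degenerate: the statistic
    carries no association signal and is reported as 0 with a flag.
    """
    total_case, total_control = totals
    if obs[0] + obs[1] != total_case or obs[2] + obs[3] != total_control:
        raise OracleError("observed counts do not match group totals")
    if total_case <= 0 or total_control <= 0:
        raise OracleError("group totals must be positive")
    col_low, col_high = obs[0] + obs[2], obs[1] + obs[3]
    if col_low == 0 or col_high == 0:
        return Chi2Result(FixedPointValue(0, fpp), True)
    exps = expected_count_mantissas(obs, fpp)
    acc = 0
    for o, e in zip(obs, exps):
        ofp = o << fpp
        num = ofp * ofp + e * e - 2 * ofp * e  # == (ofp - e)^2, all unsigned
        acc += num // e
    return Chi2Result(FixedPointValue(acc, fpp), False)


def rational_chi2(obs: tuple[int, int, int, int]) -> Fraction:
    """Exact chi-square of the 2x2 allele-count table."""
    row = (obs[0] + obs[1], obs[2] + obs[3])
    col = (obs[0] + obs[2], obs[1] + obs[3])
    n = sum(obs)
    if n == 0:
        raise OracleError("empty contingency table")
    if 0 in col or 0 in row:
        return Fraction(0)
    acc = Fraction(0)
    for i in range(2):
        for j in range(2):
            exp = Fraction(row[i] * col[j], n)
            d = Fraction(obs[2 * i + j]) - exp
            acc += d * d / exp
    return acc


def float_chi2(obs: tuple[int, int, int, int]) -> float:
    """Floating-point chi-square (no continuity correction)."""
    return float(rational_chi2(obs))


def chi2_error_bound(
    obs: tuple[int, int, int, int], fpp: int = DEFAULT_FPP
) -> Fraction:
    """Bound on |decoded fixed-point chi2 - exact chi2| for this table.

    Per cell, with E = exp * 2^fpp (real) and E' = floor(E) >= E - 1 the
    stored expected mantissa, D = (obs - exp) * 2^fpp:

        |term/2^fpp - cell|  <=  2^-fpp * (1 + (2|D| + 1)/E' + D^2 / (E * E'))

    (one ulp from the final floor, the rest from the floored expected count).
    Dominated by (cell_chi2 * 2^fpp) / E' for skewed tables, so the bound
    grows when an expected count is tiny relative to 2^-fpp.
    """
    row = (obs[0] + obs[1], obs[2] + obs[3])
    col = (obs[0] + obs[2], obs[1] + obs[3])
    n = sum(obs)
    if 0 in col:
        return Fraction(0)  # degenerate: both sides report exactly 0
    scale = 1 << fpp
    bound = Fraction(0)
    for i in range(2):
        for j in range(2):
            exp = Fraction(row[i] * col[j], n)
            e_real = exp * scale
            e_floor = (row[i] * col[j] << fpp) // n
            if e_floor == 0:
                raise OracleError(
                    f"expected count {float(exp):g} under-resolved at fpp={fpp}"
                )
            d = abs(Fraction(obs[2 * i + j]) - exp) * scale
            bound += Fraction(1, scale) * (
                1 + Fraction(2 * d + 1, e_floor) + d * d / (e_real * e_floor)
            )
    return bound
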