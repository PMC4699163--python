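# Methods

## Setting and statistics

Two institutions hold disjoint sets of individuals, each genotyped at the same
loci and partitioned into case and control groups. For a biallelic locus with
alleles (low, high) — ordered lexicographically, e.g. 'A' < 'G' — and a group
with `TOTAL` allele copies (2 × individuals), the statistics are:

* **Minor allele frequency.** With pooled low-allele count
  `lowCt = x + y` (x, y the two institutions' private counts),
  `highCt = TOTAL − lowCt`, `minCt = min(lowCt, highCt)`,
  `MAF = minCt / TOTAL ∈ [0, 0.5]`, reported separately per group.
* **Allelic χ².** Over the 2×2 table obs = (case-low, case-high,
  control-low, control-high) with row totals the public group totals, column
  totals the pooled per-allele counts, and N = total_case + total_control:
  `exp_ij = row_i · col_j / N`, `χ² = Σ (obs_ij − exp_ij)² / exp_ij`.
  The expected-count formula is the standard contingency expectation; both
  marginals depend on both parties' private counts, so the expected counts
  are computed inside the circuit, not locally. No continuity correction is
  applied, and no p-values are derived — the raw statistic is the output.

Row totals, locus list and order, allele pairs, group sizes, and the genotype
count are treated as public study metadata; only the per-locus counts are
private. This is a deliberate trade: the circuit's shape necessarily reveals
the study dimensions, and an institution unwilling to reveal its genotype
count can pad the block plan to a fixed public upper bound
(`padded_block_plan`), making every run identical in size and time.

## Fixed-point arithmetic in boolean circuits

The circuits use only unsigned integers. Fractions are unsigned fixed point
with FPP fractional bits (default 16): division becomes
`floor(numerator · 2^FPP / denominator)` via a left shift of the dividend.
Negative intermediates are impossible by construction: the χ² numerator is
expanded as `(obs−exp)² = obs² + exp² − 2·obs·exp`, whose subtraction is safe
by the AM–GM inequality; the subtraction borrow wires can be exposed
(`expose_borrows=True`) and are property-tested to be identically zero.

Widths are sized from the public totals: each party's per-group input field
occupies `bit_length(group total)` wires (counts never exceed the public
total), products are kept at full width, and fixed-point dividends carry
`width + FPP` bits. Division is restoring (bit-exact floor semantics);
division by zero is total but sentinel-valued (all-ones quotient) and is
unreachable from the statistic circuits — a pooled monomorphic column is
detected in-circuit and forces the χ² output to 0 with a per-genotype
`degenerate` flag, since such a locus carries no association signal. Ties in
the MAF comparison (`lowCt = highCt`) select either branch; both decode to
exactly 0.5. The MAF output word is FPP bits wide (a minor-allele frequency
mantissa is at most 2^(FPP−1)).

`build_chi2_circuit` requires `min(total) · 2^FPP ≥ N` so that every non-empty
column has a nonzero expected-count mantissa; at FPP = 16 this admits any
study with up to ~32k copies per group, consistent with the 16-bit input
fields (counts are capped below 2^15 copies at pack time, failing loudly
rather than wrapping).

### Truncation error

Writing E = exp·2^FPP, E′ = ⌊E⌋ and D = (obs − exp)·2^FPP for one cell, the
decoded per-cell error against real arithmetic is bounded by

    2^−FPP · ( 1 + (2|D| + 1)/E′ + D²/(E·E′) )

(one ulp from the final floor, the rest from flooring the expected count);
the total bound is the sum over the four cells (`oracles.chi2_error_bound`,
computed in exact rational arithmetic). The bound degrades as an expected
count approaches 2^−FPP — skewed tables with near-empty columns — and is a
few times 10⁻⁴ for well-populated tables at FPP = 16. Tests verify it on
thousands of random tables; the maximally skewed 20-copy table
(10,0)/(0,10) is exact: χ² = 20.0 with zero truncation.

The cleartext oracle (`oracles.cleartext_maf` / `cleartext_chi2`) replicates
the circuit's arithmetic decision for decision — same floor points, same
expansion — so circuit evaluation is checked against it bit for bit, while
`rational_chi2` / `float_chi2` provide the real-arithmetic reference
(cross-checked against `scipy.stats.chi2_contingency(correction=False)` in
tests).

## Input encoding

One genotype costs one 32-bit word per party: high 16 bits = case-group
low-allele count, low 16 bits = control-group count. Blocks hold at most
8,000 bits = 250 genotypes, rendered as fixed-case hexadecimal (first genotype
leftmost, big-endian within each word; the convention is arbitrary but
round-trip-tested). Only the low-allele count travels — the high count is
`TOTAL − low` in-circuit — halving input size. Genotype order within and
across blocks follows the reconciled metadata locus order.

Metadata reconciliation is this package's construction (the two sites must
agree on locus order and allele identity somehow): the merged locus list
follows the generator's order restricted to the shared loci, allele sets are
unioned (more than two alleles is a hard error, as is any missing/ambiguous
call — the compile-time `TOTAL` constant must be exact), and group totals are
summed. A locus monomorphic in the pooled data gets a zero-count sentinel
second allele so the block layout stays uniform; it reports MAF 0 and
degenerate χ² 0.

## Protocol

Classic Yao garbling with point-and-permute: 128-bit wire labels whose last
bit is the public point bit, four-row tables per binary gate ordered by the
input point bits, `ct = SHA-256(label_a ‖ label_b ‖ gate_id) ⊕ (label ‖ 0¹⁶)`,
authenticated by the zero padding (a wrong row fails loudly). There is no
free-XOR, half-gate or row reduction — correctness and auditability first;
the gate basis is {AND, XOR, NOT, CONST} with OR desugared, NOT garbled free
by swapping the label pair, and CONST wires published as their active label.

Evaluator input labels travel by semi-honest Naor–Pinkas-style 1-out-of-2
oblivious transfer over the RFC 3526 2048-bit MODP group with 256-bit
exponents, one OT per evaluator input bit, batched into three messages with a
shared blinding element per batch (sound in the semi-honest model; each
unchosen message still requires a CDH instance).

The generator decodes the returned output labels and shares the plaintext
with the evaluator, so both parties end with the statistics; the plaintext
message uses fixed-width words so every message size in the transcript
depends only on the public circuit shape, never on count values — asserted by
tests that compare transcript shapes across different private inputs.

Protocol randomness comes from OS entropy by default; a seeded source (which
logs an explicit not-secure warning) makes garbling, OT, and hence whole
transcripts byte-reproducible for tests and audits. Per-block seeds are
derived from the master seed and block index, so results are independent of
worker scheduling.

Out of scope by design: more than two parties, malicious or covert security
(cut-and-choose), OT extension, and garbling-aware circuit optimizations.

## Parallelism

Per-genotype outputs are independent sub-circuits with no cross-genotype
wires, so blocks are embarrassingly parallel: one session per block, at most
`workers` concurrent (default 2 × detected cores, the queueing rule that
saturates commodity hardware without thrashing), merged outputs in global
genotype order regardless of completion order, and whole-run failure naming
the first failing block. Simulate mode multiplexes both roles over in-process
loopback queues; real runs use length-prefixed TCP frames, block sessions in
sequence over one connection.

## Synthetic data generator

The generator emulates a two-institution case/control study: by default 100
case and 100 control individuals per institution (400 allele copies per
pooled group) and 311 biallelic loci — the reference layout used throughout —
with population minor-allele frequency drawn uniformly from [0.05, 0.5],
Hardy–Weinberg sampling (each individual's two allele copies i.i.d.
Bernoulli), and 10% of loci "associated" via a +0.10 additive shift of the
case-group minor-allele frequency (clamped to [0, 1]). The frequency range
and effect size are chosen as a realistic common-variant scenario: shifts of
this size at these frequencies are comfortably detectable at N = 800 copies
without saturating the statistic. Ground truth (true frequencies, exact drawn
counts, association flags) is emitted as TSV beside the four SNP files.

The generator deliberately omits linkage disequilibrium, population
stratification, relatedness, missingness, and genotyping error. Passing
end-to-end tests therefore demonstrates that the secure pipeline computes
exactly what a centralized analysis of the same counts would — not that the
χ² statistic is robust to real-data pathologies, which is a property of the
statistic, not of the protocol.

## Problem sizes used by the test suite

Unit and property tests run circuits at small public totals (tens of copies)
where a block is thousands to tens of thousands of gates. The end-to-end
acceptance test uses the default group layout (100/100/100/100 individuals)
at 50 loci with a 13-genotype block capacity, so the multi-block merge and
the 1-vs-4 worker paths are genuinely exercised (~5.5M garbled gates per χ²
run); garbled-vs-plain equivalence is checked on 1,000 random count tables
per statistic by garbling one full block and evaluating it repeatedly. These
sizes were chosen so the whole suite completes in minutes on one CPU while
still covering full-width (FPP = 16) arithmetic; nothing in the construction
is specific to them, and block capacity 250 with thousands of loci runs the
same code path.

## Known limitations

* Two parties only; the block protocol would need a different MPC substrate
  for three or more sites.
* Semi-honest security: a malicious generator could garble a wrong circuit
  undetected (output-label authentication catches corruption, not a
  dishonestly constructed circuit).
* Garbled tables for χ² are large (≈128 bytes per gate, ~10⁵ gates per
  genotype at 400-copy groups); communication is the practical bottleneck,
  and χ² transcripts are consistently several times MAF transcripts at equal
  genotype count.
* The SNP text dialect is the only ingestion format (no VCF/PLINK); no
  quality filtering, HWE checks, or imputation — inputs are taken as given.
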