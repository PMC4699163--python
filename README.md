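# fedgwas

Privacy-preserving two-party GWAS statistics over Yao garbled circuits.

Two institutions each hold case/control SNP genotypes that privacy law and
data-use agreements prevent them from pooling in the clear. `fedgwas` lets
them jointly compute, per locus,

* the **minor allele frequency** (MAF) of each group, and
* the allelic **χ² association statistic**
  χ² = Σᵢⱼ (obsᵢⱼ − expᵢⱼ)² / expᵢⱼ over the 2×2 table of
  group (case/control) × allele counts, with expᵢⱼ = rowᵢ·colⱼ/N,

without either party revealing its per-locus allele counts. Allele counting
is local; only the cross-institution aggregation and the statistics run inside
the secure protocol. The threat model is semi-honest (honest-but-curious):
parties follow the protocol but may inspect everything they receive.

## How it works

1. **Preprocess (local).** Each institution parses its case and control SNP
   text files (alternating rsID / genotype-call lines) and counts allele
   copies per locus. Locus ids, allele pairs, and group sizes become shared
   public metadata; the counts stay private.
2. **Pack (local).** Per genotype, the count of the lexicographically lower
   allele for the case and control groups fills one 32-bit word (16 bits per
   group). Words are packed into hexadecimal input blocks of at most 8,000
   bits — 250 genotypes per block; a 9,330-genotype study becomes 38 blocks.
   The higher allele's count is reconstructed in-circuit as `TOTAL − low`,
   where `TOTAL` (allele copies per group) is a public constant.
3. **Evaluate (joint).** Per block, the generator institution builds and
   garbles a boolean circuit computing the statistic for every genotype in
   the block; the evaluator obtains wire labels for its own input bits
   through 1-out-of-2 oblivious transfer, evaluates the garbled circuit, and
   returns the output labels. The generator decodes and shares the results,
   so both parties end with the statistics. All circuit arithmetic is
   unsigned fixed point with FPP = 16 fractional bits: division is
   `floor(numerator · 2¹⁶ / denominator)`, and (obs−exp)² is expanded as
   obs² + exp² − 2·obs·exp so no intermediate can go negative.
4. **Report (local).** Fixed-point mantissas decode to exact decimal strings;
   results are written as a TSV of `locus_id, statistic, value, degenerate`.

Blocks are independent, so sessions run in parallel (a 2-per-core worker
queue by default). A `--simulate` mode runs both roles in one process over a
loopback transport; real runs speak length-prefixed TCP.

## Worked example

The textbook locus with five individuals genotyped `AA AG AA AG GG`: the
minor allele G occurs 4 times among 10 copies, so MAF = 0.4. Split the
individuals between two institutions (A holds three, B holds two) and run the
full protocol:

```sh
$ python examples/02_simulate_maf.py
locus_id        statistic       value   degenerate
rs11686243      maf_case        0.399993896484375       0
rs11686243      maf_control     0.399993896484375       0

fixed-point mantissa 26214 / 2^16 = 0.399993896484375
rounded to one decimal: 0.4
```

`26214 = floor(4·2¹⁶/10)` is the fixed-point image of the exact frequency
2/5; truncation error is below 2⁻¹⁶. The same pipeline is available from the
shell:

```sh
fedgwas synth -o study --loci 12 --n-case 20 20 --n-control 20 20
fedgwas run --simulate --statistic chi2 \
    --party-a-case study/party_A_case.snp --party-a-control study/party_A_control.snp \
    --party-b-case study/party_B_case.snp --party-b-control study/party_B_control.snp
fedgwas decode 0x6666        # -> 0.399993896484375
```

Real two-site runs use `fedgwas run --role evaluator --listen host:port ...`
on one side and `--role generator --peer host:port ...` on the other, after
exchanging the public `metadata.json` sidecars written by `fedgwas
preprocess`.

The `examples/` scripts walk through each capability: preprocessing and
packing, the worked MAF example, a synthetic χ² study checked against a
centralized analysis, garbled-vs-plain equivalence, and transcript sizes
(χ² sessions move several times the bytes of MAF sessions, since garbled
multiplication and division dominate).

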