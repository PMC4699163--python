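"""The worked minor-allele-frequency example through the full MPC pipeline.

Genotypes AA, AG, AA, AG, GG at one locus: the minor allele G occurs 4 times
out of 10 copies, so MAF = 0.4.  Both institutions learn that value — and
nothing about each other's counts — via the garbled-circuit protocol run here
in simulate mode (both roles in one process over a loopback transport).
"""

import io

from fedgwas import pipeline

party_a = pipeline.preprocess(io.StringIO("rs11686243\nAA AG AA\n"),
                              io.StringIO("rs11686243\nAA AG AA\n"))
party_b = pipeline.preprocess(io.StringIO("rs11686243\nAG GG\n"),
                              io.StringIO("rs11686243\nAG GG\n"))

cfg = pipeline.RunConfig(statistic="maf", fpp=16, seed=1)
rows, transcripts = pipeline.simulate_study(party_a, party_b, cfg)

print(pipeline.results_tsv(rows))
row = rows[0]
print(f"fixed-point mantissa {row.mantissa} / 2^16 = {row.value}")
print(f"rounded to one decimal: {round(row.mantissa / 2**16, 1)}")
# Expected output: mantissa 26214 = floor(4 * 65536 / 10), i.e. 0.3999938...,
# the fixed-point image of the exact frequency 0.4.
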