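"""Parse one institution's SNP files, count alleles, and pack input blocks.

The five-individual textbook locus is split across two institutions; this
script plays institution A (three individuals), reconciles metadata with B,
and shows the hexadecimal input block A would feed the secure protocol.
"""

import io

from fedgwas import pipeline, snp_io

PARTY_A = "rs11686243\nAA AG AA\n"
PARTY_B = "rs11686243\nAG GG\n"

party_a = pipeline.preprocess(io.StringIO(PARTY_A), io.StringIO(PARTY_A))
party_b = pipeline.preprocess(io.StringIO(PARTY_B), io.StringIO(PARTY_B))
meta = snp_io.reconcile_metadata(party_a.metadata, party_b.metadata)

print("joint loci:", meta.loci)
print("allele pair:", meta.allele_pair("rs11686243"))
print("allele-copy totals: case", meta.total_case, "control", meta.total_control)

blocks = pipeline.pack_party(party_a, meta, pipeline.RunConfig())
print("institution A's input block (hex):", blocks[0].to_hex())
# The low allele is 'A'; A holds 5 of its copies in each group, so the 32-bit
# word is (5 << 16) | 5 = 0x00050005.  Only low-allele counts ever leave the
# preprocessing step, and they do so garbled, never in this cleartext form.
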