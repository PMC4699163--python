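"""Communication cost: chi-square sessions move far more bytes than MAF.

Multiplication and division dominate the chi-square circuit, and garbled
boolean gates pay per gate, so its transcript is several times the MAF one at
the same genotype count.  Transcript shape depends only on the public circuit
shape, never on the private counts.
"""

from fedgwas import gwas_circuits, snp_io
from fedgwas.encoding import CountWord, PackedBlock
from fedgwas.mpc.session import simulate_session

meta = snp_io.StudyMetadata(
    [f"rs{i}" for i in range(4)], {f"rs{i}": ("A", "G") for i in range(4)}, 10, 10
)
blk = PackedBlock(0, tuple(CountWord(i + 2, 7 - i) for i in range(4)))
va = gwas_circuits.block_input_value(blk, meta)

for name, builder in (("maf", gwas_circuits.build_maf_circuit),
                      ("chi2", gwas_circuits.build_chi2_circuit)):
    circ = builder(4, meta, 16)
    gen, ev = simulate_session(circ, va, va, seed=5, context=name.encode())
    print(f"{name:>5}: {circ.n_gates:>8} gates | generator sent "
          f"{gen.transcript.bytes_sent:>12,} B | evaluator sent "
          f"{ev.transcript.bytes_sent:>8,} B")
    for direction, mtype, size in gen.transcript.shape()[:4]:
        print(f"        {direction:<5} {mtype:<24} {size:>10,} B")
# The generator ships the garbled tables (the bulk of the traffic); the
# chi-square tables are an order of magnitude larger than MAF's.
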