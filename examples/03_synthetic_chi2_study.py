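"""A small synthetic two-institution case/control study, chi-square statistic.

Generates 12 biallelic loci for 20+20 case and 20+20 control individuals
(a scaled-down version of the default 100/100/100/100 layout), runs the
secure chi-square protocol in simulate mode, and compares the result with
what a centralized analysis of the pooled counts would give.
"""

from fedgwas import pipeline, snp_io, synth
from fedgwas.oracles import float_chi2

spec = synth.SyntheticStudySpec(
    n_case=(20, 20), n_control=(20, 20), n_loci=12,
    frac_associated=0.25, effect_shift=0.2, seed=11,
)
study = synth.generate_synthetic_study(spec)


def party(p):
    case = snp_io.count_alleles(study.records[(p, "case")], "case")
    ctrl = snp_io.count_alleles(study.records[(p, "control")], "control")
    return pipeline.PartyData(case, ctrl, snp_io.build_metadata(case, ctrl))


pa, pb = party("A"), party("B")
rows, _ = pipeline.simulate_study(pa, pb, pipeline.RunConfig(statistic="chi2", seed=3))

meta = snp_io.reconcile_metadata(pa.metadata, pb.metadata)
truth = {t.locus_id: t for t in study.truth}
print(f"{'locus':<10} {'secure chi2':>12} {'centralized':>12}  associated")
for r in rows:
    t = truth[r.locus_id]
    low = meta.low_allele(r.locus_id)
    cl = t.case_low_count if low == t.alleles[0] else meta.total_case - t.case_low_count
    ol = t.control_low_count if low == t.alleles[0] else meta.total_control - t.control_low_count
    central = float_chi2((cl, meta.total_case - cl, ol, meta.total_control - ol))
    print(f"{r.locus_id:<10} {float(r.mantissa) / 2**16:>12.4f} {central:>12.4f}  "
          f"{'yes' if t.associated else 'no'}")
# The secure values match the centralized chi-square up to fixed-point
# truncation (well below 0.01 here); loci carrying a simulated effect
# stand out with larger statistics.
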