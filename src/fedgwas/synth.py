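"""Synthetic two-institution case/control genotype studies.

Emits the exact SNP text dialect consumed by :mod:`fedgwas.snp_io` — one
case and one control file per institution — plus a tab-separated ground-truth
table, so the whole pipeline is testable end to end without external data.

Sampling model: each locus is biallelic with a population minor-allele
frequency drawn from a configurable uniform range; individuals are sampled
under Hardy-Weinberg equilibrium (the two allele copies are i.i.d. Bernoulli
draws).  A configurable fraction of loci are "associated": their case-group
minor-allele frequency is shifted additively by a fixed effect size and
clamped to [0, 1].  No linkage disequilibrium, population stratification, or
genotyping error is modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .snp_io import NUCLEOTIDES, SnpRecord

PARTIES = ("A", "B")
GROUPS = ("case", "control")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Study conditions for the generator.

    Defaults reproduce the reference two-institution layout: 100 case and 100
    control individuals at each institution (400 individuals, 400 allele
    copies per group), 311 biallelic loci, population MAF uniform on
    [0.05, 0.5], 10% of loci carrying a +0.10 additive case-group shift.
    """

    n_case: tuple[int, int] = (100, 100)  # individuals per institution
    n_control: tuple[int, int] = (100, 100)
    n_loci: int = 311
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_associated: float = 0.10
    effect_shift: float = 0.10
    seed: int = 0

    def validate(self) -> "SyntheticStudySpec":
        if min(self.n_case) <= 0 or min(self.n_control) <= 0:
            raise SynthError("every institution/group needs at least one individual")
        if self.n_loci <= 0:
            raise SynthError("need at least one locus")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise SynthError("MAF range must lie inside [0, 0.5]")
        if not 0 <= self.frac_associated <= 1:
            raise SynthError("frac_associated must lie in [0, 1]")
        return self


@dataclass
class GroundTruthRow:
    locus_id: str
    alleles: tuple[str, str]  # (low, high) lexicographic
    minor_allele: str
    maf_control: float  # population (true) frequencies
    maf_case: float
    associated: bool
    # exact pooled low-allele copies actually drawn, per group
    case_low_count: int = 0
    control_low_count: int = 0


@dataclass
class SyntheticStudy:
    """Generated study: per-(party, group) SNP records plus ground truth."""

    spec: SyntheticStudySpec
    records: dict[tuple[str, str], list[SnpRecord]]
    truth: list[GroundTruthRow]

    def write_files(self, out_dir: str | Path) -> dict[tuple[str, str], Path]:
        """Write party_{A,B}_{case,control}.snp plus ground_truth.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, recs in self.records.items():
            party, group = key
            p = out / f"party_{party}_{group}.snp"
            with open(p, "w") as fh:
                for rec in recs:
                    fh.write(rec.locus_id + "\n")
                    fh.write(" ".join(rec.calls) + "\n")
            paths[key] = p
        tpath = out / "ground_truth.tsv"
        with open(tpath, "w") as fh:
            fh.write(
                "locus_id\tlow_allele\thigh_allele\tminor_allele\tmaf_control\t"
                "maf_case\tassociated\tcase_low_count\tcontrol_low_count\n"
            )
            for r in self.truth:
                fh.write(
                    f"{r.locus_id}\t{r.alleles[0]}\t{r.alleles[1]}\t{r.minor_allele}\t"
                    f"{r.maf_control:.6f}\t{r.maf_case:.6f}\t{int(r.associated)}\t"
                    f"{r.case_low_count}\t{r.control_low_count}\n"
                )
        paths[("truth", "")] = tpath
        return paths


def generate_synthetic_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Draw a complete two-party study; the seed fully determines the output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pairs = list(itertools.combinations(NUCLEOTIDES, 2))

    n_by = {
        ("A", "case"): spec.n_case[0],
        ("B", "case"): spec.n_case[1],
        ("A", "control"): spec.n_control[0],
        ("B", "control"): spec.n_control[1],
    }
    calls: dict[tuple[str, str], list[list[str]]] = {k: [] for k in n_by}
    truth: list[GroundTruthRow] = []

    lo, hi = spec.maf_range
    for i in range(spec.n_loci):
        locus_id = f"rs{1000000 + i}"
        low, high = pairs[rng.integers(len(pairs))]
        minor = low if rng.random() < 0.5 else high
        maf = float(rng.uniform(lo, hi))
        associated = bool(rng.random() < spec.frac_associated)
        maf_case = min(1.0, max(0.0, maf + spec.effect_shift)) if associated else maf
        freqs = {"case": maf_case, "control": maf}
        row = GroundTruthRow(locus_id, (low, high), minor, maf, maf_case, associated)
        for (party, group), n in n_by.items():
            f_minor = freqs[group]
            # Hardy-Weinberg: each of the 2n allele copies i.i.d.
            copies = rng.random((n, 2)) < f_minor
            major = high if minor == low else low
            geno = []
            low_copies = 0
            for c0, c1 in copies:
                a0 = minor if c0 else major
                a1 = minor if c1 else major
                geno.append(min(a0, a1) + max(a0, a1))
                low_copies += (a0 == low) + (a1 == low)
            calls[(party, group)].append(geno)
            if group == "case":
                row.case_low_count += low_copies
            else:
                row.control_low_count += low_copies
        truth.append(row)

    records = {
        key: [
            SnpRecord(truth[i].locus_id, tuple(locus_calls))
            for i, locus_calls in enumerate(calls[key])
        ]
        for key in calls
    }
    return SyntheticStudy(spec, records, truth)
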