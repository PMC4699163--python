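import io

import pytest

from fedgwas import pipeline, snp_io

# The five-individual textbook locus: genotypes AA AG AA AG GG, minor allele G
# at frequency 4/10 = 0.4.  Split 3/2 between institutions A and B, duplicated
# as the control group so both groups total 10 allele copies.
WORKED_LOCUS = "rs11686243"
WORKED_A = f"{WORKED_LOCUS}\nAA AG AA\n"
WORKED_B = f"{WORKED_LOCUS}\nAG GG\n"
WORKED_MAF_MANTISSA = 26214  # floor(4 * 2^16 / 10)


def party_from_text(case_text: str, control_text: str) -> pipeline.PartyData:
    return pipeline.preprocess(io.StringIO(case_text), io.StringIO(control_text))


@pytest.fixture
def worked_party_a() -> pipeline.PartyData:
    return party_from_text(WORKED_A, WORKED_A)


@pytest.fixture
def worked_party_b() -> pipeline.PartyData:
    return party_from_text(WORKED_B, WORKED_B)


@pytest.fixture
def worked_meta(worked_party_a, worked_party_b) -> snp_io.StudyMetadata:
    return snp_io.reconcile_metadata(worked_party_a.metadata, worked_party_b.metadata)


def make_meta(total_case: int, total_control: int, n_loci: int = 1) -> snp_io.StudyMetadata:
    """Minimal biallelic metadata with the given allele-copy totals."""
    assert total_case % 2 == 0 and total_control % 2 == 0
    loci = [f"rs{i}" for i in range(n_loci)]
    return snp_io.StudyMetadata(
        loci, {l: ("A", "G") for l in loci}, total_case // 2, total_control // 2
    )
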