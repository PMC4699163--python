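"""SNP text-file parsing, local allele counting, and shared study metadata.

The input dialect is the plain two-line-per-locus text format used for
case/control genotype exchange:

    rs11686243
    AG AG AA AG GG AA ...

Each two-character call is one individual's diploid genotype at that locus.
Allele counting is purely local to an institution; only the per-locus counts
are private.  Locus ids, locus order, allele pairs, and group sizes are public
study metadata that both institutions must agree on before a joint run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, TextIO

NUCLEOTIDES = "ACGT"
GROUPS = ("case", "control")


class SnpFormatError(ValueError):
    """Malformed SNP text input (bad call, bad nucleotide, ragged file)."""


class StudyError(ValueError):
    """Semantically invalid study (multi-allelic locus, empty group, ...)."""


@dataclass(frozen=True)
class SnpRecord:
    """One locus: rsID plus the ordered diploid calls of every individual."""

    locus_id: str
    calls: tuple[str, ...]

    def __post_init__(self):
        if not self.calls:
            raise SnpFormatError(f"locus {self.locus_id}: no genotype calls")
        for call in self.calls:
            if len(call) != 2 or any(ch not in NUCLEOTIDES for ch in call):
                raise SnpFormatError(
                    f"locus {self.locus_id}: invalid call {call!r}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.calls)


def parse_snp_file(stream: TextIO | Iterable[str]) -> list[SnpRecord]:
    """Parse alternating rsID / genotype lines into SnpRecords.

    Any whitespace separates calls (wrapped or tab-separated dialects are
    accepted).  Missing-data tokens such as "NN" or "00" are rejected: the
    downstream circuits bake the exact allele total in as a public constant,
    so every individual must have a complete call at every locus.
    """
    records: list[SnpRecord] = []
    pending_id: str | None = None
    n_expected: int | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if pending_id is None:
            pending_id = line
            id_lineno = lineno
            continue
        calls = line.split()
        for col, call in enumerate(calls, start=1):
            if len(call) != 2:
                raise SnpFormatError(
                    f"line {lineno}, call {col}: {call!r} is not a two-nucleotide call"
                )
            for ch in call:
                if ch not in NUCLEOTIDES:
                    raise SnpFormatError(
                        f"line {lineno}, call {col}: invalid nucleotide {ch!r}"
                    )
        if n_expected is None:
            n_expected = len(calls)
        elif len(calls) != n_expected:
            raise SnpFormatError(
                f"line {lineno}: locus {pending_id!r} has {len(calls)} individuals, "
                f"expected {n_expected}"
            )
        records.append(SnpRecord(pending_id, tuple(calls)))
        pending_id = None
    if pending_id is not None:
        raise SnpFormatError(
            f"line {id_lineno}: locus {pending_id!r} has no genotype line"
        )
    return records


class AlleleCountTable:
    """Per-locus nucleotide counts (allele copies) for one group at one site."""

    def __init__(self, group: str, counts: dict[str, dict[str, int]]):
        if group not in GROUPS:
            raise StudyError(f"unknown group {group!r}")
        self.group = group
        self.counts = counts  # ordered: locus_id -> {nucleotide: copies}

    @property
    def loci(self) -> list[str]:
        return list(self.counts)

    def n_individuals(self) -> int:
        first = next(iter(self.counts.values()))
        return sum(first.values()) // 2

    def count(self, locus_id: str, nucleotide: str) -> int:
        return self.counts[locus_id].get(nucleotide, 0)


def count_alleles(records: list[SnpRecord], group: str) -> AlleleCountTable:
    """Tally allele copies per locus: a pure fold over call characters."""
    counts: dict[str, dict[str, int]] = {}
    n = None
    for rec in records:
        if rec.locus_id in counts:
            raise StudyError(f"duplicate locus {rec.locus_id!r}")
        if n is None:
            n = rec.n_individuals
        elif rec.n_individuals != n:
            raise StudyError(
                f"locus {rec.locus_id!r}: {rec.n_individuals} individuals, expected {n}"
            )
        tally: dict[str, int] = {}
        for call in rec.calls:
            for ch in call:
                tally[ch] = tally.get(ch, 0) + 1
        counts[rec.locus_id] = tally
    return AlleleCountTable(group, counts)


def _sentinel_allele(observed: str) -> str:
    """Placeholder second allele for a monomorphic locus (count stays 0)."""
    for ch in NUCLEOTIDES:
        if ch != observed:
            return ch
    raise AssertionError("unreachable")


@dataclass
class StudyMetadata:
    """The public study description both parties must share.

    `alleles[locus]` is the observed nucleotide set (1 or 2, sorted).  The
    circuit-facing pair — with a zero-count sentinel completing monomorphic
    loci — comes from :meth:`allele_pair`.  Totals are in allele copies
    (2 × individuals).
    """

    loci: list[str]
    alleles: dict[str, tuple[str, ...]]
    n_case_individuals: int
    n_control_individuals: int

    @property
    def total_case(self) -> int:
        return 2 * self.n_case_individuals

    @property
    def total_control(self) -> int:
        return 2 * self.n_control_individuals

    def allele_pair(self, locus_id: str) -> tuple[str, str]:
        obs = self.alleles[locus_id]
        pair = obs if len(obs) == 2 else tuple(sorted((obs[0], _sentinel_allele(obs[0]))))
        return (pair[0], pair[1])

    def low_allele(self, locus_id: str) -> str:
        return self.allele_pair(locus_id)[0]

    def validate(self) -> "StudyMetadata":
        if len(set(self.loci)) != len(self.loci):
            raise StudyError("duplicate loci in metadata")
        if self.n_case_individuals <= 0 or self.n_control_individuals <= 0:
            raise StudyError("both groups must contain at least one individual")
        for locus in self.loci:
            a = self.allele_pair(locus)
            if not a[0] < a[1]:
                raise StudyError(f"locus {locus!r}: allele pair not ordered")
        return self

    # -- serialization (small JSON sidecar) --------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "fedgwas-metadata v1",
                "n_case_individuals": self.n_case_individuals,
                "n_control_individuals": self.n_control_individuals,
                "loci": [
                    {"id": l, "alleles": "".join(self.alleles[l])} for l in self.loci
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StudyMetadata":
        obj = json.loads(text)
        if obj.get("format") != "fedgwas-metadata v1":
            raise StudyError("unrecognized metadata format")
        loci = [e["id"] for e in obj["loci"]]
        alleles = {e["id"]: tuple(e["alleles"]) for e in obj["loci"]}
        return cls(
            loci, alleles, obj["n_case_individuals"], obj["n_control_individuals"]
        ).validate()


def build_metadata(
    case_counts: AlleleCountTable, control_counts: AlleleCountTable
) -> StudyMetadata:
    """Derive one institution's public metadata from its two count tables."""
    if case_counts.group != "case" or control_counts.group != "control":
        raise StudyError("tables must be a (case, control) pair")
    if case_counts.loci != control_counts.loci:
        raise StudyError("case and control files cover different loci")
    if not case_counts.loci:
        raise StudyError("no loci in study")
    alleles: dict[str, tuple[str, ...]] = {}
    for locus in case_counts.loci:
        observed = {
            n
            for table in (case_counts, control_counts)
            for n, c in table.counts[locus].items()
            if c > 0
        }
        if len(observed) > 2:
            raise StudyError(
                f"locus {locus!r} is not biallelic: saw {sorted(observed)}"
            )
        alleles[locus] = tuple(sorted(observed))
    return StudyMetadata(
        loci=list(case_counts.loci),
        alleles=alleles,
        n_case_individuals=case_counts.n_individuals(),
        n_control_individuals=control_counts.n_individuals(),
    ).validate()


def reconcile_metadata(meta_a: StudyMetadata, meta_b: StudyMetadata) -> StudyMetadata:
    """Merge two institutions' metadata into the joint study description.

    Locus order follows `meta_a` restricted to the shared loci (in a protocol
    session the generator's ordering is authoritative and the handshake digest
    enforces agreement); allele sets are unioned and must stay biallelic;
    group totals are summed across institutions.  Symmetric in locus *set*,
    allele pairs, and totals.
    """
    common = set(meta_a.loci) & set(meta_b.loci)
    if not common:
        raise StudyError("no loci in common between institutions")
    loci = [l for l in meta_a.loci if l in common]
    alleles = {}
    for locus in loci:
        union = sorted(set(meta_a.alleles[locus]) | set(meta_b.alleles[locus]))
        if len(union) > 2:
            raise StudyError(
                f"locus {locus!r}: irreconcilable alleles {union} across institutions"
            )
        alleles[locus] = tuple(union)
    return StudyMetadata(
        loci=loci,
        alleles=alleles,
        n_case_individuals=meta_a.n_case_individuals + meta_b.n_case_individuals,
        n_control_individuals=meta_a.n_control_individuals
        + meta_b.n_control_individuals,
    ).validate()
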