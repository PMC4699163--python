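"""End-to-end workflow glue: preprocess → pack → sessions → decoded report.

This module is the library face of the five-step workflow: parse and count
locally, agree on public metadata, pack counts into input blocks, run one
protocol session per block (simulated in-process or over TCP), and decode the
fixed-point outputs into the tab-separated cleartext report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from . import encoding, gwas_circuits, snp_io
from .circuit import Circuit, evaluate_plain
from .encoding import PackedBlock, decode_fixed_point
from .mpc.session import (
    BlockSessionError,
    block_seeds,
    run_parallel_simulated,
    run_session,
)

log = logging.getLogger(__name__)

STATISTICS = ("maf", "chi2")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Shared public run parameters; both parties must agree on all of them."""

    statistic: str = "chi2"
    fpp: int = encoding.DEFAULT_FPP
    block_genotypes: int = encoding.GENOTYPES_PER_BLOCK
    workers: int = 1
    pad_to: int | None = None
    seed: int | None = None

    def validate(self) -> "RunConfig":
        if self.statistic not in STATISTICS:
            raise PipelineError(f"statistic must be one of {STATISTICS}")
        if self.fpp < 1:
            raise PipelineError("fpp must be >= 1")
        if not 0 < self.block_genotypes <= encoding.GENOTYPES_PER_BLOCK:
            raise PipelineError(
                f"block capacity must be in [1, {encoding.GENOTYPES_PER_BLOCK}]"
            )
        if self.workers < 1:
            raise PipelineError("workers must be >= 1")
        return self


@dataclass
class PartyData:
    """One institution's private side: count tables plus its local metadata."""

    case_counts: snp_io.AlleleCountTable
    control_counts: snp_io.AlleleCountTable
    metadata: snp_io.StudyMetadata


def preprocess(case_source, control_source) -> PartyData:
    """Parse one institution's case and control SNP files and count locally."""
    case_records = _parse(case_source)
    control_records = _parse(control_source)
    case_counts = snp_io.count_alleles(case_records, "case")
    control_counts = snp_io.count_alleles(control_records, "control")
    meta = snp_io.build_metadata(case_counts, control_counts)
    return PartyData(case_counts, control_counts, meta)


def _parse(source) -> list[snp_io.SnpRecord]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return snp_io.parse_snp_file(fh)
    return snp_io.parse_snp_file(source)


def pack_party(
    party: PartyData, meta: snp_io.StudyMetadata, config: RunConfig
) -> list[PackedBlock]:
    """Pack a party's counts against the *reconciled* metadata.

    The joint metadata decides each locus's low allele; packing against local
    metadata alone can disagree on monomorphic loci.
    """
    return encoding.pack_counts(
        party.case_counts,
        party.control_counts,
        meta,
        pad_to=config.pad_to,
        block_genotypes=config.block_genotypes,
    )


def session_context(
    meta: snp_io.StudyMetadata, config: RunConfig, block_index: int, n_genotypes: int
) -> bytes:
    """Canonical public context; any disagreement fails the handshake."""
    meta_digest = hashlib.sha256(meta.to_json().encode()).hexdigest()
    return (
        f"fedgwas/{config.statistic}/fpp={config.fpp}"
        f"/block={block_index}/n={n_genotypes}"
        f"/cap={config.block_genotypes}/meta={meta_digest}"
    ).encode()


def build_block_circuit(
    n_genotypes: int, meta: snp_io.StudyMetadata, config: RunConfig, **kw
) -> Circuit:
    builder = (
        gwas_circuits.build_maf_circuit
        if config.statistic == "maf"
        else gwas_circuits.build_chi2_circuit
    )
    return builder(n_genotypes, meta, config.fpp, **kw)


def block_circuits(
    blocks: list[PackedBlock], meta: snp_io.StudyMetadata, config: RunConfig
) -> list[Circuit]:
    """One circuit per block; blocks of equal size share the (immutable) circuit."""
    by_size: dict[int, Circuit] = {}
    out = []
    for blk in blocks:
        if blk.n_genotypes not in by_size:
            by_size[blk.n_genotypes] = build_block_circuit(blk.n_genotypes, meta, config)
        out.append(by_size[blk.n_genotypes])
    return out


@dataclass(frozen=True)
class ResultRow:
    """One decoded statistic for one locus."""

    locus_id: str
    statistic: str
    mantissa: int
    fpp: int
    degenerate: bool = False

    @property
    def value(self) -> str:
        return decode_fixed_point(self.mantissa, self.fpp)

    def tsv(self) -> str:
        return f"{self.locus_id}\t{self.statistic}\t{self.value}\t{int(self.degenerate)}"


TSV_HEADER = "locus_id\tstatistic\tvalue\tdegenerate"


def results_tsv(rows: Iterable[ResultRow]) -> str:
    return "\n".join([TSV_HEADER, *(r.tsv() for r in rows)]) + "\n"


def merge_block_outputs(
    outputs_per_block: list[dict[str, int]],
    blocks: list[PackedBlock],
    meta: snp_io.StudyMetadata,
    config: RunConfig,
) -> list[ResultRow]:
    """Flatten per-block outputs into locus-ordered rows, dropping padding."""
    rows: list[ResultRow] = []
    g = 0
    n_real = len(meta.loci)
    for blk, outs in zip(blocks, outputs_per_block):
        for i in range(blk.n_genotypes):
            if g >= n_real:  # padding genotype: discard
                g += 1
                continue
            locus = meta.loci[g]
            if config.statistic == "maf":
                for group in ("case", "control"):
                    rows.append(
                        ResultRow(locus, f"maf_{group}", outs[f"maf_{group}/{i}"], config.fpp)
                    )
            else:
                rows.append(
                    ResultRow(
                        locus,
                        "chi2",
                        outs[f"chi2/{i}"],
                        config.fpp,
                        degenerate=bool(outs[f"chi2_degenerate/{i}"]),
                    )
                )
            g += 1
    return rows


def simulate_study(
    party_a: PartyData, party_b: PartyData, config: RunConfig
) -> tuple[list[ResultRow], list[tuple]]:
    """Full two-party run with both roles in-process over loopback transports.

    Party A acts as the circuit generator, party B as the evaluator.  Returns
    the decoded rows plus the (generator, evaluator) transcripts per block.
    """
    config.validate()
    meta = snp_io.reconcile_metadata(party_a.metadata, party_b.metadata)
    blocks_a = pack_party(party_a, meta, config)
    blocks_b = pack_party(party_b, meta, config)
    circs = block_circuits(blocks_a, meta, config)
    ins_a = [gwas_circuits.block_input_value(b, meta) for b in blocks_a]
    ins_b = [gwas_circuits.block_input_value(b, meta) for b in blocks_b]
    results = run_parallel_simulated(
        circs,
        ins_a,
        ins_b,
        workers=config.workers,
        seed=config.seed,
        context_fn=lambda i: session_context(meta, config, i, blocks_a[i].n_genotypes),
    )
    outs = [gen.outputs for gen, _ev in results]
    rows = merge_block_outputs(outs, blocks_a, meta, config)
    transcripts = [(gen.transcript, ev.transcript) for gen, ev in results]
    return rows, transcripts


def cleartext_study(
    party_a: PartyData, party_b: PartyData, config: RunConfig
) -> list[ResultRow]:
    """The same statistics via plain circuit evaluation (no garbling).

    This is the correctness oracle for :func:`simulate_study`: identical rows
    are expected, bit for bit.
    """
    config.validate()
    meta = snp_io.reconcile_metadata(party_a.metadata, party_b.metadata)
    blocks_a = pack_party(party_a, meta, config)
    blocks_b = pack_party(party_b, meta, config)
    circs = block_circuits(blocks_a, meta, config)
    outs = []
    for circ, ba, bb in zip(circs, blocks_a, blocks_b):
        outs.append(
            evaluate_plain(
                circ,
                gwas_circuits.block_input_value(ba, meta),
                gwas_circuits.block_input_value(bb, meta),
            )
        )
    return merge_block_outputs(outs, blocks_a, meta, config)


def run_networked(
    role: str,
    party: PartyData,
    peer_metadata: snp_io.StudyMetadata,
    config: RunConfig,
    transport,
) -> list[ResultRow]:
    """Run all block sessions sequentially over one framed transport.

    The generator reconciles (own, peer) metadata; the evaluator (peer, own):
    both sides thereby agree on the generator-ordered joint locus list, and
    the per-block handshake digests verify the agreement.
    """
    config.validate()
    if role == "generator":
        meta = snp_io.reconcile_metadata(party.metadata, peer_metadata)
    else:
        meta = snp_io.reconcile_metadata(peer_metadata, party.metadata)
    blocks = pack_party(party, meta, config)
    circs = block_circuits(blocks, meta, config)
    outs = []
    for i, (circ, blk) in enumerate(zip(circs, blocks)):
        sg, se = block_seeds(config.seed, i)
        seed = sg if role == "generator" else se
        ctx = session_context(meta, config, i, blk.n_genotypes)
        try:
            res = run_session(
                role,
                circ,
                gwas_circuits.block_input_value(blk, meta),
                transport,
                seed=seed,
                context=ctx,
            )
        except Exception as e:
            raise BlockSessionError(i, e) from e
        outs.append(res.outputs)
    return merge_block_outputs(outs, blocks, meta, config)
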