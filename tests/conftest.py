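"""Shared fixtures: toy annotations, per-base bitmap oracles, SAM builders."""

from __future__ import annotations

import io

import numpy as np
import pytest

from rnadiff.gene_models import (
    GeneIntervalSet,
    GenomicInterval,
    Transcript,
    build_gene_model,
    parse_annotation,
)


def make_transcript(gene_id, tid, spans, chrom="chr1", strand="+"):
    return Transcript(
        tid, gene_id, [GenomicInterval(chrom, s, e, strand) for s, e in spans]
    )


def make_model(gene_id, spans, chrom="chr1", strand="+"):
    return GeneIntervalSet(
        gene_id, chrom, strand, [GenomicInterval(chrom, s, e, strand) for s, e in spans]
    )


def base_set(spans) -> set[int]:
    """Per-base bitmap oracle: the set of bases covered by spans."""
    out: set[int] = set()
    for s, e in spans:
        out.update(range(s, e))
    return out


def spans_of(model: GeneIntervalSet) -> list[tuple[int, int]]:
    return model.spans()


def random_annotation(rng: np.random.Generator, max_genes=5, max_tx=4, max_coord=1000):
    """Random toy annotation as gene_id -> transcripts, exons within one chrom."""
    genes = {}
    for g in range(rng.integers(1, max_genes + 1)):
        gid = f"G{g}"
        txs = []
        for t in range(rng.integers(1, max_tx + 1)):
            n_ex = int(rng.integers(1, 5))
            spans = []
            for _ in range(n_ex):
                s = int(rng.integers(0, max_coord - 2))
                e = int(rng.integers(s + 1, min(s + 120, max_coord)))
                spans.append((s, e))
            txs.append(make_transcript(gid, f"{gid}.T{t}", sorted(spans)))
        genes[gid] = txs
    return genes


@pytest.fixture
def toy_gtf_text():
    return (
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T1";\n'
        'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T1";\n'
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T2";\n'
        'chr1\tsrc\texon\t251\t300\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T2";\n'
        'chr1\tsrc\texon\t501\t700\t.\t-\t.\tgene_id "G2"; transcript_id "G2.T1";\n'
    )


@pytest.fixture
def toy_genes(toy_gtf_text):
    return parse_annotation(io.StringIO(toy_gtf_text))


def write_sam(path, records, chroms=None, samples=("s1",)):
    """Write a minimal SAM file.

    records: iterable of (read_id, sample, chrom, start_0based, length,
    strand, nh) tuples.
    """
    records = list(records)
    if chroms is None:
        chroms = {}
        for _, _, chrom, start, length, _, _ in records:
            chroms[chrom] = max(chroms.get(chrom, 0), start + length + 10)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in sorted(chroms):
            fh.write(f"@SQ\tSN:{c}\tLN:{chroms[c]}\n")
        for s in samples:
            fh.write(f"@RG\tID:{s}\tSM:{s}\n")
        for rid, sample, chrom, start, length, strand, nh in records:
            flag = 16 if strand == "-" else 0
            seq = "A" * length
            fh.write(
                f"{rid}\t{flag}\t{chrom}\t{start + 1}\t255\t{length}M\t*\t0\t0\t"
                f"{seq}\t{'I' * length}\tRG:Z:{sample}\tNH:i:{nh}\n"
            )
    return path
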