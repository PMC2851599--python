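"""Read placement, pileups, and threshold-based SNP calling.

Reads are placed on reference transcripts with a unique exact k-mer seed and
ungapped end-to-end extension (match/mismatch only — indels are outside the
SNP definition used here). Pileup columns accumulate base counts per covered
position, and SNPs are called wherever depth and the alternate-allele
frequency clear preset thresholds, the convention used for pooled-sample
454 EST data: depth >= 10x with alternate frequency >= 20% for deeply
covered contigs, depth >= 8x for the genome-wide preset. Both bounds are
inclusive.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .ssr_markers import revcomp

__all__ = [
    "Placement",
    "PileupColumn",
    "SNPCall",
    "map_reads",
    "build_pileup",
    "call_snps",
    "snp_rate",
    "contig_read_filter",
    "write_sam",
    "read_sam",
    "write_vcf",
]


@dataclass(frozen=True)
class Placement:
    """An ungapped placement of a read on a reference.

    ``strand`` is '+' or '-'; ``aligned_sequence`` is the read sequence in
    reference orientation (already reverse-complemented for '-' placements),
    so ``aligned_sequence[i]`` stacks on reference position ``ref_start + i``.
    ``edit`` is a per-base string of '=' (match) / 'X' (mismatch).
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    aligned_sequence: str
    edit: str

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.aligned_sequence)

    @property
    def n_mismatches(self) -> int:
        return self.edit.count("X")


@dataclass
class PileupColumn:
    """Base counts over one reference position. ``depth`` = sum of all counts."""

    ref_id: str
    position: int
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SNPCall:
    """A biallelic substitution call at a pileup column."""

    ref_id: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_frequency: float


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def _kmer_index(references: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for rid, seq in references.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append((rid, i))
    return dict(index)


def _place(
    seq: str,
    references: Mapping[str, str],
    index: Mapping[str, list[tuple[str, int]]],
    k: int,
    max_mismatch_rate: float,
) -> tuple[str, int] | None:
    """Unique diagonal for one oriented read sequence, or None."""
    diagonals: set[tuple[str, int]] = set()
    for i in range(0, len(seq) - k + 1, k):
        for rid, pos in index.get(seq[i : i + k], ()):
            diagonals.add((rid, pos - i))
        if len(diagonals) > 1:
            return None  # ambiguous
    if len(diagonals) != 1:
        return None
    rid, start = next(iter(diagonals))
    if start < 0 or start + len(seq) > len(references[rid]):
        return None  # would hang off the reference
    ref = references[rid]
    mismatches = sum(a != b for a, b in zip(seq, ref[start : start + len(seq)]))
    if mismatches > max_mismatch_rate * len(seq):
        return None
    return rid, start


def map_reads(
    reads: Iterable,
    references: Mapping[str, str],
    k: int = 21,
    max_mismatch_rate: float = 0.05,
) -> tuple[list[Placement], list[str]]:
    """Place reads by unique exact k-mer seed + ungapped end-to-end extension.

    ``reads`` yields objects with ``.id`` and ``.sequence`` (or (id, seq)
    tuples). A read is mapped when exactly one (reference, diagonal) is
    supported by its k-mer seeds on either strand and the full-length
    extension has a mismatch rate <= ``max_mismatch_rate``; anything else
    (no seed, multiple candidate diagonals, too many mismatches, read
    overhanging the reference, read shorter than k) is reported unmapped.
    Deterministic for a fixed input order.
    """
    index = _kmer_index(references, k)
    placements: list[Placement] = []
    unmapped: list[str] = []
    for read in reads:
        rid_, seq = (read.id, read.sequence) if hasattr(read, "id") else read
        seq = seq.upper()
        if len(seq) < k:
            unmapped.append(rid_)
            continue
        hits = []
        fwd = _place(seq, references, index, k, max_mismatch_rate)
        if fwd is not None:
            hits.append(("+", seq, fwd))
        rc = revcomp(seq)
        rev = _place(rc, references, index, k, max_mismatch_rate)
        if rev is not None:
            hits.append(("-", rc, rev))
        if len(hits) != 1:
            unmapped.append(rid_)
            continue
        strand, oriented, (ref_id, start) = hits[0]
        ref = references[ref_id]
        edit = "".join(
            "=" if a == b else "X"
            for a, b in zip(oriented, ref[start : start + len(oriented)])
        )
        placements.append(Placement(rid_, ref_id, start, strand, oriented, edit))
    return placements, unmapped


# ---------------------------------------------------------------------------
# Pileup and calling
# ---------------------------------------------------------------------------

def build_pileup(
    placements: Iterable[Placement], references: Mapping[str, str]
) -> list[PileupColumn]:
    """One column per covered reference position, in (ref, position) order.

    Conservation: the summed depth over all columns equals the summed aligned
    length over all placements (every aligned base, including N, lands in
    exactly one column's counts).
    """
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for p in placements:
        for i, base in enumerate(p.aligned_sequence):
            counts[(p.ref_id, p.ref_start + i)][base] += 1
    columns = []
    for (rid, pos) in sorted(counts):
        columns.append(
            PileupColumn(rid, pos, references[rid][pos], dict(counts[(rid, pos)]))
        )
    return columns


def call_snps(
    pileup: Iterable[PileupColumn],
    min_depth: int = 8,
    min_alt_freq: float = 0.20,
) -> list[SNPCall]:
    """Emit a call per column meeting the depth and alternate-frequency presets.

    N bases are excluded from counts; depth here is the A/C/G/T depth. The
    single most frequent non-reference base is the alternate (ties broken
    alphabetically); a call requires depth >= ``min_depth`` and
    alt/depth >= ``min_alt_freq``, both inclusive. Indels never arise
    (ungapped placements).
    """
    calls = []
    for col in pileup:
        acgt = {b: c for b, c in col.counts.items() if b in "ACGT"}
        depth = sum(acgt.values())
        if depth < min_depth:
            continue
        alts = {b: c for b, c in acgt.items() if b != col.ref_base}
        if not alts:
            continue
        top = max(alts.values())
        alt = min(b for b, c in alts.items() if c == top)  # ties -> lexicographic
        freq = alts[alt] / depth
        if freq >= min_alt_freq - 1e-12:
            calls.append(SNPCall(col.ref_id, col.position, col.ref_base, alt, depth, freq))
    return calls


def snp_rate(calls: int | Sequence, total_bp: int) -> float:
    """SNPs per 100 bp, rounded to 1 decimal (the conventional reporting scale)."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    n = calls if isinstance(calls, int) else len(calls)
    return round(100.0 * n / total_bp, 1)


def contig_read_filter(read_counts: Mapping[str, int], min_reads: int = 20) -> list[str]:
    """Contigs with strictly more than ``min_reads`` reads (sorted ids)."""
    return sorted(cid for cid, n in read_counts.items() if n > min_reads)


# ---------------------------------------------------------------------------
# SAM / VCF
# ---------------------------------------------------------------------------

def write_sam(
    placements: Sequence[Placement],
    unmapped: Sequence[str],
    references: Mapping[str, str],
    reads_by_id: Mapping[str, str],
    path: str,
) -> None:
    """Write placements as a minimal SAM file (mapped/unmapped, ungapped CIGAR)."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(references[n])} for n in names],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for p in placements:
            a = pysam.AlignedSegment(out.header)
            a.query_name = p.read_id
            a.query_sequence = p.aligned_sequence
            a.flag = 16 if p.strand == "-" else 0
            a.reference_id = names.index(p.ref_id)
            a.reference_start = p.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(p.aligned_sequence))]
            a.set_tag("NM", p.n_mismatches)
            out.write(a)
        for rid in unmapped:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rid
            a.flag = 4
            a.query_sequence = reads_by_id.get(rid)
            out.write(a)


def read_sam(path: str, references: Mapping[str, str]) -> tuple[list[Placement], list[str]]:
    """Read a minimal SAM file back into placements (recomputing edit strings)."""
    placements, unmapped = [], []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                unmapped.append(a.query_name)
                continue
            seq = a.query_sequence
            ref = references[a.reference_name]
            start = a.reference_start
            edit = "".join(
                "=" if x == y else "X" for x, y in zip(seq, ref[start : start + len(seq)])
            )
            placements.append(
                Placement(a.query_name, a.reference_name, start,
                          "-" if a.is_reverse else "+", seq, edit)
            )
    return placements, unmapped


def write_vcf(calls: Sequence[SNPCall], references: Mapping[str, str], path: str) -> None:
    """Write SNP calls as VCF 4.2 with DP and AF INFO fields (1-based positions)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=estmine\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total A/C/G/T depth">\n')
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        for name, seq in references.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            out.write(
                f"{c.ref_id}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth};AF={c.alt_frequency:.4f}\n"
            )
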