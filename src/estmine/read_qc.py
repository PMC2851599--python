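"""Raw-read quality control for 454 EST collections.

Partitions reads into kept/discarded sets with three filters applied in a
fixed, documented order: optional adapter trimming, retroelement similarity,
long SSR runs (> 50 bp), and mean base quality (< 18 discarded). Each
discarded read carries exactly one reason — the first filter it triggers —
so report counts are reproducible even for reads failing several filters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ssr_markers import longest_ssr_run_bp

__all__ = ["Read", "QCReport", "mean_quality", "qc_filter", "read_fastq", "write_fastq"]


@dataclass
class Read:
    """A sequencing read: id, nucleotide string, per-base phred qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QCReport:
    """Counts of input reads and their fate under the QC filters."""

    n_input: int = 0
    n_kept: int = 0
    n_discarded_quality: int = 0
    n_discarded_long_ssr: int = 0
    n_discarded_retro: int = 0
    n_discarded_adapter_only: int = 0

    def to_tsv(self) -> str:
        rows = [
            ("input", self.n_input),
            ("kept", self.n_kept),
            ("discarded_quality", self.n_discarded_quality),
            ("discarded_long_ssr", self.n_discarded_long_ssr),
            ("discarded_retro", self.n_discarded_retro),
            ("discarded_adapter_only", self.n_discarded_adapter_only),
        ]
        return "category\tcount\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def mean_quality(read: Read) -> float:
    """Arithmetic mean of the read's phred quality integers."""
    if not read.qualities:
        raise ValueError(f"read {read.id!r} is empty")
    return sum(read.qualities) / len(read.qualities)


def _trim_adapters(read: Read, adapters: Sequence[str]) -> Read:
    # exact-prefix/suffix matching only; longest matching adapter wins
    seq, quals = read.sequence, read.qualities
    for a in sorted(adapters, key=len, reverse=True):
        if a and seq.startswith(a):
            seq, quals = seq[len(a) :], quals[len(a) :]
            break
    for a in sorted(adapters, key=len, reverse=True):
        if a and seq.endswith(a):
            seq, quals = seq[: -len(a)], quals[: -len(a)]
            break
    if seq == read.sequence:
        return read
    return Read(read.id, seq, list(quals))


def qc_filter(
    reads: Iterable[Read],
    min_mean_q: float = 18.0,
    max_ssr_run_bp: int = 50,
    retro_matcher: Callable[[str], bool] | None = None,
    adapters: Sequence[str] | None = None,
) -> tuple[list[Read], list[tuple[Read, str]], QCReport]:
    """Partition reads into (kept, discarded-with-reason, report).

    Filter order is fixed: adapter trim -> retroelement similarity -> long SSR
    run -> mean quality. Boundaries are strict per the filter definitions:
    mean quality exactly ``min_mean_q`` is kept ("less than" discards), an SSR
    run of exactly ``max_ssr_run_bp`` bp is kept ("longer than" discards).
    Kept reads are unmodified apart from adapter trimming; a read left empty
    by trimming is discarded with reason ``adapter_only``.
    """
    kept: list[Read] = []
    discarded: list[tuple[Read, str]] = []
    report = QCReport()
    for read in reads:
        report.n_input += 1
        if adapters:
            read = _trim_adapters(read, adapters)
            if len(read) == 0:
                discarded.append((read, "adapter_only"))
                report.n_discarded_adapter_only += 1
                continue
        if retro_matcher is not None and retro_matcher(read.sequence):
            discarded.append((read, "retro"))
            report.n_discarded_retro += 1
            continue
        if longest_ssr_run_bp(read.sequence) > max_ssr_run_bp:
            discarded.append((read, "long_ssr"))
            report.n_discarded_long_ssr += 1
            continue
        if mean_quality(read) < min_mean_q:
            discarded.append((read, "quality"))
            report.n_discarded_quality += 1
            continue
        kept.append(read)
        report.n_kept += 1
    return kept, discarded, report


# ---------------------------------------------------------------------------
# FASTQ I/O (phred+33 throughout)
# ---------------------------------------------------------------------------

def read_fastq(handle: TextIO | str) -> list[Read]:
    """Parse a Sanger (phred+33) FASTQ file into Read objects."""
    reads = []
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            reads.append(
                Read(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near read {len(reads) + 1}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read | tuple[Read, str]], handle: TextIO | str) -> None:
    """Write reads as phred+33 FASTQ; (read, reason) pairs put the reason in the description."""
    records = []
    for item in reads:
        read, desc = item if isinstance(item, tuple) else (item, "")
        rec = SeqRecord(Seq(read.sequence), id=read.id, description=desc)
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, handle, "fastq")
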