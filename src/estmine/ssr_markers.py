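"""Microsatellite (SSR) detection, coding-context summaries, and PCR primer design.

Detects di-, tri- and tetra-nucleotide simple sequence repeats as maximal,
primitive-unit tandem runs with a minimum number of contiguous repeat units,
classifies loci by overlap with coding intervals, and enumerates primer pairs
in the flanking regions under stringent amplification constraints (GC content,
melting temperature window, Tm difference, product size, 3' GC clamp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "SSRLocus",
    "PrimerPair",
    "PrimerConstraints",
    "SSRContextSummary",
    "find_ssrs",
    "classify_long_runs",
    "longest_ssr_run_bp",
    "ssr_context",
    "design_primers",
    "check_primer_pair",
    "canonical_motif",
    "loci_to_gff3",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SSRLocus:
    """A maximal tandem repeat run, reported on the reference strand.

    ``start``/``end`` are 0-based half-open; ``end - start == unit_size * n_units``.
    ``motif`` is the lexicographically smallest rotation of the repeat unit on
    the reported strand (no reverse-complement folding, since EST sequence is
    strand-specific).
    """

    seq_id: str
    start: int
    end: int
    motif: str
    unit_size: int
    n_units: int

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def find_ssrs(
    seq: str,
    seq_id: str = "",
    unit_sizes: Iterable[int] = (2, 3, 4),
    min_units: int = 4,
    max_len_bp: int | None = None,
) -> list[SSRLocus]:
    """Locate maximal, primitive-unit tandem repeats of the given unit sizes.

    A locus is the left-anchored complete-unit portion of a maximal periodic
    region: a stretch where ``seq[j] == seq[j - u]`` throughout, that cannot be
    extended in either direction. Runs whose repeat unit has a smaller period
    (e.g. ATAT, a doubled AT) are suppressed at the larger size and reported
    only at their primitive unit size, so no run is double-reported. ``N``
    breaks a run and never participates in one.

    With ``max_len_bp`` set, only runs *shorter* than that many bp are returned
    (the marker-discovery convention; long runs are a QC matter — see
    :func:`classify_long_runs`).
    """
    seq = seq.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for u in unit_sizes:
        limit = n - u
        j = 0
        while j < limit:
            if seq[j] != seq[j + u] or seq[j] == "N":
                j += 1
                continue
            start = j
            while j < limit and seq[j] == seq[j + u] and seq[j] != "N":
                j += 1
            run_matches = j - start           # periodic region is [start, start+run+u)
            n_units = (run_matches + u) // u  # complete units, left-anchored
            if n_units >= min_units:
                unit = seq[start : start + u]
                if _is_primitive(unit):
                    end = start + u * n_units
                    if max_len_bp is None or end - start < max_len_bp:
                        loci.append(
                            SSRLocus(seq_id, start, end, canonical_motif(unit), u, n_units)
                        )
    loci.sort(key=lambda l: (l.start, l.end, l.unit_size))
    return loci


def classify_long_runs(seq: str, max_run_bp: int = 50, seq_id: str = "") -> list[SSRLocus]:
    """Return SSR runs strictly longer than ``max_run_bp`` (QC flagging).

    Reuses :func:`find_ssrs` without the length cap; a run of exactly
    ``max_run_bp`` bp is *not* flagged ("longer than" is strict).
    """
    return [
        locus
        for locus in find_ssrs(seq, seq_id=seq_id, max_len_bp=None)
        if locus.length > max_run_bp
    ]


def longest_ssr_run_bp(seq: str) -> int:
    """Length in bp of the longest di/tri/tetra-nucleotide run in ``seq`` (0 if none)."""
    loci = find_ssrs(seq, max_len_bp=None)
    return max((l.length for l in loci), default=0)


# ---------------------------------------------------------------------------
# Coding / non-coding context
# ---------------------------------------------------------------------------

@dataclass
class SSRContextSummary:
    n_ssrs_total: int
    n_in_coding: int
    n_in_noncoding: int
    coding_bp: int
    noncoding_bp: int
    density_coding: float
    density_noncoding: float


def ssr_context(
    loci: Sequence[SSRLocus],
    coding_intervals: Mapping[str, Sequence[tuple[int, int]]],
    seq_lengths: Mapping[str, int],
) -> SSRContextSummary:
    """Partition SSR loci into coding vs non-coding and compute densities.

    An SSR counts as coding iff its interval overlaps any coding interval of
    its sequence by at least 1 bp. Densities are loci per bp of each region
    class, summed over all sequences in ``seq_lengths``.
    """
    coding_bp = 0
    total_bp = 0
    for sid, length in seq_lengths.items():
        total_bp += length
        for s, e in coding_intervals.get(sid, ()):
            if s < 0 or e > length or s > e:
                raise ValueError(f"coding interval ({s}, {e}) outside sequence {sid!r}")
            coding_bp += e - s
    noncoding_bp = total_bp - coding_bp

    n_coding = 0
    for locus in loci:
        hits = any(
            locus.start < e and s < locus.end
            for s, e in coding_intervals.get(locus.seq_id, ())
        )
        n_coding += hits
    n_total = len(loci)
    n_noncoding = n_total - n_coding
    return SSRContextSummary(
        n_ssrs_total=n_total,
        n_in_coding=n_coding,
        n_in_noncoding=n_noncoding,
        coding_bp=coding_bp,
        noncoding_bp=noncoding_bp,
        density_coding=(n_coding / coding_bp) if coding_bp else 0.0,
        density_noncoding=(n_noncoding / noncoding_bp) if noncoding_bp else 0.0,
    )


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerConstraints:
    """Amplification constraints for SSR genotyping primers.

    Defaults follow stringent EST-SSR marker design practice: product
    100-450 bp, per-primer Tm 52-62 degC with at most 4 degC difference,
    GC >= 30% per primer, and a two-base 3' GC clamp. Primer length 18-24 bp.
    ``tm_method`` is ``"nn"`` (nearest-neighbor thermodynamics at 50 mM
    monovalent salt, 50 nM primer) or ``"wallace"`` (2(A+T)+4(G+C) rule).
    """

    primer_len_min: int = 18
    primer_len_max: int = 24
    product_len_min: int = 100
    product_len_max: int = 450
    tm_min: float = 52.0
    tm_max: float = 62.0
    max_tm_diff: float = 4.0
    min_gc_pct: float = 30.0
    gc_clamp: int = 2
    tm_method: str = "nn"


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a template.

    Positions are 0-based half-open template coordinates of the annealing
    sites; ``reverse`` is the primer sequence itself (reverse complement of
    the template window).
    """

    forward: str
    reverse: str
    forward_start: int
    forward_end: int
    reverse_start: int
    reverse_end: int
    product_length: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float


def melting_temp(primer: str, constraints: PrimerConstraints | None = None) -> float:
    c = constraints or PrimerConstraints()
    if c.tm_method == "wallace":
        return float(_mt.Tm_Wallace(primer))
    # primer3-comparable conditions: 50 mM Na+, 50 nM annealing oligo
    return float(_mt.Tm_NN(primer, Na=50, dnac1=50, dnac2=0))


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


_RULES = ("product_length", "tm_range", "tm_difference", "gc_content", "gc_clamp")


def check_primer_pair(
    pair: PrimerPair, constraints: PrimerConstraints | None = None
) -> tuple[bool, list[str]]:
    """Check the five amplification rules; return (verdict, violated rule names).

    Numeric rules use the pair's stored Tm/GC/product fields; the GC clamp is
    read off the primer sequences (last ``gc_clamp`` bases must be G or C).
    Boundaries are inclusive: GC of exactly 30% passes, Tm of exactly 52 or
    62 passes, a Tm difference of exactly 4 passes.
    """
    c = constraints or PrimerConstraints()
    violations = []
    if not (c.product_len_min <= pair.product_length <= c.product_len_max):
        violations.append("product_length")
    if not (c.tm_min <= pair.tm_forward <= c.tm_max and c.tm_min <= pair.tm_reverse <= c.tm_max):
        violations.append("tm_range")
    if abs(pair.tm_forward - pair.tm_reverse) > c.max_tm_diff:
        violations.append("tm_difference")
    if pair.gc_forward < c.min_gc_pct or pair.gc_reverse < c.min_gc_pct:
        violations.append("gc_content")
    clamp = c.gc_clamp
    if clamp and not (
        all(b in "GC" for b in pair.forward[-clamp:])
        and all(b in "GC" for b in pair.reverse[-clamp:])
    ):
        violations.append("gc_clamp")
    return (not violations, violations)


def _candidate_primers(
    template: str,
    lo: int,
    hi: int,
    strand: str,
    c: PrimerConstraints,
) -> list[tuple[int, int, str, float, float]]:
    """All primer windows within template[lo:hi) passing single-primer rules.

    Returns (start, end, primer_seq, tm, gc) tuples. For the reverse strand
    the primer is the reverse complement of the window and its 3' end sits at
    the window *start*.
    """
    out = []
    for length in range(c.primer_len_min, c.primer_len_max + 1):
        for start in range(lo, hi - length + 1):
            window = template[start : start + length]
            if "N" in window:
                continue
            primer = window if strand == "+" else revcomp(window)
            if c.gc_clamp and not all(b in "GC" for b in primer[-c.gc_clamp :]):
                continue
            gc = gc_percent(primer)
            if gc < c.min_gc_pct:
                continue
            tm = melting_temp(primer, c)
            if not (c.tm_min <= tm <= c.tm_max):
                continue
            out.append((start, start + length, primer, tm, gc))
    return out


def design_primers(
    template: str,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """Enumerate primer pairs flanking an SSR locus that pass all five rules.

    Forward primers anneal entirely 5' of the repeat, reverse primers entirely
    3' of it, so the product spans the SSR. All candidate windows within
    amplifiable distance are enumerated and every pair passing
    :func:`check_primer_pair` is kept, sorted by closeness of the mean Tm to
    57 degC, then by closeness of the product length to 250 bp (tie-broken by
    position for determinism). Returns an empty list when no window pair
    qualifies.
    """
    c = constraints or PrimerConstraints()
    template = template.upper()
    fwd_lo = max(0, locus.end - c.product_len_max)
    fwds = _candidate_primers(template, fwd_lo, locus.start, "+", c)
    rev_hi = min(len(template), locus.start + c.product_len_max)
    revs = _candidate_primers(template, locus.end, rev_hi, "-", c)

    pairs: list[PrimerPair] = []
    for (fs, fe, fseq, ftm, fgc), (rs, re_, rseq, rtm, rgc) in itertools.product(fwds, revs):
        product = re_ - fs
        if not (c.product_len_min <= product <= c.product_len_max):
            continue
        if abs(ftm - rtm) > c.max_tm_diff:
            continue
        pairs.append(
            PrimerPair(
                forward=fseq,
                reverse=rseq,
                forward_start=fs,
                forward_end=fe,
                reverse_start=rs,
                reverse_end=re_,
                product_length=product,
                tm_forward=ftm,
                tm_reverse=rtm,
                gc_forward=fgc,
                gc_reverse=rgc,
            )
        )
    pairs.sort(
        key=lambda p: (
            abs((p.tm_forward + p.tm_reverse) / 2 - 57.0),
            abs(p.product_length - 250),
            p.forward_start,
            p.reverse_start,
        )
    )
    return pairs if max_pairs is None else pairs[:max_pairs]


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def loci_to_gff3(loci: Sequence[SSRLocus]) -> str:
    """Render SSR loci as GFF3 (type ``microsatellite``, 1-based coordinates)."""
    lines = ["##gff-version 3"]
    for l in loci:
        attrs = f"motif={l.motif};units={l.n_units}"
        lines.append(
            "\t".join(
                [l.seq_id, "estmine", "microsatellite", str(l.start + 1), str(l.end), ".", "+", ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"
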