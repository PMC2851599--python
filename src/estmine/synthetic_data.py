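"""Synthetic 454 EST data with known ground truth.

Emulates a normalized-cDNA pyrosequencing experiment on a conifer
transcriptome: a pool of transcripts with CDS+UTR structure, a configurable
fraction of retroelement-derived and contaminant (e.g. fungal) transcripts,
planted SSR runs and biallelic SNPs segregating in a small diploid pool
(4 individuals -> 8 chromosomes by default), and single-end reads with a
unimodal (truncated normal) length distribution centered on 306 bp,
per-base phred qualities and substitution errors. Mock protein hit tables
and GO assignments stand in for similarity-search outputs so annotation
summaries are testable offline. Every planted feature is recorded in a
:class:`TruthTable`, and all randomness flows from one seed, so identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_qc import Read
from .ssr_markers import SSRLocus, canonical_motif, revcomp, _is_primitive

__all__ = [
    "Transcript",
    "SimulationConfig",
    "TruthTable",
    "HaplotypePool",
    "SimulationResult",
    "AnnotationParams",
    "make_retro_library",
    "generate_transcriptome",
    "plant_ssr",
    "plant_ssrs",
    "plant_variants",
    "simulate_reads",
    "fabricate_annotation_table",
    "fabricate_go_assignments",
    "simulate",
    "write_transcripts_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """A source transcript: sequence, CDS interval, and origin label."""

    id: str
    sequence: str
    cds_interval: tuple[int, int]  # [start, end) in transcript coordinates
    origin: str  # gene | retroelement | contaminant

    def __post_init__(self) -> None:
        s, e = self.cds_interval
        if not (0 <= s <= e <= len(self.sequence)):
            raise ValueError(f"transcript {self.id!r}: CDS {self.cds_interval} outside bounds")
        if self.origin not in ("gene", "retroelement", "contaminant"):
            raise ValueError(f"transcript {self.id!r}: unknown origin {self.origin!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulationConfig:
    """All knobs of the simulated experiment.

    Defaults describe the emulated study design at desk scale: transcripts
    averaging 2,000 bp (the gene-length assumption behind transcriptome
    coverage estimates), reads averaging 306 bp with a free sd of 75
    truncated to [50, 600], SSR unit-size weights following the observed
    di/tri/tetra proportions, an alternate-allele frequency grid of k/8
    (four pooled diploids), a SNP density of 0.6/100 bp, and a few percent
    of retroelement-origin transcripts.
    """

    n_genes: int = 300
    gene_length_distribution: tuple[float, float] = (2000.0, 500.0)
    min_gene_length: int = 300
    ssr_plant_rate: float = 0.25
    ssr_unit_size_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.771, 3: 0.201, 4: 0.028}
    )
    ssr_repeat_count_distribution: tuple[int, int] = (4, 12)
    snp_rate: float = 0.006
    snp_alt_freq_choices: tuple[float, ...] = tuple(k / 8 for k in range(1, 8))
    n_chromosomes: int = 8
    retro_fraction: float = 0.04
    contaminant_fraction: float = 0.10
    retro_divergence: float = 0.02
    n_reads: int = 20_000
    read_length_distribution: tuple[float, float] = (306.0, 75.0)
    read_length_bounds: tuple[int, int] = (50, 600)
    base_error_rate: float = 0.004
    quality_model: tuple[float, float] = (28.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.ssr_plant_rate, self.snp_rate, self.retro_fraction,
            self.contaminant_fraction, self.base_error_rate,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.retro_fraction + self.contaminant_fraction >= 1:
            raise ValueError("retro_fraction + contaminant_fraction must be < 1")
        for pair in (self.gene_length_distribution, self.read_length_distribution,
                     self.quality_model):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError(f"distribution parameters must be positive: {pair}")
        if self.n_genes <= 0 or self.n_reads < 0:
            raise ValueError("n_genes must be positive and n_reads non-negative")
        lo, hi = self.ssr_repeat_count_distribution
        if lo < 4 or hi < lo:
            raise ValueError("SSR repeat counts must satisfy 4 <= min <= max")
        for f in self.snp_alt_freq_choices:
            if not 0 < f < 1:
                raise ValueError(f"alternate-allele frequency {f} outside (0, 1)")
        total_w = sum(self.ssr_unit_size_weights.values())
        if total_w <= 0 or set(self.ssr_unit_size_weights) - {2, 3, 4}:
            raise ValueError("ssr_unit_size_weights must weight unit sizes 2/3/4")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("gene_length_distribution", "read_length_distribution",
                    "quality_model", "ssr_repeat_count_distribution",
                    "read_length_bounds", "snp_alt_freq_choices"):
            if key in data:
                data[key] = tuple(data[key])
        if "ssr_unit_size_weights" in data:
            data["ssr_unit_size_weights"] = {
                int(k): v for k, v in data["ssr_unit_size_weights"].items()
            }
        return cls(**data)


@dataclass(frozen=True)
class ReadOrigin:
    transcript_id: str
    offset: int
    strand: str


@dataclass
class TruthTable:
    """Ground truth for a simulated data set."""

    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)
    planted_ssrs: list[SSRLocus] = field(default_factory=list)
    planted_snps: list[tuple[str, int, str, str, float]] = field(default_factory=list)
    retro_read_ids: set[str] = field(default_factory=set)
    truncated_read_ids: set[str] = field(default_factory=set)


@dataclass
class HaplotypePool:
    """Reference transcripts plus their per-chromosome haplotype sequences."""

    transcripts: list[Transcript]
    haplotypes: dict[str, list[str]]  # transcript id -> n_chromosomes sequences


@dataclass
class SimulationResult:
    config: SimulationConfig
    transcripts: list[Transcript]
    retro_library: dict[str, str]
    pool: HaplotypePool
    reads: list[Read]
    truth: TruthTable
    annotation: pd.DataFrame
    go_assignments: pd.DataFrame


# ---------------------------------------------------------------------------
# Transcript pool
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _trunc_normal_int(rng, mean, sd, lo, hi) -> int:
    # rejection sampling; the acceptance region always has mass for sane configs
    for _ in range(10_000):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal sampler failed; check distribution parameters")


def make_retro_library(
    rng: np.random.Generator, n_elements: int = 3, mean_length: int = 5000
) -> dict[str, str]:
    """A synthetic library of complete retroelement sequences (stand-ins for
    conifer elements like IFG7, PpRT1 and Gymny)."""
    return {
        f"retro_element_{i + 1}": _random_seq(rng, _trunc_normal_int(rng, mean_length, mean_length / 5, 1000, 10 * mean_length))
        for i in range(n_elements)
    }


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def generate_transcriptome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    retro_library: Mapping[str, str] | None = None,
) -> tuple[list[Transcript], TruthTable]:
    """Draw the transcript pool: genes, retroelement transcripts, contaminants.

    Exactly ``round(n_genes * retro_fraction)`` transcripts are of
    retroelement origin (contiguous segments of library elements, optionally
    diverged) and ``round(n_genes * contaminant_fraction)`` are contaminants;
    the remainder are genes with a CDS flanked by UTRs. Lengths are drawn
    from the configured truncated normal. Deterministic given the rng state.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_retro = int(round(config.n_genes * config.retro_fraction))
    n_contam = int(round(config.n_genes * config.contaminant_fraction))
    n_gene = config.n_genes - n_retro - n_contam
    if n_retro > 0 and retro_library is None:
        retro_library = make_retro_library(rng)
    mean, sd = config.gene_length_distribution
    lo = config.min_gene_length
    hi = int(mean + 6 * sd)

    transcripts: list[Transcript] = []
    origins = ["gene"] * n_gene + ["retroelement"] * n_retro + ["contaminant"] * n_contam
    lib_items = list(retro_library.items()) if retro_library else []
    for i, origin in enumerate(origins):
        length = _trunc_normal_int(rng, mean, sd, lo, hi)
        if origin == "retroelement":
            name, element = lib_items[rng.integers(len(lib_items))]
            length = min(length, len(element))
            start = int(rng.integers(0, len(element) - length + 1))
            seq = _mutate(rng, element[start : start + length], config.retro_divergence)
        else:
            seq = _random_seq(rng, length)
        # CDS: ~10% 5'UTR, ~15% 3'UTR, in-frame length
        cds_start = int(round(0.10 * length))
        cds_len = 3 * (int(round(0.75 * length)) // 3)
        transcripts.append(
            Transcript(f"tx{i:05d}", seq, (cds_start, cds_start + cds_len), origin)
        )
    return transcripts, TruthTable()


# ---------------------------------------------------------------------------
# Marker planting
# ---------------------------------------------------------------------------

def plant_ssr(
    transcript: Transcript, motif: str, n_units: int, position: int
) -> tuple[Transcript, SSRLocus]:
    """Overwrite a window of the transcript with an SSR run and guard bases.

    The run ``motif * n_units`` is written at ``position`` and the single
    bases immediately before and after are forced to break the periodicity
    (guard bases differ from the base one unit away), so the planted locus
    is a maximal run with exactly the recorded coordinates. Transcript
    length is unchanged. Requires 1 <= position and position + run < length.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    u = len(motif)
    run = motif * n_units
    if position < 1 or position + len(run) >= len(transcript.sequence):
        raise ValueError("SSR run (with guard bases) does not fit in the transcript")
    seq = list(transcript.sequence)
    seq[position : position + len(run)] = run
    # left guard: break seq[pos-1] == seq[pos-1+u]; right guard: break
    # seq[pos+len] == seq[pos+len-u] (== motif[0])
    if seq[position - 1] == run[u - 1]:
        seq[position - 1] = "ACGT"[("ACGT".index(run[u - 1]) + 1) % 4]
    end = position + len(run)
    if seq[end] == motif[0]:
        seq[end] = "ACGT"[("ACGT".index(motif[0]) + 1) % 4]
    new = Transcript(transcript.id, "".join(seq), transcript.cds_interval, transcript.origin)
    locus = SSRLocus(transcript.id, position, end, canonical_motif(motif), u, n_units)
    return new, locus


def _random_primitive_motif(rng: np.random.Generator, u: int) -> str:
    while True:
        m = _random_seq(rng, u)
        if _is_primitive(m):
            return m


def plant_ssrs(
    transcripts: Sequence[Transcript],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[Transcript], list[SSRLocus]]:
    """Plant detectable-class SSR runs (< 50 bp) at the configured rate.

    Each transcript independently receives one run with probability
    ``ssr_plant_rate``; unit size follows ``ssr_unit_size_weights`` and the
    repeat count the configured range (the defaults keep every run under
    50 bp, the detectable marker class).
    """
    sizes = sorted(config.ssr_unit_size_weights)
    weights = np.array([config.ssr_unit_size_weights[s] for s in sizes], dtype=float)
    weights /= weights.sum()
    lo, hi = config.ssr_repeat_count_distribution
    out: list[Transcript] = []
    loci: list[SSRLocus] = []
    for t in transcripts:
        if rng.random() >= config.ssr_plant_rate:
            out.append(t)
            continue
        u = int(rng.choice(sizes, p=weights))
        n_units = int(rng.integers(lo, hi + 1))
        run_len = u * n_units
        if len(t) < run_len + 2:
            out.append(t)
            continue
        pos = int(rng.integers(1, len(t) - run_len))
        motif = _random_primitive_motif(rng, u)
        planted, locus = plant_ssr(t, motif, n_units, pos)
        out.append(planted)
        loci.append(locus)
    return out, loci


def plant_variants(
    transcripts: Sequence[Transcript],
    config: SimulationConfig,
    rng: np.random.Generator,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[HaplotypePool, list[tuple[str, int, str, str, float]]]:
    """Plant biallelic SNPs and build the chromosome pool they segregate in.

    Each position is a SNP site with probability ``snp_rate`` (positions in
    ``exclude`` intervals, e.g. planted SSR runs, are skipped). The design
    frequency is drawn from ``snp_alt_freq_choices``; the alternate allele is
    assigned to ``round(freq * n_chromosomes)`` of the chromosomes, so a read
    drawn from a uniformly chosen chromosome carries the alternate with
    probability exactly equal to the design frequency when frequencies are on
    the k/n_chromosomes grid (the default: four diploids, eight chromosomes).
    """
    for f in config.snp_alt_freq_choices:
        if not 0 < f < 1:
            raise ValueError(f"design frequency {f} outside (0, 1)")
    exclude = exclude or {}
    n_chrom = config.n_chromosomes
    haplotypes: dict[str, list[str]] = {}
    truth: list[tuple[str, int, str, str, float]] = []
    freqs = np.asarray(config.snp_alt_freq_choices)
    for t in transcripts:
        length = len(t)
        masked = np.zeros(length, dtype=bool)
        for s, e in exclude.get(t.id, ()):
            masked[s:e] = True
        is_site = (rng.random(length) < config.snp_rate) & ~masked
        positions = np.nonzero(is_site)[0]
        haps = [list(t.sequence) for _ in range(n_chrom)]
        for pos in positions:
            ref = t.sequence[pos]
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            freq = float(freqs[rng.integers(len(freqs))])
            n_alt = int(round(freq * n_chrom))
            n_alt = min(max(n_alt, 1), n_chrom - 1)
            carriers = rng.choice(n_chrom, size=n_alt, replace=False)
            for c in carriers:
                haps[c][pos] = alt
            truth.append((t.id, int(pos), ref, alt, freq))
        haplotypes[t.id] = ["".join(h) for h in haps]
    return HaplotypePool(list(transcripts), haplotypes), truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    pool: HaplotypePool,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: TruthTable | None = None,
) -> tuple[list[Read], TruthTable]:
    """Draw single-end reads from the haplotype pool.

    Source transcripts are chosen with probability proportional to length
    (uniform coverage per bp, as after cDNA normalization), lengths from the
    truncated normal read-length model, strands with probability 0.5 each,
    substitution errors at ``base_error_rate``, and per-base qualities from
    the normal quality model clipped to [2, 40] (phred+33 on output). Every
    read's origin — source transcript, offset on the reference strand, and
    strand — is recorded in the truth table; reads longer than their source
    transcript are truncated to it and flagged.
    """
    if not pool.transcripts:
        raise ValueError("empty transcript pool")
    truth = truth if truth is not None else TruthTable()
    lengths = np.array([len(t) for t in pool.transcripts], dtype=float)
    probs = lengths / lengths.sum()
    mean_len, sd_len = config.read_length_distribution
    lo, hi = config.read_length_bounds
    mean_q, sd_q = config.quality_model
    retro_ids = {t.id for t in pool.transcripts if t.origin == "retroelement"}
    reads: list[Read] = []
    n_digits = max(6, len(str(max(config.n_reads - 1, 1))))
    for i in range(config.n_reads):
        ti = int(rng.choice(len(pool.transcripts), p=probs))
        t = pool.transcripts[ti]
        rlen = _trunc_normal_int(rng, mean_len, sd_len, lo, hi)
        rid = f"read{i:0{n_digits}d}"
        if rlen > len(t):
            rlen = len(t)
            truth.truncated_read_ids.add(rid)
        haps = pool.haplotypes.get(t.id) or [t.sequence]
        hap = haps[int(rng.integers(len(haps)))]
        offset = int(rng.integers(0, len(t) - rlen + 1))
        seq = hap[offset : offset + rlen]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if config.base_error_rate > 0:
            seq = _mutate(rng, seq, config.base_error_rate)
        quals = np.clip(np.rint(rng.normal(mean_q, sd_q, rlen)), 2, 40).astype(int)
        reads.append(Read(rid, seq, quals.tolist()))
        truth.read_origins[rid] = ReadOrigin(t.id, offset, strand)
        if t.id in retro_ids:
            truth.retro_read_ids.add(rid)
    return reads, truth


# ---------------------------------------------------------------------------
# Mock annotation
# ---------------------------------------------------------------------------

_GENERIC_DESCRIPTIONS = (
    "hypothetical protein",
    "heat shock protein 70",
    "cellulose synthase catalytic subunit",
    "chlorophyll a/b binding protein",
    "ribulose bisphosphate carboxylase small chain",
    "cytochrome P450 monooxygenase",
    "ubiquitin-conjugating enzyme E2",
    "DNA polymerase delta catalytic subunit",
    "serine/threonine protein kinase",
    "pathogenesis-related protein PR-1",
)

_RETRO_DESCRIPTIONS = (
    "Ty1-copia retrotransposon polyprotein",
    "putative reverse transcriptase",
    "integrase core domain protein",
    "gag-pol polyprotein precursor",
    "gypsy-like retrotransposon pol polyprotein",
    "retroelement nucleocapsid protein",
)

_DEFAULT_TAXON_WEIGHTS = {
    # mirrors the combined-set taxonomic mixture of a conifer EST annotation
    "Conifer": 0.098, "Other plant": 0.530, "Insect": 0.090, "Fungi": 0.104,
    "Protozoa": 0.015, "Other Eukaryote": 0.144, "Bacteria": 0.017, "Virus": 0.002,
}


@dataclass
class AnnotationParams:
    """Controls for the fabricated protein hit table.

    ``hit_intercept``/``hit_slope`` parameterize the logistic probability of
    a transcript having a hit as a function of its length (defaults are the
    length-effect magnitudes typical of 454 EST annotation); retro-origin
    transcripts receive retroelement keyword descriptions with probability
    ``retro_keyword_prob``.
    """

    hit_intercept: float = -3.899
    hit_slope: float = 0.0058
    retro_hit_prob: float = 0.8
    retro_keyword_prob: float = 0.9
    accession_sharing: float = 0.3
    taxon_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXON_WEIGHTS)
    )


def fabricate_annotation_table(
    transcripts: Sequence[Transcript],
    params: AnnotationParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A mock 15-column protein hit table (outfmt-6 std + slen/staxon/stitle).

    Gene transcripts get a hit with logistic probability in their length;
    contaminants are labeled Fungi; retro transcripts get retroelement
    keyword descriptions with the configured probability. Subject lengths
    approximate CDS length / 3 and aligned subject intervals are random
    sub-spans, so downstream coverage ratios have known construction.
    """
    params = params or AnnotationParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    cats = sorted(params.taxon_weights)
    cat_w = np.array([params.taxon_weights[c] for c in cats], dtype=float)
    cat_w /= cat_w.sum()
    rows = []
    accessions: list[str] = []
    for t in transcripts:
        length = len(t)
        if t.origin == "retroelement":
            p_hit = params.retro_hit_prob
        else:
            z = params.hit_intercept + params.hit_slope * length
            p_hit = 1.0 / (1.0 + math.exp(-z))
        if rng.random() >= p_hit:
            continue
        if accessions and rng.random() < params.accession_sharing:
            acc = accessions[int(rng.integers(len(accessions)))]
        else:
            acc = f"UP{len(accessions):05d}"
            accessions.append(acc)
        if t.origin == "retroelement" and rng.random() < params.retro_keyword_prob:
            desc = _RETRO_DESCRIPTIONS[int(rng.integers(len(_RETRO_DESCRIPTIONS)))]
        else:
            desc = _GENERIC_DESCRIPTIONS[int(rng.integers(len(_GENERIC_DESCRIPTIONS)))]
        if t.origin == "contaminant":
            taxon = "Fungi"
        else:
            taxon = str(rng.choice(cats, p=cat_w))
        cds_len = t.cds_interval[1] - t.cds_interval[0]
        slen = max(50, int(round(cds_len / 3 * rng.uniform(0.8, 1.2))))
        aln_len = int(rng.integers(max(1, slen // 4), slen + 1))
        sstart = int(rng.integers(1, slen - aln_len + 2))
        send = sstart + aln_len - 1
        qstart = int(rng.integers(1, max(2, length - 3 * aln_len + 2)))
        qend = min(length, qstart + 3 * aln_len - 1)
        rows.append(
            {
                "qseqid": t.id, "sseqid": acc,
                "pident": round(rng.uniform(60, 98), 1), "length": aln_len,
                "mismatch": int(rng.integers(0, max(1, aln_len // 10))), "gapopen": 0,
                "qstart": qstart, "qend": qend, "sstart": sstart, "send": send,
                "evalue": float(10.0 ** -rng.uniform(7, 50)),
                "bitscore": round(rng.uniform(80, 400), 1),
                "slen": slen, "staxon": taxon, "stitle": desc,
            }
        )
    from .annotate_summarize import HIT_TABLE_COLUMNS_EXTENDED

    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS_EXTENDED)


def fabricate_go_assignments(
    gene_ids: Iterable[str],
    rng: np.random.Generator | None = None,
    namespace_weights: tuple[float, float, float] = (0.562, 0.253, 0.185),
    mean_terms: float = 4.0,
) -> pd.DataFrame:
    """Mock GO term assignments with a controlled namespace mixture.

    The default mixture weights molecular_function, biological_process and
    cellular_component at the proportions typical of EST-collection
    annotation; each gene gets a Poisson number of terms (at least one).
    """
    from .annotate_summarize import GO_NAMESPACES

    rng = rng if rng is not None else np.random.default_rng(0)
    w = np.asarray(namespace_weights, dtype=float)
    w /= w.sum()
    rows = []
    for gid in gene_ids:
        for _ in range(max(1, int(rng.poisson(mean_terms)))):
            rows.append(
                {
                    "query_id": gid,
                    "go_id": f"GO:{int(rng.integers(1, 10**7)):07d}",
                    "namespace": str(rng.choice(GO_NAMESPACES, p=w)),
                }
            )
    return pd.DataFrame(rows, columns=["query_id", "go_id", "namespace"])


# ---------------------------------------------------------------------------
# Orchestration and I/O
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Run the full generator: transcripts, markers, reads, mock annotation."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    retro_library = make_retro_library(rng) if config.retro_fraction > 0 else {}
    transcripts, truth = generate_transcriptome(config, rng, retro_library or None)
    transcripts, truth.planted_ssrs = plant_ssrs(transcripts, config, rng)
    ssr_intervals: dict[str, list[tuple[int, int]]] = {}
    for locus in truth.planted_ssrs:
        ssr_intervals.setdefault(locus.seq_id, []).append((locus.start, locus.end))
    pool, truth.planted_snps = plant_variants(transcripts, config, rng, exclude=ssr_intervals)
    reads, truth = simulate_reads(pool, config, rng, truth)
    annotation = fabricate_annotation_table(transcripts, AnnotationParams(), rng)
    gene_ids = sorted(set(annotation["qseqid"]))
    go = fabricate_go_assignments(gene_ids, rng)
    return SimulationResult(
        config=config,
        transcripts=transcripts,
        retro_library=retro_library,
        pool=pool,
        reads=reads,
        truth=truth,
        annotation=annotation,
        go_assignments=go,
    )


def write_transcripts_fasta(transcripts: Iterable[Transcript], handle) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id,
                  description=f"origin={t.origin} cds={t.cds_interval[0]}-{t.cds_interval[1]}")
        for t in transcripts
    ]
    SeqIO.write(records, handle, "fasta")


def write_truth_tables(truth: TruthTable, prefix: str) -> None:
    """Write the truth table as documented TSVs next to ``prefix``."""
    pd.DataFrame(
        [
            {"read_id": rid, "transcript_id": o.transcript_id, "offset": o.offset,
             "strand": o.strand, "retro_origin": int(rid in truth.retro_read_ids),
             "truncated": int(rid in truth.truncated_read_ids)}
            for rid, o in truth.read_origins.items()
        ]
    ).to_csv(f"{prefix}.read_origins.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"seq_id": l.seq_id, "start": l.start, "end": l.end, "motif": l.motif,
             "unit_size": l.unit_size, "n_units": l.n_units}
            for l in truth.planted_ssrs
        ]
    ).to_csv(f"{prefix}.planted_ssrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.planted_snps,
        columns=["transcript_id", "position", "ref", "alt", "design_frequency"],
    ).to_csv(f"{prefix}.planted_snps.tsv", sep="\t", index=False)
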