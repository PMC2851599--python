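"""Annotation and coverage summaries for an assembled EST collection.

Consumes tabular similarity-search results (BLAST outfmt-6 dialect, 12 or 15
columns) and GO assignments, and computes the summaries used to characterize
a transcriptome: best hit per query, unique protein accessions, taxonomy
breakdown, GO namespace proportions, a logistic model of hit presence versus
sequence length, per-query and summed ortholog coverage, a back-of-envelope
transcriptome coverage estimate, and basic assembly statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "HIT_TABLE_COLUMNS",
    "HIT_TABLE_COLUMNS_EXTENDED",
    "read_hit_table",
    "write_hit_table",
    "best_hits",
    "unique_accession_count",
    "taxon_breakdown",
    "go_namespace_proportions",
    "hit_length_logistic",
    "LogisticSummary",
    "SeparationError",
    "ortholog_coverage",
    "transcriptome_coverage_estimate",
    "assembly_summary",
    "AssemblySummary",
]

#: Standard 12 BLAST tabular columns (outfmt 6).
HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
#: Extended dialect carrying subject length, taxon label and description
#: (outfmt "6 std slen staxids stitle" style).
HIT_TABLE_COLUMNS_EXTENDED = HIT_TABLE_COLUMNS + ["slen", "staxon", "stitle"]

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

TAXON_CATEGORIES = (
    "Conifer", "Other plant", "Insect", "Fungi",
    "Protozoa", "Other Eukaryote", "Bacteria", "Virus",
)


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12- or 15-column tab-separated hit table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 12:
        df.columns = HIT_TABLE_COLUMNS
    elif df.shape[1] == 15:
        df.columns = HIT_TABLE_COLUMNS_EXTENDED
    else:
        raise ValueError(
            f"{path}: expected 12 or 15 tab-separated columns, found {df.shape[1]}"
        )
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = df[col].astype(int)
    if "slen" in df.columns:
        df["slen"] = df["slen"].astype(int)
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    cols = HIT_TABLE_COLUMNS_EXTENDED if "slen" in df.columns else HIT_TABLE_COLUMNS
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Best hits and annotation breakdowns
# ---------------------------------------------------------------------------

def best_hits(records: pd.DataFrame, max_evalue: float = 1e-6) -> pd.DataFrame:
    """One best record per query: E <= threshold, lowest E, then highest bit
    score, then lexicographically smallest accession (a total order, so the
    result is independent of input row order)."""
    kept = records[records["evalue"] <= max_evalue]
    if kept.empty:
        return kept.copy()
    ordered = kept.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def unique_accession_count(best: pd.DataFrame) -> int:
    """Number of distinct subject accessions among the best hits."""
    return 0 if best.empty else int(best["sseqid"].nunique())


def taxon_breakdown(
    best: pd.DataFrame,
    taxon_category_map: Mapping[str, str],
    precision: int = 1,
) -> pd.DataFrame:
    """Counts and percentages of best hits per taxonomic category.

    ``taxon_category_map`` maps taxon labels (the ``staxon`` column) to the
    reporting categories; unmapped labels are tallied under "Unclassified"
    with a warning. Percentages are of the categorized (non-Unclassified)
    total, at ``precision`` decimals.
    """
    cats = []
    for label in best.get("staxon", pd.Series(dtype=str)):
        cat = taxon_category_map.get(label)
        if cat is None:
            logger.warning("taxon label %r not in category map; counting as Unclassified", label)
            cat = "Unclassified"
        cats.append(cat)
    counts = pd.Series(cats, dtype=str).value_counts()
    classified_total = int(counts.drop("Unclassified", errors="ignore").sum())
    rows = []
    for cat in list(TAXON_CATEGORIES) + ["Unclassified"]:
        n = int(counts.get(cat, 0))
        if cat == "Unclassified" and n == 0:
            continue
        pct = round(100.0 * n / classified_total, precision) if classified_total else 0.0
        rows.append({"category": cat, "count": n, "percent": pct if cat != "Unclassified" else float("nan")})
    return pd.DataFrame(rows)


def go_namespace_proportions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of GO term assignments per namespace (1 decimal).

    ``assignments`` needs columns ``query_id``, ``go_id``, ``namespace``; the
    denominator is the total number of term assignments (a gene may carry
    many terms).
    """
    bad = set(assignments["namespace"]) - set(GO_NAMESPACES)
    if bad:
        raise ValueError(f"unknown GO namespaces: {sorted(bad)}")
    total = len(assignments)
    rows = []
    for ns in GO_NAMESPACES:
        n = int((assignments["namespace"] == ns).sum())
        rows.append(
            {"namespace": ns, "count": n,
             "percent": round(100.0 * n / total, 1) if total else 0.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hit-vs-length logistic model
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """The logistic fit is degenerate (one class, or perfect separation)."""


@dataclass
class LogisticSummary:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_value_slope: float
    n: int


def hit_length_logistic(
    has_hit: Sequence[int] | Sequence[bool], lengths: Sequence[float]
) -> LogisticSummary:
    """Maximum-likelihood logistic regression of hit presence on sequence length.

    Models P(hit) = expit(intercept + slope x length) — the standard check
    that longer assembled sequences are more likely to have a protein match.
    Raises :class:`SeparationError` when only one class is present or the
    classes are perfectly separated.
    """
    y = np.asarray(has_hit, dtype=float)
    x = np.asarray(lengths, dtype=float)
    if y.min() == y.max():
        raise SeparationError("all sequences are in one hit class")
    X = sm.add_constant(x)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # PerfectSeparationError and kin
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("fit did not converge (likely separation)")
    if not np.all(np.isfinite(fit.bse)):
        raise SeparationError("non-finite standard errors (separation)")
    # fitted probabilities pinned to 0/1 for every observation => separation
    p = fit.predict(X)
    if np.all((p < 1e-8) | (p > 1 - 1e-8)):
        raise SeparationError("perfect separation detected")
    return LogisticSummary(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        p_value_slope=float(fit.pvalues[1]),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Ortholog coverage
# ---------------------------------------------------------------------------

def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def ortholog_coverage(
    best: pd.DataFrame,
    query_lengths: Mapping[str, int],
    divide_by_three: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-query length ratios and per-subject summed coverage.

    Ratio = query length (nt) / subject length, with the subject residue
    length multiplied by 3 when ``divide_by_three`` (nucleotide vs protein
    convention; ratios above 1 typically reflect UTR sequence in the query).
    Summed coverage per subject = |union of aligned subject intervals across
    all queries| / subject length, capped at 1. Subject intervals in the hit
    table are 1-based inclusive (BLAST convention) and are converted here.
    Requires the extended table (``slen`` column).
    """
    if "slen" not in best.columns:
        raise ValueError("ortholog coverage requires the extended hit table (slen column)")
    if (best["slen"] <= 0).any():
        raise ValueError("zero or negative subject length in hit table")
    denom = 3.0 if divide_by_three else 1.0
    ratios = pd.DataFrame(
        {
            "qseqid": best["qseqid"],
            "sseqid": best["sseqid"],
            "ratio": [
                query_lengths[q] / (denom * s)
                for q, s in zip(best["qseqid"], best["slen"])
            ],
        }
    )
    per_subject = []
    for sseqid, group in best.groupby("sseqid"):
        slen = int(group["slen"].iloc[0])
        intervals = [
            (min(a, b) - 1, max(a, b)) for a, b in zip(group["sstart"], group["send"])
        ]
        covered = min(_interval_union_length(intervals), slen)
        per_subject.append(
            {"sseqid": sseqid, "slen": slen, "covered": covered,
             "coverage": covered / slen, "n_queries": len(group)}
        )
    return ratios, pd.DataFrame(per_subject)


def transcriptome_coverage_estimate(
    n_reads: int,
    mean_read_len: float,
    n_genes: int = 25_000,
    mean_gene_len: float = 2_000,
) -> float:
    """Expected fold coverage of the transcriptome, to 1 decimal.

    (total sequenced bp) / (transcriptome size), with the Arabidopsis-scale
    defaults of 25,000 genes averaging 2,000 bp.
    """
    denom = n_genes * mean_gene_len
    if denom <= 0 or n_reads < 0 or mean_read_len < 0:
        raise ValueError("inputs must be positive")
    return round(n_reads * mean_read_len / denom, 1)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblySummary:
    n_contigs: int
    mean_length: float
    length_quantiles: dict[float, float]  # deciles 0.0 .. 1.0
    n_over_800bp: int
    reads_per_contig: dict[str, int]
    depth_per_contig: dict[str, float]  # sum of aligned bp / contig length


def assembly_summary(
    contig_lengths: Mapping[str, int],
    placements: Iterable | None = None,
    long_threshold: int = 800,
) -> AssemblySummary:
    """Contig count/length statistics plus per-contig read counts and depth.

    ``n_over_800bp`` uses a strict > threshold. Depth for a contig is the
    summed aligned read length divided by the contig length (0 when no reads
    are placed, or when no placements are supplied).
    """
    if not contig_lengths:
        raise ValueError("empty contig set")
    lengths = np.array(list(contig_lengths.values()), dtype=float)
    quantiles = {
        round(q, 1): float(np.quantile(lengths, q)) for q in np.linspace(0, 1, 11)
    }
    reads_per = {cid: 0 for cid in contig_lengths}
    aligned_bp = {cid: 0 for cid in contig_lengths}
    if placements is not None:
        for p in placements:
            reads_per[p.ref_id] += 1
            aligned_bp[p.ref_id] += len(p.aligned_sequence)
    depth_per = {cid: aligned_bp[cid] / contig_lengths[cid] for cid in contig_lengths}
    return AssemblySummary(
        n_contigs=len(contig_lengths),
        mean_length=float(lengths.mean()),
        length_quantiles=quantiles,
        n_over_800bp=int((lengths > long_threshold).sum()),
        reads_per_contig=reads_per,
        depth_per_contig=depth_per,
    )
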