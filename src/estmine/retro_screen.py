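"""Retroelement screening of EST reads and contigs.

Identifies retrotransposon-like sequences two ways: by nucleotide similarity
to a library of complete retroelement sequences (conifer elements such as
IFG7, PpRT1 and Gymny, plus other plant copia/gypsy-like elements), and by
keyword matching against protein annotation descriptions. Also computes
per-EST-collection retroelement abundance percentages and the proportion of
retro-matched contigs whose best protein hit is *not* a retroelement product
(a signal of retroelement fragments embedded in ordinary genes).

The internal similarity screen (k-mer seed, ungapped extension, aligned
length >= 50 bp at >= 80% identity) is a portable stand-in for a BLASTn
search at E <= 1e-6, whose E-values depend on database size; external-table
mode consumes a real BLAST tabular output for exact parity.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ssr_markers import revcomp

__all__ = [
    "RETRO_KEYWORDS",
    "AbundanceRow",
    "KmerScreen",
    "similarity_screen",
    "keyword_classify",
    "abundance_table",
    "classify_retro_contigs",
]

#: Annotation terms marking retroelement-associated proteins. "pol" and "gag"
#: are matched as standalone words only (so "polymerase" never matches).
RETRO_KEYWORDS = (
    "copia",
    "gag",
    "pol",
    "retroelement",
    "integrase",
    "reverse transcriptase",
    "retrotransposon",
)

_KEYWORD_RE = re.compile(
    r"\b(" + "|".join(k.replace(" ", r"\s+") for k in RETRO_KEYWORDS) + r")\b",
    re.IGNORECASE,
)


def keyword_classify(description: str) -> str:
    """Classify an annotation description as ``"retro"`` or ``"non_retro"``.

    Case-insensitive whole-word matching against :data:`RETRO_KEYWORDS`;
    substring hits inside longer words (e.g. "pol" in "polymerase") do not
    count.
    """
    return "retro" if _KEYWORD_RE.search(description or "") else "non_retro"


# ---------------------------------------------------------------------------
# Similarity screen
# ---------------------------------------------------------------------------

class KmerScreen:
    """Seeded ungapped similarity screen against a retroelement library.

    A query matches when some library element shares an exact ``k``-mer with
    it (either strand) and the seed extends on its diagonal to a stretch of
    at least ``min_len`` aligned bases at >= ``min_identity`` identity.
    Extension is greedy from the seed in both directions, tolerating
    mismatches while the running identity of the extended arm stays at or
    above the threshold.
    """

    def __init__(
        self,
        library: Mapping[str, str],
        k: int = 11,
        min_len: int = 50,
        min_identity: float = 0.80,
    ) -> None:
        if not library:
            raise ValueError("retroelement library is empty")
        if len(set(library)) != len(library):
            raise ValueError("library names must be unique")
        self.library = {name: seq.upper() for name, seq in library.items()}
        self.k = k
        self.min_len = min_len
        self.min_identity = min_identity
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.library.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((name, i))

    def _extend(self, query: str, lib_seq: str, qpos: int, lpos: int) -> int:
        """Longest >=identity stretch through the seed on this diagonal (bp)."""
        ident = self.min_identity
        # right arm (includes the seed itself); scan the whole diagonal
        # overlap so isolated mismatch clusters cannot hide a long match
        matches = length = 0
        best_right = 0
        q, l = qpos, lpos
        while q < len(query) and l < len(lib_seq):
            matches += query[q] == lib_seq[l]
            length += 1
            if matches >= ident * length:
                best_right = length
            q += 1
            l += 1
        # left arm
        matches = length = 0
        best_left = 0
        q, l = qpos - 1, lpos - 1
        while q >= 0 and l >= 0:
            matches += query[q] == lib_seq[l]
            length += 1
            if matches >= ident * length:
                best_left = length
            q -= 1
            l -= 1
        return best_left + best_right

    def matches(self, query: str) -> bool:
        query = query.upper()
        for oriented in (query, revcomp(query)):
            seen_diagonals: set[tuple[str, int]] = set()
            for i in range(0, len(oriented) - self.k + 1):
                for name, pos in self._index.get(oriented[i : i + self.k], ()):
                    diag = (name, pos - i)
                    if diag in seen_diagonals:
                        continue
                    seen_diagonals.add(diag)
                    if self._extend(oriented, self.library[name], i, pos) >= self.min_len:
                        return True
        return False


def similarity_screen(
    sequences: Mapping[str, str],
    library: Mapping[str, str] | None = None,
    mode: str = "internal",
    hit_table: pd.DataFrame | None = None,
    max_evalue: float = 1e-6,
    **screen_kwargs,
) -> set[str]:
    """Ids of sequences similar to the retroelement library.

    ``mode="internal"`` runs the built-in :class:`KmerScreen`;
    ``mode="external-table"`` consumes a 12-column BLAST tabular hit table
    (query ids in column ``qseqid``) filtered at E <= ``max_evalue``.
    """
    if mode == "internal":
        if not library:
            raise ValueError("retroelement library is empty")
        screen = KmerScreen(library, **screen_kwargs)
        return {sid for sid, seq in sequences.items() if screen.matches(seq)}
    if mode == "external-table":
        if hit_table is None:
            raise ValueError("external-table mode requires a hit table")
        kept = hit_table[hit_table["evalue"] <= max_evalue]
        return set(kept["qseqid"]) & set(sequences)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Abundance and contig classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceRow:
    """Retroelement abundance in one EST collection."""

    collection: str
    n_ests: int
    n_matching: int
    percent: float  # 100 * n_matching / n_ests, 4 decimals


def abundance_table(
    collections: Mapping[str, tuple[int, int | Iterable[str]]]
) -> list[AbundanceRow]:
    """Per-collection retroelement abundance: name -> (n_ests, matched count or ids).

    Percent is 100 x n_matching / n_ests rounded to 4 decimals, the precision
    at which such cross-collection comparisons are reported.
    """
    rows = []
    for name, (n_ests, matched) in collections.items():
        if n_ests <= 0:
            raise ValueError(f"collection {name!r}: n_ests must be positive")
        n_matching = matched if isinstance(matched, int) else len(set(matched))
        if not 0 <= n_matching <= n_ests:
            raise ValueError(f"collection {name!r}: matching count out of range")
        rows.append(AbundanceRow(name, n_ests, n_matching, round(100.0 * n_matching / n_ests, 4)))
    return rows


def abundance_to_tsv(rows: Sequence[AbundanceRow]) -> str:
    lines = ["collection\tn_ests\tn_matching_retro\tpercent"]
    for r in rows:
        lines.append(f"{r.collection}\t{r.n_ests}\t{r.n_matching}\t{r.percent:.4f}")
    return "\n".join(lines) + "\n"


def classify_retro_contigs(
    retro_contig_ids: Iterable[str],
    protein_hit_table: pd.DataFrame,
    max_evalue: float = 1e-4,
) -> dict:
    """Proportion of retro-matched contigs whose best protein hits are non-retro.

    Takes the contigs built from retroelement-similar reads and their protein
    hit table (BLASTx-style, E threshold 1e-4 by default). The best hit per
    contig (lowest E, ties by bit score) is reduced to its unique protein
    accessions, and each accession's description is classified by
    :func:`keyword_classify` — an automated proxy for manual protein-database
    inspection, flagged as such in the output. Returns counts and the percent
    of unique proteins that are not retroelement products (1 decimal).
    """
    from .annotate_summarize import best_hits  # local import avoids a cycle

    ids = set(retro_contig_ids)
    best = best_hits(protein_hit_table, max_evalue=max_evalue)
    best = best[best["qseqid"].isin(ids)]
    if "stitle" not in best.columns:
        raise ValueError("protein hit table lacks description column 'stitle'")
    per_accession = best.drop_duplicates("sseqid")
    n_unique = len(per_accession)
    n_non_retro = int(
        (per_accession["stitle"].map(keyword_classify) == "non_retro").sum()
    )
    return {
        "n_contigs_with_hits": int(best["qseqid"].nunique()),
        "n_unique_proteins": n_unique,
        "n_non_retro": n_non_retro,
        "percent_non_retro": round(100.0 * n_non_retro / n_unique, 1) if n_unique else 0.0,
        "method": "automated keyword classification",
    }
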