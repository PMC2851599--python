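"""Independent brute-force oracles used to verify the implementation.

These deliberately re-derive results from first principles (triple
enumeration, interval stabbing, full scans) rather than sharing code with
the package.
"""

from __future__ import annotations


def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def _canon(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def ssr_oracle(seq, unit_sizes=(2, 3, 4), min_units=4, max_len_bp=None, seq_id=""):
    """Enumerate every (start, unit size, unit count) triple and keep maximal,
    primitive, left-anchored runs.

    A candidate start ``a`` must begin a periodic region (either a == 0 or
    position a-1 breaks the period); the count is grown unit by unit while
    the next full unit repeats; the resulting run is kept if it has enough
    units, a primitive unit, and (optionally) a length under the cap.
    """
    seq = seq.upper()
    n = len(seq)
    found = []
    for u in unit_sizes:
        for a in range(0, n - u * min_units + 1):
            # region-start condition: periodicity must not extend through a-1
            if a > 0 and a - 1 + u < n and seq[a - 1] != "N" and seq[a - 1] == seq[a - 1 + u]:
                continue
            unit = seq[a : a + u]
            if "N" in unit or not _primitive(unit):
                continue
            count = 1
            while True:
                nxt = seq[a + u * count : a + u * (count + 1)]
                prev = seq[a + u * (count - 1) : a + u * count]
                if len(nxt) == u and "N" not in nxt and nxt == prev:
                    count += 1
                else:
                    break
            if count >= min_units and (max_len_bp is None or u * count < max_len_bp):
                found.append((seq_id, a, a + u * count, _canon(unit), u, count))
    return sorted(found, key=lambda t: (t[1], t[2], t[4]))


def pileup_depth_oracle(placements, ref_id, position):
    """Interval-stabbing count: how many placements cover the position."""
    return sum(
        1
        for p in placements
        if p.ref_id == ref_id and p.ref_start <= position < p.ref_start + len(p.aligned_sequence)
    )


def snp_call_oracle(ref_base, counts, min_depth, min_alt_freq):
    """Apply the depth/frequency thresholds to one column's A/C/G/T counts.

    Returns (alt, depth, freq) or None.
    """
    acgt = {b: c for b, c in counts.items() if b in "ACGT" and c > 0}
    depth = sum(acgt.values())
    if depth < min_depth:
        return None
    alts = {b: c for b, c in acgt.items() if b != ref_base}
    if not alts:
        return None
    top = max(alts.values())
    alt = min(b for b, c in alts.items() if c == top)
    freq = top / depth
    if freq >= min_alt_freq - 1e-12:
        return (alt, depth, freq)
    return None


def best_hit_oracle(rows, max_evalue):
    """Full scan: per query, the row minimizing (evalue, -bitscore, sseqid)."""
    best = {}
    for row in rows:
        if row["evalue"] > max_evalue:
            continue
        q = row["qseqid"]
        key = (row["evalue"], -row["bitscore"], row["sseqid"])
        if q not in best or key < best[q][0]:
            best[q] = (key, row)
    return {q: row for q, (_, row) in best.items()}


def interval_union_oracle(intervals):
    """Membership-set size of the union of half-open integer intervals."""
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered)
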