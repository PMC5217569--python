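"""Brute-force reference implementations used only to check the package.

Each oracle re-derives a result by direct enumeration, independently of the
code paths it validates.
"""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_cytosines(name: str, seq: str) -> list[tuple[str, int, str, str]]:
    """Two-strand scan for cytosines with 5'->3' dinucleotide context."""
    ctx_plus = {"G": "CpG", "A": "CpA", "T": "CpT", "C": "CpC"}
    ctx_minus = {"C": "CpG", "T": "CpA", "A": "CpT", "G": "CpC"}
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            nxt = seq[i + 1] if i + 1 < len(seq) else None
            out.append((name, i, "+", ctx_plus.get(nxt, "unknown")))
        if b == "G":
            prv = seq[i - 1] if i > 0 else None
            out.append((name, i, "-", ctx_minus.get(prv, "unknown")))
    out.sort(key=lambda r: (r[1], r[2]))
    return out


def _reduce(seq: str, reduction: str) -> str:
    return seq.replace("C", "T") if reduction == "CT" else seq.replace("G", "A")


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def brute_align(read_bases: str, reduction: str, genome, params):
    """Exhaustive all-positions, all-views three-letter alignment.

    Returns (status, chrom, plus_pos, view, mismatches) with plus_pos the
    0-based plus-strand start of the covered interval.
    """
    rred = _reduce(read_bases.upper(), reduction)
    rlen = len(rred)
    hits = []
    for chrom, seq in genome:
        L = len(seq)
        for orient in "+-":
            src = seq if orient == "+" else brute_revcomp(seq)
            ref = _reduce(src, reduction)
            for p in range(L - rlen + 1):
                seg = ref[p : p + rlen]
                seed_mm = _mismatches(seg[: params.seed_len], rred[: params.seed_len])
                if seed_mm > params.seed_mismatch_max:
                    continue
                mm = seed_mm + _mismatches(
                    seg[params.seed_len :], rred[params.seed_len :]
                )
                if mm <= params.total_mismatch_max:
                    plus_pos = p if orient == "+" else L - p - rlen
                    hits.append((mm, chrom, plus_pos, reduction + orient))
    if not hits:
        return ("unmapped", None, None, None, None)
    best = min(h[0] for h in hits)
    winners = [h for h in hits if h[0] == best]
    if len(winners) > 1:
        return ("ambiguous", None, None, None, None)
    mm, chrom, pos, view = winners[0]
    return ("unique", chrom, pos, view, mm)


def brute_weighted_level(counts: list[tuple[int, int]]) -> float:
    """One-pass pooled ratio over (meth, unmeth) pairs, in percent."""
    meth = sum(m for m, _ in counts)
    total = sum(m + u for m, u in counts)
    return 100.0 * meth / total


def brute_pmds(window_rows, min_covered=10, threshold=70.0, min_length=100_000):
    """Re-derive PMD intervals from per-window (chrom, start, end,
    n_covered, level) rows by direct scanning."""
    out = []
    run = []

    def flush():
        if run and run[-1][2] - run[0][1] > min_length:
            out.append((run[0][0], run[0][1], run[-1][2]))
        run.clear()

    for chrom, start, end, n_cov, level in window_rows:
        ok = level is not None and n_cov >= min_covered and level < threshold
        if ok and run and run[0][0] == chrom and run[-1][2] == start:
            run.append((chrom, start, end))
        else:
            flush()
            if ok:
                run.append((chrom, start, end))
    flush()
    return out


def brute_drops(quals: list[int], threshold: int = 10) -> list[int]:
    """Pairwise scan for adjacent-cycle quality drops."""
    return [
        i
        for i in range(1, len(quals))
        if quals[i - 1] - quals[i] > threshold
    ]
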