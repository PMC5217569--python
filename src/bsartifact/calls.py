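"""Per-cytosine methylation extraction and weighted levels.

A uniquely aligned read reports on the cytosines of the strand it derives
from.  On the converted-strand views (CT+/CT-) the read base at a cytosine
is C (methylated, conversion-protected) or T (unmethylated, converted); on
the complementary views (GA+/GA-) the partner bases are G (methylated) and
A (unmethylated).  Any other base is a sequencing or base-calling mismatch
and yields *no call* — it is dropped, not counted as unmethylated, which is
what lets a G-undercalled-as-A artifact depress the level exactly as the
closed form m(1-q) predicts while other miscalls merely lose coverage.

All levels are *weighted*: total methylated calls over total calls across
the selected cytosines, i.e. deeper-covered sites weigh more — not a mean
of per-site levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord, TrimRule
from .genome import CONTEXT_NAMES, NONCPG_CODES, CytosineIndex
from .simulate import BisulfiteRead

_MATE_I = {"R1": 0, "R2": 1}
_BASE_I = {"A": 0, "C": 1, "G": 2, "T": 3}

# view -> (target strand, methylated base, unmethylated base, read runs along minus)
VIEW_RULES = {
    "CT+": ("+", ord("C"), ord("T"), False),
    "GA-": ("+", ord("G"), ord("A"), True),
    "CT-": ("-", ord("C"), ord("T"), True),
    "GA+": ("-", ord("G"), ord("A"), False),
}

_CONTEXT_SEL = {name: (code,) for code, name in enumerate(CONTEXT_NAMES)}
_CONTEXT_SEL["non-CpG"] = tuple(NONCPG_CODES)


class ZeroCoverageError(ValueError):
    """Raised when a level is requested over a selection with no calls."""


class CytosineCallTable:
    """Mate-stratified methylated/unmethylated counts per indexed cytosine."""

    def __init__(self, index: CytosineIndex):
        self.index = index
        # (cytosine, mate, state) with state 0=methylated, 1=unmethylated
        self.counts = np.zeros((len(index), 2, 2), dtype=np.int64)
        # observed base tallies (A,C,G,T) over call-yielding positions per mate
        self.base_counts = np.zeros((2, 4), dtype=np.int64)

    # -- accumulation ------------------------------------------------------

    def add_alignment(
        self,
        rec: AlignmentRecord,
        read: BisulfiteRead,
        exclude: np.ndarray | None = None,
    ) -> np.ndarray:
        """Accumulate calls from one unique alignment; returns the flat
        cytosine indices that yielded a call (for overlap dedup)."""
        if rec.status != "unique":
            raise ValueError("only unique alignments yield methylation calls")
        if rec.chrom not in self.index.chrom_lengths:
            raise KeyError(f"alignment on unknown chromosome {rec.chrom!r}")
        strand, mb, ub, reverse = VIEW_RULES[rec.view]
        rlen = len(read.bases)
        pos_arr, flat_arr = self.index.strand_positions(rec.chrom, strand)
        lo, hi = np.searchsorted(pos_arr, [rec.pos, rec.pos + rlen])
        if lo == hi:
            return np.empty(0, np.int64)
        ps = pos_arr[lo:hi]
        flat = flat_arr[lo:hi]
        offs = (rec.pos + rlen - 1) - ps if reverse else ps - rec.pos
        bases = np.frombuffer(read.bases.encode(), np.uint8)[offs]
        meth = bases == mb
        unmeth = bases == ub
        if exclude is not None and len(exclude):
            keep = ~np.isin(flat, exclude)
            meth &= keep
            unmeth &= keep
        mi = _MATE_I[read.mate]
        self.counts[flat[meth], mi, 0] += 1
        self.counts[flat[unmeth], mi, 1] += 1
        called = meth | unmeth
        for b in np.frombuffer(bases[called].tobytes(), np.uint8):
            self.base_counts[mi, _BASE_I[chr(b)]] += 1
        return flat[called]

    def merge(self, other: "CytosineCallTable") -> "CytosineCallTable":
        if other.index is not self.index and len(other.index) != len(self.index):
            raise ValueError("call tables built on different cytosine indexes")
        out = CytosineCallTable(self.index)
        out.counts = self.counts + other.counts
        out.base_counts = self.base_counts + other.base_counts
        return out

    # -- selection and levels ----------------------------------------------

    def _select(
        self,
        context: str | None,
        region: tuple[str, int, int] | None,
    ) -> np.ndarray:
        mask = np.ones(len(self.index), dtype=bool)
        if context is not None:
            codes = _CONTEXT_SEL.get(context)
            if codes is None:
                raise ValueError(f"unknown context {context!r}")
            mask &= np.isin(self.index.context, codes)
        if region is not None:
            chrom, start, end = region
            ci = self.index.chroms.index(chrom)
            mask &= (
                (self.index.chrom_id == ci)
                & (self.index.pos >= start)
                & (self.index.pos < end)
            )
        return mask

    def counts_for(
        self,
        context: str | None = "CpG",
        mate: str = "both",
        region: tuple[str, int, int] | None = None,
    ) -> tuple[int, int]:
        """(methylated, total) calls over a selection."""
        mask = self._select(context, region)
        c = self.counts[mask]
        if mate in _MATE_I:
            c = c[:, _MATE_I[mate], :]
            return int(c[:, 0].sum()), int(c.sum())
        return int(c[:, :, 0].sum()), int(c.sum())

    def coverage(self, context: str | None = "CpG") -> np.ndarray:
        """Per-cytosine total calls (mates pooled) over the full index,
        zeroed outside the selected context."""
        cov = self.counts.sum(axis=(1, 2))
        if context is not None:
            cov = np.where(self._select(context, None), cov, 0)
        return cov

    def to_dataframe(self) -> pd.DataFrame:
        idx = self.index
        return pd.DataFrame(
            {
                "chrom": np.array(idx.chroms, dtype=object)[idx.chrom_id],
                "pos": idx.pos,
                "strand": np.array(["+", "-"])[idx.strand],
                "context": np.array(CONTEXT_NAMES)[idx.context],
                "meth_r1": self.counts[:, 0, 0],
                "unmeth_r1": self.counts[:, 0, 1],
                "meth_r2": self.counts[:, 1, 0],
                "unmeth_r2": self.counts[:, 1, 1],
            }
        )


def extract_calls(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[BisulfiteRead],
    index: CytosineIndex,
    dedup_overlap: bool = False,
) -> CytosineCallTable:
    """Accumulate calls from unique alignments only.

    With ``dedup_overlap`` the region where both mates of a pair cover the
    same cytosine is counted once, preferring R1.
    """
    by_key = {(r.id, r.mate): r for r in reads}
    table = CytosineCallTable(index)
    unique = [a for a in alignments if a.status == "unique"]
    if not dedup_overlap:
        for rec in unique:
            read = by_key.get((rec.read_id, rec.mate))
            if read is None:
                raise KeyError(f"alignment refers to unknown read {rec.read_id}/{rec.mate}")
            table.add_alignment(rec, read)
        return table
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in unique:
        by_id.setdefault(rec.read_id, []).append(rec)
    for rid, recs in by_id.items():
        recs.sort(key=lambda r: r.mate)  # R1 first
        seen = np.empty(0, np.int64)
        for rec in recs:
            read = by_key.get((rec.read_id, rec.mate))
            if read is None:
                raise KeyError(f"alignment refers to unknown read {rec.read_id}/{rec.mate}")
            called = table.add_alignment(rec, read, exclude=seen if rec.mate == "R2" else None)
            seen = np.union1d(seen, called)
    return table


def weighted_level(
    table: CytosineCallTable,
    context: str | None = "CpG",
    mate: str = "both",
    region: tuple[str, int, int] | None = None,
) -> float:
    """Depth-weighted methylation level in percent:
    100 * sum(meth) / sum(meth + unmeth) over the selected cytosines."""
    meth, total = table.counts_for(context, mate, region)
    if total == 0:
        raise ZeroCoverageError(
            f"no calls for context={context!r} mate={mate!r} region={region!r}"
        )
    return 100.0 * meth / total


@dataclass(frozen=True)
class LevelReport:
    global_cpg: float
    cpg_r1: float
    cpg_r2: float
    r1_r2_gap: float  # percentage points, R1 - R2
    noncpg: float
    cpa: float
    cpt: float
    cpc: float
    g_fraction_r1: float  # share of G among R1 call-yielding bases

    def as_dict(self) -> dict:
        return {
            "global_cpg": self.global_cpg,
            "cpg_r1": self.cpg_r1,
            "cpg_r2": self.cpg_r2,
            "r1_r2_gap": self.r1_r2_gap,
            "noncpg": self.noncpg,
            "cpa": self.cpa,
            "cpt": self.cpt,
            "cpc": self.cpc,
            "g_fraction_r1": self.g_fraction_r1,
        }


def level_report(table: CytosineCallTable) -> LevelReport:
    """Global CpG levels (pooled and per mate), non-CpG levels by context,
    the R1-R2 gap, and the R1 G fraction."""
    r1 = weighted_level(table, "CpG", "R1")
    r2 = weighted_level(table, "CpG", "R2")
    r1_calls = int(table.base_counts[0].sum())
    if r1_calls == 0:
        raise ZeroCoverageError("no R1 calls")
    return LevelReport(
        global_cpg=weighted_level(table, "CpG", "both"),
        cpg_r1=r1,
        cpg_r2=r2,
        r1_r2_gap=r1 - r2,
        noncpg=weighted_level(table, "non-CpG", "both"),
        cpa=weighted_level(table, "CpA", "both"),
        cpt=weighted_level(table, "CpT", "both"),
        cpc=weighted_level(table, "CpC", "both"),
        g_fraction_r1=float(table.base_counts[0, 2]) / r1_calls,
    )


# ------------------------------------------------------- truth-based calls

def truth_alignment(
    read: BisulfiteRead, trim: TrimRule | None = None
) -> AlignmentRecord:
    """Derive the alignment a read *should* have from its simulation
    provenance — used to measure artifact effects without running the
    aligner, and to check aligner output against truth."""
    if read.truth is None:
        raise ValueError("read carries no truth provenance")
    t = read.truth
    rl = len(read.bases) + (trim.trim5 + trim.trim3 if trim else 0)
    t5 = trim.trim5 if trim else 0
    t3 = trim.trim3 if trim else 0
    forward = (read.protocol == "PBAT") == (read.mate == "R2")
    s, f = t.frag_start, t.frag_len
    if t.strand == "+":
        if forward:
            pos, view = s + t5, "CT+"
        else:
            pos, view = s + f - rl + t3, "GA-"
    else:
        if forward:
            pos, view = s + f - rl + t3, "CT-"
        else:
            pos, view = s + t5, "GA+"
    return AlignmentRecord(read.id, read.mate, "unique", t.chrom, pos, view, 0)


def extract_calls_truth(
    reads: Sequence[BisulfiteRead],
    index: CytosineIndex,
    trim: TrimRule | None = None,
) -> CytosineCallTable:
    """Call table built from provenance instead of alignment (reads are
    assumed untrimmed unless a rule is given, matching the simulator)."""
    table = CytosineCallTable(index)
    from .align import trim_read

    for read in reads:
        r = trim_read(read, trim) if trim else read
        table.add_alignment(truth_alignment(r, trim), r)
    return table


# ------------------------------------------------------------------- I/O

def write_cytosine_report(table: CytosineCallTable, path: str | Path) -> None:
    """TSV: chrom, 1-based position, strand, meth, unmeth (mates pooled),
    context — the common cytosine-report convention."""
    df = table.to_dataframe()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": df["strand"],
            "meth": df["meth_r1"] + df["meth_r2"],
            "unmeth": df["unmeth_r1"] + df["unmeth_r2"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_cytosine_report(path: str | Path, index: CytosineIndex) -> CytosineCallTable:
    """Rebuild a (mate-pooled) call table from a cytosine report; pooled
    counts land in the R1 stratum."""
    df = pd.read_csv(path, sep="\t")
    table = CytosineCallTable(index)
    key = {}
    for i, (c, p, s) in enumerate(zip(index.chrom_id, index.pos, index.strand)):
        key[(index.chroms[c], int(p), "+-"[s])] = i
    for row in df.itertuples(index=False):
        i = key.get((row.chrom, int(row.pos) - 1, row.strand))
        if i is None:
            raise KeyError(f"report row not in index: {row.chrom}:{row.pos}{row.strand}")
        table.counts[i, 0, 0] += int(row.meth)
        table.counts[i, 0, 1] += int(row.unmeth)
    return table


def write_bedgraph(
    table: CytosineCallTable, path: str | Path, context: str = "CpG", min_calls: int = 1
) -> None:
    """Per-cytosine levels (percent) as bedGraph over covered cytosines."""
    df = table.to_dataframe()
    meth = df["meth_r1"] + df["meth_r2"]
    total = meth + df["unmeth_r1"] + df["unmeth_r2"]
    keep = (total >= min_calls) & (df["context"] == context)
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="methylation level (%)"\n')
        for chrom, pos, m, t in zip(
            df["chrom"][keep], df["pos"][keep], meth[keep], total[keep]
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100.0 * m / t:.6g}\n")


def write_level_report(report: LevelReport, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
        fh.write("\n")
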