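"""Trimming and a three-letter bisulfite aligner for small references.

Bisulfite conversion destroys the C/T distinction on the converted strand,
so reads are aligned in a reduced alphabet: the read is collapsed C->T or
G->A (depending on which strand of the original molecule it represents)
and compared against the matching collapsed views of the reference.  Four
views exist — C->T and G->A collapses of the plus and minus strands — and
a read's mate/protocol determines which collapse applies (PBAT R1 is
complementary to the converted strand, hence G->A; PBAT R2 is the converted
strand itself, hence C->T; MethylC-seq mirrors this).

The aligner is a deliberate full-sensitivity scan rather than an FM-index:
candidate loci are generated by exact lookup of seed chunks (pigeonhole
over ``seed_mismatch_max + 1`` pieces of the seed, so no locus passing the
seed filter can be missed) and verified by direct mismatch counting.  A
single strictly best locus is ``unique``; tied best loci are ``ambiguous``
and discarded downstream; only unique alignments feed methylation calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .genome import ReferenceGenome, revcomp
from .simulate import BisulfiteRead

VIEWS = ("CT+", "CT-", "GA+", "GA-")

# base codes: reference N (4) mismatches everything incl. read N (5)
_CODE = np.full(256, 5, dtype=np.uint8)
for i, b in enumerate(b"ACGTN"):
    _CODE[b] = i

_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")


def read_reduction(protocol: str, mate: str) -> str:
    """Which collapse a read needs: 'CT' or 'GA'."""
    if protocol == "PBAT":
        return "GA" if mate == "R1" else "CT"
    if protocol == "MethylC":
        return "CT" if mate == "R1" else "GA"
    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass(frozen=True)
class TrimRule:
    trim5: int = 4  # residual adapter bases at the 5' end
    trim3: int = 1

    def __post_init__(self) -> None:
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trim lengths must be >= 0")


def trim_read(read: BisulfiteRead, rule: TrimRule = TrimRule()) -> BisulfiteRead:
    """Slice bases and qualities identically (101 -> 96 under defaults)."""
    n = len(read.bases)
    if rule.trim5 + rule.trim3 >= n:
        raise ValueError(f"read of length {n} too short for trim rule {rule}")
    end = n - rule.trim3
    return BisulfiteRead(
        read.id,
        read.mate,
        read.protocol,
        read.bases[rule.trim5 : end],
        read.quals[rule.trim5 : end].copy(),
        read.truth,
    )


@dataclass(frozen=True)
class AlignParams:
    seed_len: int = 28
    seed_mismatch_max: int = 1
    total_mismatch_max: int = 3

    def __post_init__(self) -> None:
        if self.seed_len < self.seed_mismatch_max + 1:
            raise ValueError("seed too short for the mismatch allowance")
        if self.seed_mismatch_max < 0 or self.total_mismatch_max < 0:
            raise ValueError("mismatch limits must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mate: str
    status: str  # 'unique' | 'ambiguous' | 'unmapped'
    chrom: str | None = None
    pos: int | None = None  # 0-based plus-strand start of the covered interval
    view: str | None = None
    mismatches: int | None = None


class GenomeIndex:
    """Collapsed reference views plus seed-chunk k-mer lookup tables."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.chroms = genome.names
        self._views: dict[tuple[str, str], np.ndarray] = {}
        self._raw: dict[tuple[str, str], bytes] = {}
        for name in self.chroms:
            plus = genome.seq_bytes(name)
            minus = revcomp(plus)
            for view, src, table in (
                ("CT+", plus, _CT), ("CT-", minus, _CT),
                ("GA+", plus, _GA), ("GA-", minus, _GA),
            ):
                reduced = src.translate(table)
                self._raw[(name, view)] = reduced
                self._views[(name, view)] = _CODE[np.frombuffer(reduced, np.uint8)]
        # (chrom, view, offset, clen) -> (sorted kmer codes, positions by code order)
        self._kmers: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def view_codes(self, chrom: str, view: str) -> np.ndarray:
        return self._views[(chrom, view)]

    def _chunk_table(self, chrom: str, view: str, offset: int, clen: int):
        key = (chrom, view, offset, clen)
        tab = self._kmers.get(key)
        if tab is None:
            codes = self._views[(chrom, view)].astype(np.uint64)
            if len(codes) < clen:
                tab = (np.empty(0, np.uint64), np.empty(0, np.int64))
            else:
                powers = (6 ** np.arange(clen - 1, -1, -1)).astype(np.uint64)
                win = np.lib.stride_tricks.sliding_window_view(codes, clen)
                km = win @ powers
                order = np.argsort(km, kind="stable")
                tab = (km[order], order.astype(np.int64))
            self._kmers[key] = tab
        return tab

    def candidates(
        self, chrom: str, view: str, rcodes: np.ndarray, params: AlignParams
    ) -> np.ndarray:
        """All view positions that can satisfy the seed filter (pigeonhole)."""
        n_chunks = params.seed_mismatch_max + 1
        bounds = [params.seed_len * i // n_chunks for i in range(n_chunks + 1)]
        L = len(self._views[(chrom, view)])
        rlen = len(rcodes)
        hits: list[np.ndarray] = []
        for i in range(n_chunks):
            o, e = bounds[i], bounds[i + 1]
            clen = e - o
            powers = (6 ** np.arange(clen - 1, -1, -1)).astype(np.uint64)
            code = np.uint64(rcodes[o:e].astype(np.uint64) @ powers)
            km, order = self._chunk_table(chrom, view, o, clen)
            lo = np.searchsorted(km, code, "left")
            hi = np.searchsorted(km, code, "right")
            if hi > lo:
                hits.append(order[lo:hi] - o)
        if not hits:
            return np.empty(0, np.int64)
        pos = np.unique(np.concatenate(hits))
        return pos[(pos >= 0) & (pos <= L - rlen)]


def _reduce_read(bases: str, reduction: str) -> np.ndarray:
    table = _CT if reduction == "CT" else _GA
    return _CODE[np.frombuffer(bases.upper().encode().translate(table), np.uint8)]


def _plus_interval_start(view: str, view_pos: int, L: int, rlen: int) -> int:
    if view.endswith("+"):
        return view_pos
    return L - view_pos - rlen


def align_read(
    read: BisulfiteRead,
    gindex: GenomeIndex,
    params: AlignParams = AlignParams(),
    reduction: str | None = None,
) -> AlignmentRecord:
    """Align one (already trimmed) read against both orientations of its
    collapsed view; strictly-best locus wins, ties are ambiguous."""
    rlen = len(read.bases)
    if rlen < params.seed_len:
        raise ValueError("read shorter than seed length")
    if reduction is None:
        reduction = read_reduction(read.protocol, read.mate)
    rcodes = _reduce_read(read.bases, reduction)
    hits: list[tuple[int, str, str, int]] = []  # (mm, chrom, view, view_pos)
    for view in (f"{reduction}+", f"{reduction}-"):
        for chrom in gindex.chroms:
            ref = gindex.view_codes(chrom, view)
            for p in gindex.candidates(chrom, view, rcodes, params):
                seg = ref[p : p + rlen]
                seed_mm = int(np.count_nonzero(seg[: params.seed_len] != rcodes[: params.seed_len]))
                if seed_mm > params.seed_mismatch_max:
                    continue
                mm = seed_mm + int(
                    np.count_nonzero(seg[params.seed_len :] != rcodes[params.seed_len :])
                )
                if mm <= params.total_mismatch_max:
                    hits.append((mm, chrom, view, int(p)))
    if not hits:
        return AlignmentRecord(read.id, read.mate, "unmapped")
    best = min(h[0] for h in hits)
    winners = [h for h in hits if h[0] == best]
    if len(winners) > 1:
        return AlignmentRecord(read.id, read.mate, "ambiguous")
    mm, chrom, view, vpos = winners[0]
    L = gindex.genome.length(chrom)
    return AlignmentRecord(
        read.id, read.mate, "unique", chrom,
        _plus_interval_start(view, vpos, L, rlen), view, mm,
    )


@dataclass
class AlignmentSummary:
    n_reads: int = 0
    n_unique: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0

    @property
    def mapped_fraction(self) -> float:
        return (self.n_unique + self.n_ambiguous) / self.n_reads if self.n_reads else 0.0

    @property
    def unique_fraction(self) -> float:
        return self.n_unique / self.n_reads if self.n_reads else 0.0

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_unique": self.n_unique,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
            "mapped_fraction": self.mapped_fraction,
            "unique_fraction": self.unique_fraction,
        }


def align_batch(
    reads: Sequence[BisulfiteRead],
    gindex: GenomeIndex,
    params: AlignParams = AlignParams(),
) -> tuple[list[AlignmentRecord], AlignmentSummary]:
    records = [align_read(r, gindex, params) for r in reads]
    summary = AlignmentSummary(n_reads=len(records))
    for rec in records:
        if rec.status == "unique":
            summary.n_unique += 1
        elif rec.status == "ambiguous":
            summary.n_ambiguous += 1
        else:
            summary.n_unmapped += 1
    return records, summary


# ------------------------------------------------------------------ SAM I/O

def write_sam(
    records: Sequence[AlignmentRecord],
    reads: Sequence[BisulfiteRead],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Unique alignments as minimal SAM; mismatches in NM, collapse view in
    ZV, mate in ZM.  Sequence/qualities are stored in plus-strand
    orientation per SAM convention (flag 16 for minus-view alignments)."""
    by_key = {(r.id, r.mate): r for r in reads}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            if rec.status != "unique":
                continue
            read = by_key[(rec.read_id, rec.mate)]
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            minus = rec.view.endswith("-")
            seg.flag = 16 if minus else 0
            seg.reference_id = genome.names.index(rec.chrom)
            seg.reference_start = rec.pos
            seg.mapping_quality = 255
            seg.cigartuples = [(0, len(read.bases))]
            if minus:
                seg.query_sequence = revcomp(read.bases)
                seg.query_qualities = pysam.qualitystring_to_array(
                    (read.quals[::-1] + 33).tobytes().decode()
                )
            else:
                seg.query_sequence = read.bases
                seg.query_qualities = pysam.qualitystring_to_array(
                    (read.quals + 33).tobytes().decode()
                )
            seg.set_tag("NM", rec.mismatches)
            seg.set_tag("ZV", rec.view)
            seg.set_tag("ZM", rec.mate)
            fh.write(seg)


def read_sam(path: str | Path, protocol: str = "PBAT") -> tuple[list[AlignmentRecord], list[BisulfiteRead]]:
    """Recover unique alignments plus original-orientation reads from SAM."""
    records, reads = [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            view = seg.get_tag("ZV")
            mate = seg.get_tag("ZM")
            bases = seg.query_sequence
            quals = np.array(seg.query_qualities, dtype=np.uint8)
            if view.endswith("-"):
                bases = revcomp(bases)
                quals = quals[::-1].copy()
            records.append(
                AlignmentRecord(
                    seg.query_name, mate, "unique", seg.reference_name,
                    seg.reference_start, view, int(seg.get_tag("NM")),
                )
            )
            reads.append(BisulfiteRead(seg.query_name, mate, protocol, bases, quals))
    return records, reads


def write_summary_tsv(summary: AlignmentSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        d = summary.as_dict()
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in d.values()) + "\n")
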