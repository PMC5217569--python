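"""Reference sequences, cytosine/context indexing and window tiling.

Methylation analysis of bisulfite sequencing data needs, for every cytosine
on *both* strands of the reference, its dinucleotide context (CpG, CpA, CpT,
CpC): the context is read 5'->3' along the cytosine's own strand, so a
plus-strand cytosine at position p looks at the base at p+1, while a
minus-strand cytosine (a G on the plus strand at p) looks at the complement
of the base at p-1.  Cytosines whose next base is N or missing (chromosome
end) get context ``unknown`` and are excluded from all methylation
statistics.

Coordinates are 0-based half-open throughout; text reports use the 1-based
cytosine-report convention at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset(b"ACGTN")

# context codes
CPG, CPA, CPT, CPC, UNKNOWN = range(5)
CONTEXT_NAMES = ("CpG", "CpA", "CpT", "CpC", "unknown")
NONCPG_CODES = (CPA, CPT, CPC)

# fixed fixture parameters: a GC-balanced random stand-in for the lambda
# phage genome (48,502 bp), so calibration runs need no external sequence
LAMBDA_LENGTH = 48_502
DEFAULT_GENOME_SEED = 48_502
DEFAULT_GENOME_NAME = "lambda_synth"

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str | bytes) -> str | bytes:
    """Reverse complement of a DNA sequence over {A,C,G,T,N}."""
    if isinstance(seq, str):
        return seq.encode()[::-1].translate(_COMPLEMENT).decode()
    return seq[::-1].translate(_COMPLEMENT)


class ReferenceGenome:
    """An ordered set of named, validated DNA sequences."""

    def __init__(self, records: Sequence[tuple[str, str]]):
        names = [n for n, _ in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate record names in reference")
        if any(not n for n in names):
            raise ValueError("empty record name in reference")
        self._names: list[str] = []
        self._seqs: dict[str, bytes] = {}
        self._arrays: dict[str, np.ndarray] = {}
        for name, seq in records:
            up = seq.upper().encode()
            bad = set(up) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-IUPAC characters: "
                    f"{sorted(chr(c) for c in bad)}"
                )
            self._names.append(name)
            self._seqs[name] = up
            self._arrays[name] = np.frombuffer(up, dtype=np.uint8)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for n in self._names:
            yield n, self._seqs[n].decode()

    def sequence(self, name: str) -> str:
        return self._seqs[name].decode()

    def seq_bytes(self, name: str) -> bytes:
        return self._seqs[name]

    def seq_array(self, name: str) -> np.ndarray:
        """Sequence as a read-only uint8 array of ASCII codes."""
        return self._arrays[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self._seqs[n]) for n in self._names}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self._names:
                fh.write(f">{name}\n")
                seq = self._seqs[name].decode()
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (possibly multi-record, line-wrapped) FASTA reference."""
    return ReferenceGenome.from_fasta(path)


def synthetic_genome(
    length: int = LAMBDA_LENGTH,
    seed: int = DEFAULT_GENOME_SEED,
    name: str = DEFAULT_GENOME_NAME,
) -> ReferenceGenome:
    """GC-balanced random genome used as the lambda-scale calibration fixture.

    The default reproduces a fixed 48,502 bp sequence (the lambda phage
    genome length) from a fixed seed, so every run sees the same fixture.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    return ReferenceGenome([(name, seq.tobytes().decode())])


class CytosineRecord(NamedTuple):
    chrom: str
    pos: int  # 0-based plus-strand coordinate of the C (G on plus if strand '-')
    strand: str  # '+' or '-'
    context: str  # one of CONTEXT_NAMES


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must be < end")

    @property
    def size(self) -> int:
        return self.end - self.start


# ASCII codes
_A, _C, _G, _T, _N = (ord(c) for c in "ACGTN")


class CytosineIndex:
    """Every cytosine on both strands of a genome, with context.

    Internally flat numpy arrays sorted by (chromosome order, position);
    per-(chromosome, strand) position arrays support fast interval queries
    during methylation extraction.
    """

    def __init__(self, genome: ReferenceGenome):
        self.chroms = genome.names
        self.chrom_lengths = genome.lengths
        chrom_ids, poss, strands, ctxs = [], [], [], []
        self._by_strand: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        offset = 0
        for ci, name in enumerate(self.chroms):
            arr = genome.seq_array(name)
            L = len(arr)
            plus_pos = np.nonzero(arr == _C)[0]
            minus_pos = np.nonzero(arr == _G)[0]

            plus_ctx = np.full(len(plus_pos), UNKNOWN, dtype=np.int8)
            ok = plus_pos < L - 1
            nxt = arr[plus_pos[ok] + 1]
            ctx = np.full(len(nxt), UNKNOWN, dtype=np.int8)
            ctx[nxt == _G] = CPG
            ctx[nxt == _A] = CPA
            ctx[nxt == _T] = CPT
            ctx[nxt == _C] = CPC
            plus_ctx[ok] = ctx

            minus_ctx = np.full(len(minus_pos), UNKNOWN, dtype=np.int8)
            ok = minus_pos > 0
            prv = arr[minus_pos[ok] - 1]  # complement gives the 5'->3' next base
            ctx = np.full(len(prv), UNKNOWN, dtype=np.int8)
            ctx[prv == _C] = CPG
            ctx[prv == _T] = CPA
            ctx[prv == _A] = CPT
            ctx[prv == _G] = CPC
            minus_ctx[ok] = ctx

            pos = np.concatenate([plus_pos, minus_pos])
            strand = np.concatenate(
                [np.zeros(len(plus_pos), np.int8), np.ones(len(minus_pos), np.int8)]
            )
            context = np.concatenate([plus_ctx, minus_ctx])
            order = np.lexsort((strand, pos))
            pos, strand, context = pos[order], strand[order], context[order]

            n = len(pos)
            chrom_ids.append(np.full(n, ci, dtype=np.int32))
            poss.append(pos)
            strands.append(strand)
            ctxs.append(context)

            flat = np.arange(offset, offset + n)
            for scode, sname in ((0, "+"), (1, "-")):
                m = strand == scode
                self._by_strand[(name, sname)] = (
                    pos[m].astype(np.int64),
                    flat[m],
                )
            offset += n

        self.chrom_id = (
            np.concatenate(chrom_ids) if chrom_ids else np.empty(0, np.int32)
        )
        self.pos = np.concatenate(poss) if poss else np.empty(0, np.int64)
        self.strand = np.concatenate(strands) if strands else np.empty(0, np.int8)
        self.context = np.concatenate(ctxs) if ctxs else np.empty(0, np.int8)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n(self) -> int:
        return len(self.pos)

    def strand_positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """(sorted plus-coordinates, flat indices) for one chromosome strand."""
        return self._by_strand.get((chrom, strand), (np.empty(0, np.int64), np.empty(0, np.int64)))

    def records(self) -> list[CytosineRecord]:
        return [
            CytosineRecord(
                self.chroms[c], int(p), "+-"[s], CONTEXT_NAMES[x]
            )
            for c, p, s, x in zip(self.chrom_id, self.pos, self.strand, self.context)
        ]

    def context_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.context == code))
            for code, name in enumerate(CONTEXT_NAMES)
        }


def index_cytosines(genome: ReferenceGenome) -> CytosineIndex:
    """Index every C (plus strand) and G (minus-strand C) with context."""
    return CytosineIndex(genome)


def tile_windows(genome: ReferenceGenome, size: int) -> list[Window]:
    """Non-overlapping full windows of `size` bases; trailing remainder dropped."""
    if size < 1:
        raise ValueError("window size must be >= 1")
    out: list[Window] = []
    for name in genome.names:
        L = genome.length(name)
        for s in range(0, (L // size) * size, size):
            out.append(Window(name, s, s + size))
    return out


def write_bed(windows: Sequence[Window], path: str | Path,
              scores: Sequence[float] | None = None) -> None:
    """Windows as BED (0-based half-open), optional score column."""
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            if scores is None:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
            else:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\twin{i}\t{scores[i]:g}\n")
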