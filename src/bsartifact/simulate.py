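"""Bisulfite read simulation with controllable base-caller artifacts.

The generator emulates the physical chain that produces a WGBS read:

1. a methylome assigns each cytosine a methylation probability (uniform
   level, a near-complete SssI-methylase model at 97.9%, or a two-component
   molecule mixture of fully methylated and unmethylated DNA);
2. a double-stranded fragment is drawn, one genomic strand is picked, and
   bisulfite chemistry converts each *unmethylated* C of that strand to T
   (with probability ``conversion_rate``) while 5mC stays C;
3. library chemistry turns the converted strand into mates: PBAT reads the
   complement of the converted strand first, so 5mC appears as G in R1 and
   C in R2; MethylC-seq is the mirror image (5mC as C in R1, G in R2);
4. optional uniform sequencing error and the parameterized base-caller
   artifact are applied: a minority-base G undercall (G miscalled as A, the
   unmethylated partner base, with a Phred penalty) and a density-dependent
   collapse of all qualities on one mate.

Same seed, same configuration -> byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .genome import CPG, CytosineIndex, ReferenceGenome

# Phred bounds of the simulated instrument
QUAL_MIN = 2
QUAL_MAX = 41

# CpG methylation level of SssI-treated lambda DNA validated by clone
# bisulfite sequencing of 58 CpG sites (near-complete in-vitro methylation)
SSSI_CLONE_LEVEL = 0.979
SSSI_CLONE_SITES = 58

_A, _C, _G, _T = (ord(c) for c in "ACGT")
_RC_LUT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _RC_LUT[a] = b


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _RC_LUT[arr][::-1]


@dataclass(frozen=True)
class MethylomeSpec:
    """Per-cytosine methylation probability model.

    mode 'uniform': every CpG at ``cpg_level``; 'sssi': every CpG at
    ``sssi_level`` (default 0.979); 'mixture': each molecule is drawn wholly
    from ``components[0]`` with probability ``mixture_proportion``, else
    from ``components[1]``.  Non-CpG cytosines (and unknown-context ones)
    sit at ``noncpg_level`` in every mode.
    """

    mode: str = "uniform"
    cpg_level: float = 0.0
    sssi_level: float = SSSI_CLONE_LEVEL
    mixture_proportion: float = 0.0
    components: tuple["MethylomeSpec", "MethylomeSpec"] | None = None
    noncpg_level: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "sssi", "mixture"):
            raise ValueError(f"unknown methylome mode {self.mode!r}")
        for p in (self.cpg_level, self.sssi_level, self.mixture_proportion,
                  self.noncpg_level):
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation probabilities must be in [0,1]")
        if self.mode == "mixture":
            if self.components is None or len(self.components) != 2:
                raise ValueError("mixture mode requires two component specs")
            if any(c.mode == "mixture" for c in self.components):
                raise ValueError("mixture components must not be mixtures")

    @classmethod
    def uniform(cls, cpg_level: float, noncpg_level: float = 0.0) -> "MethylomeSpec":
        return cls(mode="uniform", cpg_level=cpg_level, noncpg_level=noncpg_level)

    @classmethod
    def sssi(cls, level: float = SSSI_CLONE_LEVEL) -> "MethylomeSpec":
        return cls(mode="sssi", sssi_level=level)

    @classmethod
    def mixture(
        cls,
        proportion: float,
        methylated: "MethylomeSpec | None" = None,
        unmethylated: "MethylomeSpec | None" = None,
    ) -> "MethylomeSpec":
        """Physical mixture: fraction ``proportion`` of molecules methylated."""
        return cls(
            mode="mixture",
            mixture_proportion=proportion,
            components=(
                methylated or cls.uniform(1.0),
                unmethylated or cls.uniform(0.0),
            ),
        )


class RealizedMethylome:
    """Per-cytosine levels bound to a CytosineIndex.

    ``levels`` has one row per mixture component (a single row for uniform
    and SssI modes); a molecule's component is drawn once in
    ``simulate_fragment`` so that a mixture behaves like mixed DNA, not
    per-site coin flips.
    """

    def __init__(self, index: CytosineIndex, levels: np.ndarray,
                 mixture_proportion: float = 1.0):
        levels = np.atleast_2d(np.asarray(levels, dtype=float))
        if levels.shape[1] != len(index):
            raise ValueError("levels shape does not match cytosine index")
        self.index = index
        self.levels = levels
        self.mixture_proportion = float(mixture_proportion)

    @property
    def n_components(self) -> int:
        return self.levels.shape[0]

    def expected_levels(self) -> np.ndarray:
        """Marginal per-cytosine methylation probability."""
        if self.n_components == 1:
            return self.levels[0]
        pi = self.mixture_proportion
        return pi * self.levels[0] + (1.0 - pi) * self.levels[1]

    @classmethod
    def from_levels(cls, index: CytosineIndex, levels: np.ndarray) -> "RealizedMethylome":
        return cls(index, levels)


def realize_methylome(
    index: CytosineIndex, spec: MethylomeSpec, rng: np.random.Generator | None = None
) -> RealizedMethylome:
    """Map every indexed cytosine to its methylation probability."""

    def one(component: MethylomeSpec) -> np.ndarray:
        lv = np.full(len(index), component.noncpg_level, dtype=float)
        cpg = index.context == CPG
        if component.mode == "sssi":
            lv[cpg] = component.sssi_level
        else:
            lv[cpg] = component.cpg_level
        return lv

    if spec.mode == "mixture":
        assert spec.components is not None
        levels = np.stack([one(c) for c in spec.components])
        return RealizedMethylome(index, levels, spec.mixture_proportion)
    return RealizedMethylome(index, one(spec))


def domain_methylome(
    index: CytosineIndex,
    base_level: float,
    domains: Sequence[tuple[str, int, int, float]],
    noncpg_level: float = 0.0,
) -> RealizedMethylome:
    """Region-structured methylome: CpGs at ``base_level`` except inside the
    given (chrom, start, end, level) domains — used to plant PMD-like
    intermediate-methylation blocks in an otherwise highly methylated genome."""
    lv = np.full(len(index), noncpg_level, dtype=float)
    cpg = index.context == CPG
    lv[cpg] = base_level
    for chrom, start, end, level in domains:
        ci = index.chroms.index(chrom)
        m = cpg & (index.chrom_id == ci) & (index.pos >= start) & (index.pos < end)
        lv[m] = level
    return RealizedMethylome(index, lv)


@dataclass
class SimulationConfig:
    protocol: str = "PBAT"  # or "MethylC"
    read_len: int = 101
    paired: bool = True
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    n_fragments: int = 10_000
    conversion_rate: float = 1.0
    error_rate: float = 0.0
    base_quality: int = 38
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("PBAT", "MethylC"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for r in (self.conversion_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if not QUAL_MIN <= self.base_quality <= QUAL_MAX:
            raise ValueError(f"base_quality outside [{QUAL_MIN},{QUAL_MAX}]")


@dataclass(frozen=True)
class ReadTruth:
    chrom: str
    frag_start: int
    frag_len: int
    strand: str  # genomic strand the fragment was drawn from


@dataclass
class BisulfiteRead:
    id: str
    mate: str  # 'R1' or 'R2'
    protocol: str
    bases: str
    quals: np.ndarray  # uint8 Phred values
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Fragment:
    chrom: str
    start: int
    length: int
    strand: str
    seq: np.ndarray  # converted single-strand sequence, 5'->3', uint8

    @property
    def text(self) -> str:
        return self.seq.tobytes().decode()


def simulate_fragment(
    genome: ReferenceGenome,
    methylome: RealizedMethylome,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Fragment:
    """Draw one molecule and bisulfite-convert its chosen strand.

    Methylation is realized per molecule: each cytosine of the fragment
    strand is methylated with its level (in mixture mode the molecule's
    component is drawn once); unmethylated Cs convert to T with probability
    ``conversion_rate``.
    """
    names = genome.names
    lens = np.array([genome.length(n) for n in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lens / lens.sum()))]
    L = genome.length(chrom)
    flen = int(np.clip(round(rng.normal(config.fragment_mean, config.fragment_sd)),
                       config.read_len, L))
    if flen > L:
        raise ValueError("fragment length exceeds record length")
    start = int(rng.integers(0, L - flen + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return _convert_fragment(genome, methylome, config, rng, chrom, start, flen, strand)


def _convert_fragment(genome, methylome, config, rng, chrom, start, flen, strand):
    if start < 0 or start + flen > genome.length(chrom):
        raise ValueError(
            f"fragment [{start},{start + flen}) outside record {chrom!r}"
        )
    arr = genome.seq_array(chrom)[start : start + flen]
    pos_arr, flat_idx = methylome.index.strand_positions(chrom, strand)
    lo, hi = np.searchsorted(pos_arr, [start, start + flen])
    ps = pos_arr[lo:hi]
    if strand == "+":
        frag = arr.copy()
        offs = ps - start
    else:
        frag = _revcomp_arr(arr).copy()
        offs = (start + flen - 1) - ps
    if methylome.n_components > 1:
        comp = 0 if rng.random() < methylome.mixture_proportion else 1
    else:
        comp = 0
    lv = methylome.levels[comp, flat_idx[lo:hi]]
    k = len(offs)
    if k:
        meth = rng.random(k) < lv
        conv = ~meth
        if config.conversion_rate < 1.0:
            conv &= rng.random(k) < config.conversion_rate
        frag[offs[conv]] = _T
    return Fragment(chrom, start, flen, strand, frag)


def reads_from_fragment(
    fragment: Fragment, config: SimulationConfig, read_id: str
) -> tuple[BisulfiteRead, ...]:
    """Cut mates from a converted fragment.

    PBAT reads the complement of the converted strand first: R1 is the first
    ``read_len`` bases of the reverse complement, R2 the first ``read_len``
    bases of the converted strand itself, so 5mC codes as G in R1 and C in
    R2.  MethylC-seq swaps the mate roles.
    """
    rl = config.read_len
    if rl > fragment.length:
        raise ValueError("read length exceeds fragment length")
    fwd = fragment.seq[:rl].tobytes().decode()
    rev = _revcomp_arr(fragment.seq)[:rl].tobytes().decode()
    quals = np.full(rl, config.base_quality, dtype=np.uint8)
    truth = ReadTruth(fragment.chrom, fragment.start, fragment.length, fragment.strand)
    if config.protocol == "PBAT":
        r1, r2 = rev, fwd
    else:  # MethylC
        r1, r2 = fwd, rev
    reads = [BisulfiteRead(read_id, "R1", config.protocol, r1, quals.copy(), truth)]
    if config.paired:
        reads.append(BisulfiteRead(read_id, "R2", config.protocol, r2, quals.copy(), truth))
    return tuple(reads)


_OTHER = {  # cyclic substitution targets for uniform errors
    _A: (_C, _G, _T), _C: (_A, _G, _T), _G: (_A, _C, _T), _T: (_A, _C, _G),
}


def apply_errors(
    read: BisulfiteRead, config: SimulationConfig, rng: np.random.Generator
) -> BisulfiteRead:
    """Uniform per-base substitution errors; qualities untouched."""
    rate = config.error_rate
    if rate == 0.0:
        return read
    arr = np.frombuffer(read.bases.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit):
        pick = rng.integers(0, 3, size=len(hit))
        for i, j in zip(hit, pick):
            arr[i] = _OTHER.get(arr[i], (_A, _C, _G))[j]
    return replace(read, bases=arr.tobytes().decode(), quals=read.quals.copy())


@dataclass
class R2Collapse:
    """Density-dependent quality collapse of a whole mate.

    ``density`` is in thousands of clusters per mm^2.  Below ``onset`` the
    cap stays at the instrument maximum; it falls linearly to
    ``quality_floor`` at ``full_at`` and beyond — emulating base-caller
    versions that score the minority bases of low-diversity mates poorly
    once the flow cell is crowded.
    """

    density: float
    quality_floor: int = QUAL_MIN
    onset: float = 300.0
    full_at: float = 650.0

    def cap(self) -> int:
        if self.density <= self.onset:
            return QUAL_MAX
        frac = min(1.0, (self.density - self.onset) / (self.full_at - self.onset))
        return int(round(QUAL_MAX - frac * (QUAL_MAX - self.quality_floor)))


@dataclass
class ArtifactModel:
    """Parameterized base-caller artifact.

    ``g_to_a_rate`` q: each G on the targeted mate is miscalled as A with
    probability q (A being the unmethylated partner base at 5mC-coding
    positions, so the observed methylation level shrinks to m(1-q));
    ``g_quality_penalty`` delta is subtracted from the quality of miscalled
    Gs (and of retained Gs too when ``penalize_retained`` is set), floored
    at Phred 2.  ``uniform_miscall`` switches the miscall target from A to a
    uniform choice of the other three bases.  ``r2_collapse`` caps all
    qualities of the targeted mate as cluster density rises.
    """

    g_to_a_rate: float = 0.0
    g_quality_penalty: int = 0
    target_mate: str = "R1"
    penalize_retained: bool = False
    uniform_miscall: bool = False
    r2_collapse: R2Collapse | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_to_a_rate <= 1.0:
            raise ValueError("g_to_a_rate must be in [0,1]")
        if self.g_quality_penalty < 0:
            raise ValueError("g_quality_penalty must be >= 0")
        if self.target_mate not in ("R1", "R2"):
            raise ValueError("target_mate must be R1 or R2")


def apply_artifact(
    read: BisulfiteRead, model: ArtifactModel, rng: np.random.Generator
) -> BisulfiteRead:
    """Apply the artifact to a read of the targeted mate (others unchanged)."""
    if read.mate != model.target_mate:
        return read
    arr = np.frombuffer(read.bases.encode(), dtype=np.uint8).copy()
    quals = read.quals.astype(np.int16)
    gpos = np.nonzero(arr == _G)[0]
    if len(gpos):
        mis = rng.random(len(gpos)) < model.g_to_a_rate
        hit = gpos[mis]
        if model.uniform_miscall and len(hit):
            pick = rng.integers(0, 3, size=len(hit))
            for i, j in zip(hit, pick):
                arr[i] = (_A, _C, _T)[j]
        else:
            arr[hit] = _A
        if model.g_quality_penalty:
            pen = gpos if model.penalize_retained else hit
            quals[pen] -= model.g_quality_penalty
    if model.r2_collapse is not None:
        quals = np.minimum(quals, model.r2_collapse.cap())
    quals = np.clip(quals, QUAL_MIN, QUAL_MAX).astype(np.uint8)
    return replace(read, bases=arr.tobytes().decode(), quals=quals)


def simulate_library(
    genome: ReferenceGenome,
    methylome: RealizedMethylome,
    config: SimulationConfig,
    artifact: ArtifactModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[BisulfiteRead]:
    """End-to-end library: fragments -> mates -> errors -> artifact."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[BisulfiteRead] = []
    for i in range(config.n_fragments):
        frag = simulate_fragment(genome, methylome, config, rng)
        for read in reads_from_fragment(frag, config, f"sim{i}"):
            if config.error_rate > 0.0:
                read = apply_errors(read, config, rng)
            if artifact is not None:
                read = apply_artifact(read, artifact, rng)
            out.append(read)
    return out


# ---------------------------------------------------------------- FASTQ I/O

def write_fastq(reads: Iterable[BisulfiteRead], path: str | Path) -> None:
    """Plain 4-line FASTQ, Phred+33."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n")
            fh.write((r.quals + 33).tobytes().decode("ascii") + "\n")


def write_fastq_paired(
    pairs: Iterable[tuple[BisulfiteRead, BisulfiteRead]],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Synchronized mate files with matching ids."""
    p1, p2 = [], []
    for r1, r2 in pairs:
        if r1.id != r2.id:
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        p1.append(r1)
        p2.append(r2)
    write_fastq(p1, path1)
    write_fastq(p2, path2)


def read_fastq(
    path: str | Path, mate: str = "R1", protocol: str = "PBAT"
) -> list[BisulfiteRead]:
    """Read Phred+33 FASTQ; mate/protocol are supplied by the caller since
    FASTQ carries neither."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            BisulfiteRead(
                rec.id,
                mate,
                protocol,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.uint8),
            )
        )
    return out


def read_fastq_paired(
    path1: str | Path, path2: str | Path, protocol: str = "PBAT"
) -> list[tuple[BisulfiteRead, BisulfiteRead]]:
    r1 = read_fastq(path1, "R1", protocol)
    r2 = read_fastq(path2, "R2", protocol)
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    for a, b in zip(r1, r2):
        if a.id != b.id:
            raise ValueError(f"mate id mismatch: {a.id} vs {b.id}")
    return list(zip(r1, r2))


def write_truth_table(reads: Iterable[BisulfiteRead], path: str | Path) -> None:
    """Provenance TSV: read id, chrom, fragment start/length, strand, mate."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tfrag_start\tfrag_len\tstrand\tmate\n")
        for r in reads:
            if r.truth is None:
                continue
            t = r.truth
            fh.write(
                f"{r.id}\t{t.chrom}\t{t.frag_start}\t{t.frag_len}\t{t.strand}\t{r.mate}\n"
            )
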