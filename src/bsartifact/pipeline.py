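"""End-to-end drivers: simulate -> trim -> align -> call, and the mixture
calibration experiment built from them.

These are the composition points the command-line interface, the analysis
scripts and the acceptance checks all share, so every consumer runs the
same code path.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .align import (
    AlignParams,
    AlignmentSummary,
    GenomeIndex,
    TrimRule,
    align_batch,
    trim_read,
)
from .calls import CytosineCallTable, extract_calls, weighted_level
from .genome import CPG, CytosineIndex, ReferenceGenome, index_cytosines, synthetic_genome
from .regions import CalibrationPoint, calibrate_mixtures
from .simulate import (
    ArtifactModel,
    MethylomeSpec,
    RealizedMethylome,
    SimulationConfig,
    realize_methylome,
    simulate_library,
)

# the paper-style three-point spike-in mixture series: percent methylated DNA
MIXTURE_SERIES = (10.0, 44.0, 88.0)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class LibraryRun:
    """Everything one simulated library produced on its way to calls."""

    table: CytosineCallTable
    summary: AlignmentSummary
    reads: list  # trimmed reads (aligned form)
    raw_reads: list  # untrimmed reads as sequenced (QC operates on these)
    cpg_calls_per_molecule: np.ndarray  # CpG calls attributed to each fragment

    @property
    def n_cpg_calls(self) -> int:
        return int(self.cpg_calls_per_molecule.sum())


def run_library(
    genome: ReferenceGenome,
    index: CytosineIndex,
    spec: MethylomeSpec | RealizedMethylome,
    config: SimulationConfig,
    artifact: ArtifactModel | None = None,
    trim: TrimRule | None = TrimRule(),
    params: AlignParams = AlignParams(),
    seed: int | None = None,
    dedup_overlap: bool = False,
    gindex: GenomeIndex | None = None,
) -> LibraryRun:
    """Simulate a library and take it through trimming, alignment and
    methylation extraction; returns the call table plus diagnostics."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    methylome = (
        spec if isinstance(spec, RealizedMethylome) else realize_methylome(index, spec)
    )
    raw = simulate_library(genome, methylome, config, artifact=artifact, rng=rng)
    trimmed = [trim_read(r, trim) for r in raw] if trim else list(raw)
    if gindex is None:
        gindex = GenomeIndex(genome)
    records, summary = align_batch(trimmed, gindex, params)
    table = extract_calls(records, trimmed, index, dedup_overlap=dedup_overlap)

    # attribute CpG calls to source molecules (read pairs share an id)
    cpg = index.context == CPG
    per_mol: dict[str, int] = {}
    shadow = CytosineCallTable(index)
    for rec, read in zip(records, trimmed):
        if rec.status != "unique":
            continue
        called = shadow.add_alignment(rec, read)
        per_mol[rec.read_id] = per_mol.get(rec.read_id, 0) + int(cpg[called].sum())
    counts = np.array(list(per_mol.values()), dtype=np.int64)
    return LibraryRun(table, summary, trimmed, raw, counts)


def mixture_sampling_sd(pi: float, calls_per_molecule: np.ndarray) -> float:
    """Exact sampling sd (in percent) of the depth-weighted level when each
    molecule is wholly methylated with probability ``pi`` and molecule i
    contributes c_i calls: sd = 100*sqrt(pi(1-pi)*sum(c^2))/sum(c).

    This, not the binomial sd over pooled calls, is the correct sampling
    error for a physical mixture of fully methylated and unmethylated
    molecules, because all calls from one molecule are perfectly correlated.
    """
    c = np.asarray(calls_per_molecule, dtype=float)
    c = c[c > 0]
    if not len(c):
        raise ValueError("no calls")
    return 100.0 * float(np.sqrt(pi * (1.0 - pi) * (c**2).sum()) / c.sum())


@dataclass
class MixturePoint:
    predetermined: float  # percent
    run: LibraryRun
    level: float  # pooled weighted CpG level, percent
    level_r1: float
    level_r2: float
    sampling_sd: float  # percent, molecule-aware


def run_mixture_point(
    proportion_pct: float,
    n_pairs: int,
    seed: int,
    genome: ReferenceGenome | None = None,
    index: CytosineIndex | None = None,
    gindex: GenomeIndex | None = None,
    artifact: ArtifactModel | None = None,
    conversion_rate: float = 1.0,
    error_rate: float = 0.0,
) -> MixturePoint:
    """One spike-in calibration point: paired-end PBAT over a mixture of
    fully methylated and fully unmethylated molecules."""
    if genome is None:
        genome = synthetic_genome()
    if index is None:
        index = index_cytosines(genome)
    pi = proportion_pct / 100.0
    spec = MethylomeSpec.mixture(pi)
    config = SimulationConfig(
        protocol="PBAT",
        paired=True,
        n_fragments=n_pairs,
        conversion_rate=conversion_rate,
        error_rate=error_rate,
        seed=seed,
    )
    run = run_library(genome, index, spec, config, artifact=artifact,
                      seed=seed, gindex=gindex)
    return MixturePoint(
        proportion_pct,
        run,
        weighted_level(run.table, "CpG", "both"),
        weighted_level(run.table, "CpG", "R1"),
        weighted_level(run.table, "CpG", "R2"),
        mixture_sampling_sd(pi, run.cpg_calls_per_molecule),
    )


def run_mixture_series(
    n_pairs: int,
    seed: int,
    proportions_pct: tuple[float, ...] = MIXTURE_SERIES,
    artifact: ArtifactModel | None = None,
) -> tuple[list[MixturePoint], list[CalibrationPoint]]:
    """The full three-point calibration experiment on the default fixture
    genome; returns raw points and the calibration table."""
    genome = synthetic_genome()
    index = index_cytosines(genome)
    gindex = GenomeIndex(genome)
    points = [
        run_mixture_point(
            p, n_pairs, stage_seed(seed, f"mixture-{p}"), genome, index, gindex,
            artifact=artifact,
        )
        for p in proportions_pct
    ]
    calib = calibrate_mixtures([(p.predetermined, p.run.table) for p in points])
    return points, calib


def simulate_sssi_clones(
    n_sites: int = 58,
    n_clones: int = 1000,
    level: float | None = None,
    seed: int = 0,
) -> tuple[float, int]:
    """Clone-style bisulfite sequencing of an SssI-treated substrate.

    Builds a small reference whose plus strand carries ``n_sites`` CpG
    sites, realizes an SssI methylome over it, simulates ``n_clones``
    full-length molecules with complete conversion and no error, and counts
    the methylated fraction of all CpG observations — the in-silico analogue
    of validating near-complete in-vitro methylation by clone sequencing.

    Returns (level percent, number of CpG observations).
    """
    from .simulate import _convert_fragment

    spec = MethylomeSpec.sssi() if level is None else MethylomeSpec.sssi(level)
    rng = np.random.default_rng(seed)
    # plus strand: n_sites spaced CpG dyads in an A/T background
    unit = "ATTACG"
    seq = "ATTA" + unit * n_sites + "ATTA"
    genome = ReferenceGenome([("sssi_locus", seq)])
    index = index_cytosines(genome)
    methylome = realize_methylome(index, spec)
    L = genome.length("sssi_locus")
    config = SimulationConfig(protocol="PBAT", paired=False, read_len=L,
                              conversion_rate=1.0, error_rate=0.0)
    meth_obs = 0
    total_obs = 0
    ppos, pflat = index.strand_positions("sssi_locus", "+")
    is_cpg = index.context[pflat] == CPG
    cpg_positions = ppos[is_cpg]
    for _ in range(n_clones):
        frag = _convert_fragment(genome, methylome, config, rng,
                                 "sssi_locus", 0, L, "+")
        bases = frag.seq[cpg_positions]
        meth_obs += int(np.count_nonzero(bases == ord("C")))
        total_obs += len(cpg_positions)
    return 100.0 * meth_obs / total_obs, total_obs
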