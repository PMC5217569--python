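"""Windowed methylation statistics, run comparison, PMDs and calibration.

Window levels are depth-weighted within each window; windows without calls
are *undefined*, never zero.  PMD calling follows the classic sliding-window
rule: 10-kb windows with at least ten covered CpG sites are eligible,
eligible windows below 70% methylation are PMD windows, contiguous PMD
windows merge, and only merged runs longer than 100 kb are reported
(ineligible windows break contiguity).  Calibration compares observed
mate-stratified levels of spike-in mixture runs against their predetermined
methylated-DNA proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CytosineCallTable, weighted_level
from .genome import CPG, ReferenceGenome, Window, tile_windows


@dataclass
class WindowStat:
    window: Window
    n_cpg: int  # CpG cytosines in the window
    n_covered: int  # of which have >= 1 call
    level: float | None  # percent, None when the window has no calls


def window_levels(
    table: CytosineCallTable, windows: Sequence[Window]
) -> list[WindowStat]:
    """Weighted CpG level per window; windows with zero calls are undefined."""
    idx = table.index
    cpg = idx.context == CPG
    meth = table.counts[:, :, 0].sum(axis=1)
    total = table.counts.sum(axis=(1, 2))
    out: list[WindowStat] = []
    for w in windows:
        ci = idx.chroms.index(w.chrom)
        m = cpg & (idx.chrom_id == ci) & (idx.pos >= w.start) & (idx.pos < w.end)
        n_cpg = int(np.count_nonzero(m))
        tot = int(total[m].sum())
        n_cov = int(np.count_nonzero(total[m] > 0))
        level = 100.0 * meth[m].sum() / tot if tot > 0 else None
        out.append(WindowStat(w, n_cpg, n_cov, level))
    return out


def density_classes(stats_: Sequence[WindowStat], k: int = 9) -> np.ndarray:
    """Assign windows to k CpG-density classes by equal-count quantile
    boundaries on the per-window CpG count; heavily tied counts collapse
    classes (duplicate boundaries are merged)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.array([s.n_cpg for s in stats_])
    if len(counts) < k:
        raise ValueError(f"need at least {k} windows for {k} classes")
    if counts.min() == counts.max():
        return np.zeros(len(counts), dtype=int)
    classes = pd.qcut(counts, q=k, labels=False, duplicates="drop")
    return np.asarray(classes, dtype=int)


@dataclass
class RunComparison:
    table: pd.DataFrame  # chrom,start,end,n_cpg,level_a,level_b,delta,density_class
    slope: float
    intercept: float
    correlation: float

    @property
    def class_delta(self) -> pd.DataFrame:
        return (
            self.table.groupby("density_class", as_index=False)
            .agg(n=("delta", "size"), mean_delta=("delta", "mean"))
        )


def compare_runs(
    stats_a: Sequence[WindowStat],
    stats_b: Sequence[WindowStat],
    k: int = 9,
) -> RunComparison:
    """Per-window level difference (A - B), OLS regression of A on B, and
    the difference summarized per CpG-density class."""
    if [s.window for s in stats_a] != [s.window for s in stats_b]:
        raise ValueError("runs computed on different window sets")
    keep = [
        i
        for i, (a, b) in enumerate(zip(stats_a, stats_b))
        if a.level is not None and b.level is not None
    ]
    if not keep:
        raise ValueError("no window has defined levels in both runs")
    sel_a = [stats_a[i] for i in keep]
    sel_b = [stats_b[i] for i in keep]
    la = np.array([s.level for s in sel_a])
    lb = np.array([s.level for s in sel_b])
    classes = density_classes(sel_a, k=min(k, len(sel_a)))
    df = pd.DataFrame(
        {
            "chrom": [s.window.chrom for s in sel_a],
            "start": [s.window.start for s in sel_a],
            "end": [s.window.end for s in sel_a],
            "n_cpg": [s.n_cpg for s in sel_a],
            "level_a": la,
            "level_b": lb,
            "delta": la - lb,
            "density_class": classes,
        }
    )
    if np.ptp(lb) == 0 or np.ptp(la) == 0:
        # degenerate regression (constant run); slope by convention
        slope, intercept, r = (1.0, 0.0, 1.0) if np.allclose(la, lb) else (
            0.0, float(np.mean(la)), 0.0)
    else:
        res = stats.linregress(lb, la)
        slope, intercept, r = res.slope, res.intercept, res.rvalue
    return RunComparison(df, float(slope), float(intercept), float(r))


@dataclass(frozen=True)
class PMDInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    mean_level: float  # percent, pooled over the merged interval

    @property
    def length(self) -> int:
        return self.end - self.start


def call_pmds(
    table: CytosineCallTable,
    genome: ReferenceGenome | None = None,
    window_size: int = 10_000,
    min_covered_cpg: int = 10,
    level_threshold: float = 70.0,
    min_length: int = 100_000,
) -> list[PMDInterval]:
    """Sliding-window PMD calls.

    A 10-kb window is eligible iff it holds >= ``min_covered_cpg`` CpG
    sites each covered at least once; eligible windows with level strictly
    below ``level_threshold`` are PMD windows; contiguous PMD windows merge
    and only merged intervals strictly longer than ``min_length`` are
    returned.  Ineligible windows break contiguity.
    """
    if genome is not None:
        windows = tile_windows(genome, window_size)
    else:
        g_lengths = table.index.chrom_lengths
        windows = [
            Window(c, s, s + window_size)
            for c, L in g_lengths.items()
            for s in range(0, (L // window_size) * window_size, window_size)
        ]
    stats_ = window_levels(table, windows)
    out: list[PMDInterval] = []
    run: list[WindowStat] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0].window.start, run[-1].window.end
        if end - start > min_length:
            meth, total = table.counts_for(
                "CpG", "both", (run[0].window.chrom, start, end)
            )
            out.append(
                PMDInterval(run[0].window.chrom, start, end, 100.0 * meth / total)
            )
        run.clear()

    prev_chrom = None
    for s in stats_:
        eligible = s.n_covered >= min_covered_cpg and s.level is not None
        is_pmd = eligible and s.level < level_threshold
        contiguous = (
            run
            and s.window.chrom == prev_chrom
            and s.window.start == run[-1].window.end
        )
        if is_pmd and (not run or contiguous):
            run.append(s)
        else:
            flush()
            if is_pmd:
                run.append(s)
        prev_chrom = s.window.chrom
    flush()
    return out


@dataclass(frozen=True)
class CalibrationPoint:
    predetermined: float  # percent methylated DNA in the mixture
    observed_r1: float
    observed_r2: float

    @property
    def diff_r1(self) -> float:
        return self.observed_r1 - self.predetermined

    @property
    def diff_r2(self) -> float:
        return self.observed_r2 - self.predetermined

    @property
    def r1_r2_gap(self) -> float:
        return self.observed_r1 - self.observed_r2


def calibrate_mixtures(
    runs: Sequence[tuple[float, CytosineCallTable]],
) -> list[CalibrationPoint]:
    """One observed-vs-predetermined point per spike-in mixture run,
    mate-stratified."""
    if not runs:
        raise ValueError("no calibration runs given")
    out = []
    for predet, table in runs:
        out.append(
            CalibrationPoint(
                predet,
                weighted_level(table, "CpG", "R1"),
                weighted_level(table, "CpG", "R2"),
            )
        )
    return out


# ------------------------------------------------------------------- I/O

def write_windows_bed(stats_: Sequence[WindowStat], path: str | Path) -> None:
    """Windows as BED with the level (x10, rounded) in the score column;
    undefined windows get score '.'."""
    with open(path, "w") as fh:
        for i, s in enumerate(stats_):
            score = "." if s.level is None else str(int(round(s.level * 10)))
            fh.write(
                f"{s.window.chrom}\t{s.window.start}\t{s.window.end}\t"
                f"win{i}\t{score}\n"
            )


def write_pmds_bed(pmds: Sequence[PMDInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pmds):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tPMD{i}\t{int(round(p.mean_level * 10))}\n"
            )


def write_calibration_tsv(points: Sequence[CalibrationPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "predetermined": [p.predetermined for p in points],
            "observed_r1": [p.observed_r1 for p in points],
            "observed_r2": [p.observed_r2 for p in points],
            "diff_r1": [p.diff_r1 for p in points],
            "diff_r2": [p.diff_r2 for p in points],
            "r1_r2_gap": [p.r1_r2_gap for p in points],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
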