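"""Read-level diagnostics: base composition, quality classes, quality drops.

In a fully converted PBAT library R1 is nearly C-free and its G content
tracks the methylation density, so G is the minority base whose calling the
base caller can get wrong.  These diagnostics quantify that: per-cycle base
composition (low-diversity signature), Phred-class histograms for a chosen
base (how the caller scores G), and the steep-drop statistic — the fraction
of G-containing reads showing an adjacent-cycle quality drop greater than a
threshold at a G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import BisulfiteRead

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

QUALITY_CLASS_EDGES = (0, 10, 20, 30)  # [0,10) [10,20) [20,30) [30,inf)
QUALITY_CLASS_NAMES = ("[0,10)", "[10,20)", "[20,30)", "[30,inf)")


@dataclass
class CompositionProfile:
    """Per-cycle and overall base fractions.

    Fractions are normalized over called A/C/G/T; N is excluded from the
    normalization but its count is reported.
    """

    cycle_counts: np.ndarray  # (max_len, 5) counts of A,C,G,T,N per cycle
    n_reads: int

    @property
    def cycle_fractions(self) -> np.ndarray:
        acgt = self.cycle_counts[:, :4].astype(float)
        tot = acgt.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, acgt / tot, np.nan)

    @property
    def overall_fractions(self) -> dict[str, float]:
        acgt = self.cycle_counts[:, :4].sum(axis=0).astype(float)
        tot = acgt.sum()
        out = {b: (acgt[i] / tot if tot else float("nan")) for i, b in enumerate(_BASES)}
        out["N"] = int(self.cycle_counts[:, 4].sum())
        return out

    def to_dataframe(self) -> pd.DataFrame:
        fr = self.cycle_fractions
        df = pd.DataFrame(fr, columns=list(_BASES))
        df.insert(0, "cycle", np.arange(1, len(df) + 1))
        df["N_count"] = self.cycle_counts[:, 4]
        return df


def base_composition(reads: Sequence[BisulfiteRead]) -> CompositionProfile:
    """Per-cycle A/C/G/T/N fractions; ragged read sets adjust denominators."""
    if not reads:
        raise ValueError("empty read set")
    max_len = max(len(r) for r in reads)
    counts = np.zeros((max_len, 5), dtype=np.int64)
    code = np.full(256, 4, dtype=np.int8)  # everything unexpected counts as N
    for b, i in _BASE_CODE.items():
        code[ord(b)] = i
    for r in reads:
        arr = code[np.frombuffer(r.bases.encode(), np.uint8)]
        np.add.at(counts, (np.arange(len(arr)), arr), 1)
    return CompositionProfile(counts, len(reads))


@dataclass
class QualityClassHistogram:
    """Counts of one base's calls in four Phred classes."""

    base: str
    class_counts: np.ndarray  # length 4, per QUALITY_CLASS_NAMES
    total: int

    @property
    def q30_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.class_counts[3] / self.total

    def as_dict(self) -> dict:
        return {
            "base": self.base,
            "classes": dict(zip(QUALITY_CLASS_NAMES, map(int, self.class_counts))),
            "total": int(self.total),
            "q30_fraction": self.q30_fraction,
        }


def quality_classes(reads: Sequence[BisulfiteRead], base: str) -> QualityClassHistogram:
    """Histogram of the Phred scores assigned to every call of ``base``,
    in the classes [0,10), [10,20), [20,30), [30,inf); 'over 30' follows the
    Q30 convention (Q >= 30)."""
    if not reads:
        raise ValueError("empty read set")
    target = ord(base.upper())
    counts = np.zeros(4, dtype=np.int64)
    edges = np.array(QUALITY_CLASS_EDGES[1:])  # 10, 20, 30
    for r in reads:
        arr = np.frombuffer(r.bases.encode(), np.uint8)
        q = r.quals[arr == target]
        if len(q):
            cls = np.searchsorted(edges, q, side="right")
            np.add.at(counts, cls, 1)
    return QualityClassHistogram(base.upper(), counts, int(counts.sum()))


def detect_drops(
    read: BisulfiteRead, threshold: int = 10, mode: str = "adjacent"
) -> list[tuple[int, str, int]]:
    """Positions where the quality falls by more than ``threshold``.

    mode 'adjacent' (default): position i (i >= 1) is a drop iff
    qual[i-1] - qual[i] > threshold.  mode 'from_max': the drop is measured
    from the running maximum of the preceding cycles instead.
    Returns (position, base, magnitude) triples.
    """
    if len(read) < 2:
        raise ValueError("read too short for drop detection")
    q = read.quals.astype(int)
    if mode == "adjacent":
        ref = q[:-1]
    elif mode == "from_max":
        ref = np.maximum.accumulate(q)[:-1]
    else:
        raise ValueError(f"unknown drop mode {mode!r}")
    diff = ref - q[1:]
    hits = np.nonzero(diff > threshold)[0] + 1
    return [(int(i), read.bases[i], int(diff[i - 1])) for i in hits]


def g_drop_fraction(
    reads: Sequence[BisulfiteRead], threshold: int = 10, mode: str = "adjacent"
) -> float:
    """Fraction of G-containing reads with at least one steep quality drop
    located at a G."""
    n_with_g = 0
    n_drop = 0
    for r in reads:
        if "G" not in r.bases:
            continue
        n_with_g += 1
        if len(r) >= 2 and any(b == "G" for _, b, _ in detect_drops(r, threshold, mode)):
            n_drop += 1
    if n_with_g == 0:
        raise ValueError("no read contains a G")
    return n_drop / n_with_g


@dataclass
class QCReport:
    composition: CompositionProfile
    quality_by_base: dict[str, QualityClassHistogram]
    g_drop_fraction: float | None
    drop_threshold: int = 10

    def as_dict(self) -> dict:
        return {
            "n_reads": self.composition.n_reads,
            "overall_base_fractions": {
                k: (float(v) if isinstance(v, float) else v)
                for k, v in self.composition.overall_fractions.items()
            },
            "quality_classes": {b: h.as_dict() for b, h in self.quality_by_base.items()},
            "g_drop_fraction": self.g_drop_fraction,
            "drop_threshold": self.drop_threshold,
        }


def qc_report(reads: Sequence[BisulfiteRead], drop_threshold: int = 10) -> QCReport:
    comp = base_composition(reads)
    hists = {b: quality_classes(reads, b) for b in _BASES}
    try:
        gdf = g_drop_fraction(reads, drop_threshold)
    except ValueError:
        gdf = None
    return QCReport(comp, hists, gdf, drop_threshold)


def write_qc_report(report: QCReport, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
        fh.write("\n")
    if tsv_path is not None:
        report.composition.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
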