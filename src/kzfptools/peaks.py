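"""ChIP-seq peak filtering and peak-TE association.

Peaks follow the MACS2 summary-table convention: 1-based inclusive
coordinates with a summit offset, fold enrichment over input, and a
q-value.  Filtering removes any peak overlapping a negative-control peak
by >=1 bp, keeps q <= 0.01 and fold enrichment >= 10, and falls back to a
fold-enrichment cutoff of 5 for samples retaining fewer than 20 peaks.
Association with TE families uses the same uniform re-placement
permutation null as the locus enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .repeats import (
    PermutationConfig,
    RepeatRecord,
    _summarise,
    permuted_overlap_counts,
)

__all__ = [
    "PeakRecord",
    "read_peaks",
    "write_peaks",
    "filter_peaks",
    "peak_te_association",
]


@dataclass
class PeakRecord:
    """One called peak; ``begin``/``end`` 1-based inclusive."""

    chromosome: str
    begin: int
    end: int
    summit: int = 0              # offset from begin
    fold_enrichment: float = 0.0
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError("peak begin > end")
        if self.q_value < 0:
            raise ValueError("negative qValue")

    @property
    def start0(self) -> int:
        return self.begin - 1

    @property
    def end0(self) -> int:
        return self.end


_COLUMNS = ["chrom", "start", "end", "summit", "fold_enrichment", "qValue"]


def read_peaks(path: str | Path) -> list[PeakRecord]:
    """Read a tab-separated MACS2-like peak table (header required)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        PeakRecord(
            chromosome=row.chrom,
            begin=int(row.start),
            end=int(row.end),
            summit=int(row.summit),
            fold_enrichment=float(row.fold_enrichment),
            q_value=float(row.qValue),
        )
        for row in df.itertuples()
    ]


def write_peaks(peaks: list[PeakRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": p.chromosome,
                "start": p.begin,
                "end": p.end,
                "summit": p.summit,
                "fold_enrichment": p.fold_enrichment,
                "qValue": p.q_value,
            }
            for p in peaks
        ],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_bed6(peaks: list[PeakRecord], path: str | Path) -> None:
    """BED6 export (0-based half-open; score = fold enrichment)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            fh.write(
                f"{p.chromosome}\t{p.start0}\t{p.end0}\tpeak{i}\t"
                f"{p.fold_enrichment:.3g}\t.\n"
            )


def _overlaps(a: PeakRecord, b: PeakRecord) -> bool:
    return (
        a.chromosome == b.chromosome and a.start0 < b.end0 and b.start0 < a.end0
    )


def filter_peaks(
    peaks: list[PeakRecord],
    negative_control_peaks: list[PeakRecord],
    q_max: float = 0.01,
    fold_primary: float = 10.0,
    fold_fallback: float = 5.0,
    min_peaks: int = 20,
) -> list[PeakRecord]:
    """Negative-control subtraction, then q/fold-enrichment filtering.

    Any peak overlapping any negative-control peak by >=1 bp is dropped
    first (exactly abutting peaks are retained).  Survivors are filtered at
    q <= ``q_max`` and fold enrichment >= ``fold_primary``; if fewer than
    ``min_peaks`` remain, the fold cutoff is relaxed to ``fold_fallback``.
    """
    clean = [
        p
        for p in peaks
        if not any(_overlaps(p, c) for c in negative_control_peaks)
    ]
    qpass = [p for p in clean if p.q_value <= q_max]
    primary = [p for p in qpass if p.fold_enrichment >= fold_primary]
    if len(primary) >= min_peaks:
        return primary
    return [p for p in qpass if p.fold_enrichment >= fold_fallback]


def peak_te_association(
    peaks: list[PeakRecord],
    records: list[RepeatRecord],
    chrom_lengths: dict[str, int],
    cfg: PermutationConfig | None = None,
    display_p: float = 0.001,
) -> pd.DataFrame:
    """Per-family peak overlap with a permutation Z and p-value.

    For each TE family, ``observed`` is the number of peaks overlapping at
    least one family annotation; the null re-places every peak uniformly
    on its own chromosome (independent draws per family, seeded from the
    configuration).  Returns one row per family with the percentage of
    peaks overlapping, Z, p, and a ``display`` flag for p < ``display_p``.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    cfg = cfg or PermutationConfig()
    regions = [(p.chromosome, p.start0, p.end0) for p in peaks]
    families = sorted({r.family for r in records})
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=len(families))
    rows = []
    for fam, seed in zip(families, seeds):
        targets: dict[str, list[tuple[int, int]]] = {}
        for r in records:
            if r.family == fam:
                targets.setdefault(r.chromosome, []).append((r.start0, r.end0))
        rng = np.random.default_rng(int(seed))
        observed, perm = permuted_overlap_counts(
            regions, targets, chrom_lengths, cfg.n, rng
        )
        res = _summarise(observed, perm, cfg.n)
        rows.append(
            {
                "family": fam,
                "n_peaks_overlapping": res.observed,
                "percent_peaks": 100.0 * res.observed / len(peaks),
                "z": res.z,
                "p": res.p,
                "display": res.p < display_p,
            }
        )
    return pd.DataFrame(rows)
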