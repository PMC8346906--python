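"""Windowed recombination rates and triallelic-region contrasts.

Recombination rates are estimated per tiled physical window (100 kb by
default) from a genetic map by linear interpolation of the genetic (cM)
position at the window edges: rate = delta-cM / window-Mb.  Windows are
flagged by overlap with a region set (e.g. the triallelic call set) and
the two groups compared with a two-sided Mann-Whitney U test; a paired
cross-species mode compares per-window rate ratios between two species
through a user-supplied synteny pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval


def windowed_rates(gmap: pd.DataFrame, window_bp: int = 100_000,
                   regions: list[GenomicInterval] | None = None,
                   species: str = "") -> pd.DataFrame:
    """Tile each chromosome and estimate cM/Mb per window.

    ``gmap`` has columns chrom, pos (bp), cm.  Windows start at 0, are
    non-overlapping and are kept only if fully inside the chromosome's
    marker span.  Returns a DataFrame with chrom, start, end, rate,
    overlaps_triallelic, species.
    """
    rows = []
    for chrom, grp in gmap.groupby("chrom", sort=False):
        if len(grp) < 2:
            raise ValueError(f"{chrom}: need >= 2 markers")
        pos = grp["pos"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        lo, hi = pos[0], pos[-1]
        start = 0
        while start + window_bp <= hi:
            if start >= lo:
                cm_lo = float(np.interp(start, pos, cm))
                cm_hi = float(np.interp(start + window_bp, pos, cm))
                rows.append((chrom, start, start + window_bp,
                             (cm_hi - cm_lo) / (window_bp / 1e6)))
            start += window_bp
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])
    df["species"] = species
    df["overlaps_triallelic"] = False
    if regions:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for i, row in df.iterrows():
            for r in by_chrom.get(row["chrom"], ()):
                if row["start"] < r.end and r.start < row["end"]:
                    df.loc[i, "overlaps_triallelic"] = True
                    break
    return df


@dataclass
class GroupComparison:
    mean_overlap: float
    sem_overlap: float
    mean_background: float
    sem_background: float
    p: float
    n_overlap: int
    n_background: int


def group_compare(rates: pd.DataFrame,
                  value_col: str = "rate") -> GroupComparison:
    """Compare overlapping vs. background windows (two-sided Mann-Whitney)."""
    ov = rates.loc[rates["overlaps_triallelic"], value_col].to_numpy()
    bg = rates.loc[~rates["overlaps_triallelic"], value_col].to_numpy()
    if len(ov) == 0 or len(bg) == 0:
        raise ValueError("both window groups must be non-empty")
    p = float(stats.mannwhitneyu(ov, bg, alternative="two-sided").pvalue)
    return GroupComparison(
        mean_overlap=float(ov.mean()),
        sem_overlap=float(ov.std(ddof=1) / np.sqrt(len(ov))) if len(ov) > 1 else float("nan"),
        mean_background=float(bg.mean()),
        sem_background=float(bg.std(ddof=1) / np.sqrt(len(bg))) if len(bg) > 1 else float("nan"),
        p=p, n_overlap=len(ov), n_background=len(bg))


def cross_species_ratio(rates_a: pd.DataFrame, rates_b: pd.DataFrame,
                        synteny: pd.DataFrame
                        ) -> tuple[pd.DataFrame, GroupComparison | None]:
    """Per-window rate ratios between two species over syntenic pairs.

    ``synteny`` has columns chrom_a, start_a, chrom_b, start_b pairing a
    window of species A with one of species B.  Pairs whose species-B
    rate is zero are dropped (count available from the returned frame's
    attrs).  The ratio groups (triallelic flag taken from species A) are
    compared as in :func:`group_compare`; with fewer than two windows in
    either group the comparison is reported as None (descriptive only).
    """
    a = rates_a.set_index(["chrom", "start"])
    b = rates_b.set_index(["chrom", "start"])
    rows, dropped = [], 0
    for _, pair in synteny.iterrows():
        ka = (pair["chrom_a"], pair["start_a"])
        kb = (pair["chrom_b"], pair["start_b"])
        if ka not in a.index or kb not in b.index:
            continue
        rb = float(b.loc[kb, "rate"])
        if rb <= 0:
            dropped += 1
            continue
        rows.append((ka[0], ka[1], float(a.loc[ka, "rate"]) / rb,
                     bool(a.loc[ka, "overlaps_triallelic"])))
    if not rows:
        raise ValueError("no valid syntenic window pairs")
    ratios = pd.DataFrame(rows, columns=["chrom", "start", "ratio",
                                         "overlaps_triallelic"])
    ratios.attrs["n_dropped_zero_rate"] = dropped
    n_ov = int(ratios["overlaps_triallelic"].sum())
    n_bg = len(ratios) - n_ov
    if n_ov >= 2 and n_bg >= 2:
        cmp = group_compare(ratios, value_col="ratio")
    else:
        cmp = None
    return ratios, cmp
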