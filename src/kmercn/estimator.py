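"""Convert raw k-mer counts into GC-corrected, windowed diploid copy-number tracks.

Correction and conversion follow a fixed order: per-GC-bin factors are
fitted on raw control-k-mer counts, applied to every catalog k-mer, and
only then is the diploid baseline (mean corrected control count) used to
scale corrected counts to copy number, with CN 2 the control expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counter import CatalogMismatchError, CountTable
from .indexer import KmerCatalog

__all__ = [
    "EstimatorConfig",
    "GcCurve",
    "ControlSetupError",
    "fit_gc_curve",
    "apply_correction",
    "counts_to_cn",
    "window_track",
    "estimate_track",
    "write_track_bed",
    "read_track_bed",
]

TRACK_COLUMNS = ["chrom", "start", "end", "cn", "n_kmers"]


class ControlSetupError(RuntimeError):
    """No usable control k-mers (missing flags or an empty sample)."""


@dataclass(frozen=True)
class EstimatorConfig:
    window_kmers: int = 1000
    gc_bin_width: float = 0.01
    min_control_per_bin: int = 100
    keep_partial: bool = False
    stat: str = "mean"

    def __post_init__(self) -> None:
        if self.window_kmers < 1:
            raise ValueError("window_kmers must be >= 1")
        if not 0 < self.gc_bin_width <= 1:
            raise ValueError("gc_bin_width must be in (0, 1]")
        if self.stat not in ("mean", "median"):
            raise ValueError("stat must be 'mean' or 'median'")


@dataclass
class GcCurve:
    """Per-GC-bin multiplicative depth-correction factors."""

    bin_width: float
    factors: np.ndarray      # float64, one per bin
    bin_means: np.ndarray    # mean raw control count per bin
    tallies: np.ndarray      # control k-mers per bin
    qualified: np.ndarray    # bool, bins that met min_control_per_bin
    global_mean: float

    @property
    def n_bins(self) -> int:
        return self.factors.size


def _n_bins(width: float) -> int:
    return int(round(1.0 / width)) + 1


def _gc_bin(gc: np.ndarray, width: float) -> np.ndarray:
    idx = np.floor(np.asarray(gc, dtype=np.float64) / width).astype(np.int64)
    return np.clip(idx, 0, _n_bins(width) - 1)


def _check_binding(table: CountTable, catalog: KmerCatalog) -> None:
    if table.catalog_checksum != catalog.checksum():
        raise CatalogMismatchError("counts were built against a different catalog")


def fit_gc_curve(
    table: CountTable, catalog: KmerCatalog, config: EstimatorConfig = EstimatorConfig()
) -> GcCurve:
    """Fit per-bin correction factors from control k-mers.

    factor(bin) = global control mean / bin mean.  Bins with fewer than
    ``min_control_per_bin`` control k-mers (or a zero mean) inherit the
    nearest qualified bin's factor.
    """
    _check_binding(table, catalog)
    ctl = catalog.is_control
    if not ctl.any():
        raise ControlSetupError("catalog has no control k-mers")
    counts = table.counts[ctl].astype(np.float64)
    if counts.sum() == 0:
        raise ControlSetupError("all control k-mer counts are zero (empty sample?)")
    nb = _n_bins(config.gc_bin_width)
    idx = _gc_bin(catalog.gc_fraction[ctl], config.gc_bin_width)
    tallies = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=counts, minlength=nb)
    means = sums / np.maximum(tallies, 1)
    gmean = float(counts.mean())
    qualified = (tallies >= config.min_control_per_bin) & (means > 0)
    if not qualified.any():
        warnings.warn(
            "no GC bin reached min_control_per_bin; falling back to all non-empty bins",
            RuntimeWarning,
            stacklevel=2,
        )
        qualified = (tallies > 0) & (means > 0)
    q = np.flatnonzero(qualified)
    # nearest qualified bin for every bin (ties resolved toward lower GC)
    pos = np.searchsorted(q, np.arange(nb))
    left = np.clip(pos - 1, 0, q.size - 1)
    right = np.clip(pos, 0, q.size - 1)
    pick = np.where(
        np.abs(np.arange(nb) - q[left]) <= np.abs(q[right] - np.arange(nb)),
        q[left],
        q[right],
    )
    factors = gmean / means[pick]
    return GcCurve(
        bin_width=config.gc_bin_width,
        factors=factors,
        bin_means=means,
        tallies=tallies,
        qualified=qualified,
        global_mean=gmean,
    )


def apply_correction(
    table: CountTable, catalog: KmerCatalog, curve: GcCurve
) -> np.ndarray:
    """corrected[i] = counts[i] * factor(GC bin of k-mer i), for every k-mer."""
    _check_binding(table, catalog)
    idx = _gc_bin(catalog.gc_fraction, curve.bin_width)
    return table.counts.astype(np.float64) * curve.factors[idx]


def counts_to_cn(corrected: np.ndarray, catalog: KmerCatalog) -> np.ndarray:
    """cn[i] = 2 * corrected[i] / mean corrected control count."""
    corrected = np.asarray(corrected, dtype=np.float64)
    ctl = catalog.is_control
    if not ctl.any():
        raise ControlSetupError("catalog has no control k-mers")
    mu = float(corrected[ctl].mean())
    if mu == 0:
        raise ControlSetupError("diploid baseline is zero")
    return 2.0 * corrected / mu


def window_track(
    cn: np.ndarray, catalog: KmerCatalog, config: EstimatorConfig = EstimatorConfig()
) -> pd.DataFrame:
    """Group consecutive catalog k-mers W at a time into BED-style windows.

    Window cn is the mean (or median) of its k-mers' values; the interval
    runs from the first k-mer's 5' end to the last k-mer's 3' end.  Windows
    never span chromosomes; terminal groups with fewer than W k-mers are
    dropped unless ``keep_partial``.
    """
    cn = np.asarray(cn, dtype=np.float64)
    if cn.size != len(catalog):
        raise ValueError("cn array does not match catalog size")
    W = config.window_kmers
    names = catalog.chrom_names
    stat = np.mean if config.stat == "mean" else np.median
    rows: list[tuple[str, int, int, float, int]] = []
    boundaries = np.flatnonzero(np.diff(catalog.chrom_id)) + 1
    for seg in np.split(np.arange(len(catalog)), boundaries):
        if seg.size == 0:
            continue
        cid = int(catalog.chrom_id[seg[0]])
        for lo in range(0, seg.size, W):
            grp = seg[lo : lo + W]
            if grp.size < W and not config.keep_partial:
                continue
            rows.append(
                (
                    names[cid],
                    int(catalog.start[grp[0]]),
                    int(catalog.start[grp[-1]]) + catalog.k,
                    float(stat(cn[grp])),
                    int(grp.size),
                )
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def estimate_track(
    table: CountTable, catalog: KmerCatalog, config: EstimatorConfig = EstimatorConfig()
) -> pd.DataFrame:
    """Raw counts -> GC correction -> CN conversion -> windowed track."""
    curve = fit_gc_curve(table, catalog, config)
    corrected = apply_correction(table, catalog, curve)
    cn = counts_to_cn(corrected, catalog)
    return window_track(cn, catalog, config)


def write_track_bed(track: pd.DataFrame, path) -> None:
    """4-column BED (chrom, start, end, cn to 4 decimals), sorted as given."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcn\n")
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.cn:.4f}\n")


def read_track_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3]), -1))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.drop(columns=["n_kmers"])
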