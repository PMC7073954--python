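"""Multi-sample summaries: QC metrics, cross-sample window ranges, gene-level
copy numbers, heatmap tracks, and browser track-hub emission."""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmptyTrackError",
    "WindowMismatchError",
    "SexKaryotype",
    "GRCH38_PAR",
    "sample_mad",
    "outlier_fraction",
    "summarize_samples",
    "window_ranges",
    "select_longest_isoform",
    "gene_copy_number",
    "gene_cn_matrix",
    "round_half_away",
    "heatmap_bed",
    "write_bed9",
    "build_trackhub",
    "validate_trackhub",
]


class EmptyTrackError(ValueError):
    """An operation that needs >= 1 window was given an empty track."""


class WindowMismatchError(ValueError):
    """Samples being combined do not share identical window coordinates."""


#: GRCh38 pseudoautosomal regions on chrX, 0-based half-open.
GRCH38_PAR: tuple[tuple[str, int, int], ...] = (
    ("chrX", 10_000, 2_781_479),
    ("chrX", 155_701_382, 156_030_895),
)


@dataclass
class SexKaryotype:
    """Per-sample XX/XY flags plus the PAR intervals of the reference build."""

    sexes: Mapping[str, str]
    par: Sequence[tuple[str, int, int]] = GRCH38_PAR
    chrx: str = "chrX"

    def is_male(self, sample: str) -> bool:
        sex = self.sexes.get(sample, "XX").upper()
        if sex not in ("XX", "XY"):
            raise ValueError(f"sample {sample}: sex must be XX or XY, got {sex!r}")
        return sex == "XY"

    def overlaps_par(self, chrom: str, start: int, end: int) -> bool:
        return any(
            chrom == pc and start < pe and end > ps for pc, ps, pe in self.par
        )

    def in_nonpar_x(self, chrom: str, start: int, end: int) -> bool:
        """True iff the interval is on chrX and entirely outside every PAR."""
        return chrom == self.chrx and not self.overlaps_par(chrom, start, end)


# ---------------------------------------------------------------------------
# Per-sample QC
# ---------------------------------------------------------------------------

def sample_mad(track: pd.DataFrame) -> float:
    """Unscaled median absolute deviation of window copy numbers."""
    if len(track) == 0:
        raise EmptyTrackError("cannot compute MAD of an empty track")
    cn = track["cn"].to_numpy(dtype=float)
    return float(np.median(np.abs(cn - np.median(cn))))


def outlier_fraction(track: pd.DataFrame) -> float:
    """Fraction of windows with cn strictly below 1.5 or strictly above 2.5."""
    if len(track) == 0:
        raise EmptyTrackError("cannot compute outlier fraction of an empty track")
    cn = track["cn"].to_numpy(dtype=float)
    return float(np.mean((cn < 1.5) | (cn > 2.5)))


def summarize_samples(tracks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = [
        {"sample": s, "mad": sample_mad(t), "frac_outside": outlier_fraction(t)}
        for s, t in tracks.items()
    ]
    return pd.DataFrame(rows, columns=["sample", "mad", "frac_outside"])


# ---------------------------------------------------------------------------
# Cross-sample window ranges
# ---------------------------------------------------------------------------

def window_ranges(tracks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-window min / max / mean / range of cn across samples."""
    if not tracks:
        raise ValueError("no tracks supplied")
    items = list(tracks.items())
    ref = items[0][1]
    coords = ref[["chrom", "start", "end"]]
    for name, t in items[1:]:
        if len(t) != len(ref) or not coords.equals(t[["chrom", "start", "end"]]):
            raise WindowMismatchError(f"sample {name}: window coordinates differ")
    stack = np.vstack([t["cn"].to_numpy(dtype=float) for _, t in items])
    out = coords.copy()
    out["min"] = stack.min(axis=0)
    out["max"] = stack.max(axis=0)
    out["mean"] = stack.mean(axis=0)
    out["range"] = out["max"] - out["min"]
    return out


# ---------------------------------------------------------------------------
# Gene-level copy number
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["chrom", "start", "end", "gene", "transcript"]


def select_longest_isoform(genes: pd.DataFrame) -> pd.DataFrame:
    """One interval per gene symbol: the longest span, ties to the
    lexicographically smallest transcript id."""
    g = genes.copy()
    g["_span"] = g["end"] - g["start"]
    g = g.sort_values(["gene", "_span", "transcript"], ascending=[True, False, True])
    return g.drop_duplicates("gene").drop(columns="_span").reset_index(drop=True)


def _intersecting(track: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    return track[
        (track["chrom"] == chrom) & (track["end"] > start) & (track["start"] < end)
    ]


def gene_copy_number(
    gene: Mapping,
    track: pd.DataFrame,
    sample: str | None = None,
    karyotype: SexKaryotype | None = None,
    min_windows: int = 3,
) -> float | None:
    """Median cn of windows overlapping the gene (>= 1 bp, half-open).

    Returns None (excluded) when fewer than ``min_windows`` windows
    intersect.  For XY samples, values of genes lying entirely in chrX
    nonPAR are doubled before reporting.
    """
    chrom, start, end = gene["chrom"], int(gene["start"]), int(gene["end"])
    hits = _intersecting(track, chrom, start, end)
    if len(hits) < min_windows:
        return None
    value = float(np.median(hits["cn"].to_numpy(dtype=float)))
    if (
        karyotype is not None
        and sample is not None
        and karyotype.is_male(sample)
        and karyotype.in_nonpar_x(chrom, start, end)
    ):
        value *= 2.0
    return value


def gene_cn_matrix(
    genes: pd.DataFrame,
    tracks: Mapping[str, pd.DataFrame],
    karyotype: SexKaryotype | None = None,
    min_windows: int = 3,
    exclude_chroms: Sequence[str] = ("chrM",),
) -> pd.DataFrame:
    """Gene x sample matrix of median-of-windows copy numbers.

    Mitochondrial genes (``exclude_chroms``) and genes intersecting fewer
    than ``min_windows`` windows are omitted.
    """
    chosen = select_longest_isoform(genes)
    chosen = chosen[~chosen["chrom"].isin(exclude_chroms)]
    records = []
    for gene in chosen.to_dict("records"):
        values = {
            s: gene_copy_number(gene, t, s, karyotype, min_windows)
            for s, t in tracks.items()
        }
        if any(v is None for v in values.values()):
            continue
        records.append({"gene": gene["gene"], **values})
    cols = ["gene", *tracks.keys()]
    return pd.DataFrame(records, columns=cols).set_index("gene")


# ---------------------------------------------------------------------------
# Heatmap BED9 and track hub
# ---------------------------------------------------------------------------

#: itemRgb palette for rounded copy numbers 0..10 plus a >10 saturation color
HEATMAP_PALETTE: tuple[str, ...] = (
    "229,229,229",  # 0  light grey
    "196,196,255",  # 1
    "0,0,0",        # 2  black: the diploid expectation
    "255,255,0",    # 3
    "255,192,0",    # 4
    "255,128,0",    # 5
    "255,64,0",     # 6
    "255,0,0",      # 7
    "192,0,64",     # 8
    "128,0,128",    # 9
    "64,0,192",     # 10
)
HEATMAP_SATURATION = "0,0,255"  # > 10


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (2.5 -> 3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def heatmap_bed(track: pd.DataFrame) -> pd.DataFrame:
    """BED9 rows whose itemRgb encodes the rounded copy number."""
    level = round_half_away(track["cn"].to_numpy(dtype=float)).astype(int)
    colors = [
        HEATMAP_PALETTE[v] if 0 <= v <= 10 else HEATMAP_SATURATION for v in level
    ]
    return pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["start"],
            "end": track["end"],
            "name": [f"cn_{v}" for v in level],
            "score": 0,
            "strand": ".",
            "thickStart": track["start"],
            "thickEnd": track["end"],
            "itemRgb": colors,
        }
    )


def write_bed9(bed9: pd.DataFrame, path: str | Path) -> None:
    bed9.to_csv(path, sep="\t", header=False, index=False)


_REQUIRED_TRACK_KEYS = ("track", "shortLabel", "longLabel", "type", "bigDataUrl")


def build_trackhub(
    samples: Sequence[tuple[str, str, str | Path, str | Path]],
    outdir: str | Path,
    hub_name: str = "kmercn",
    genome: str = "custom",
    email: str = "nobody@example.org",
) -> Path:
    """Emit a hub directory (hub.txt, genomes.txt, trackDb.txt).

    ``samples`` holds (sample, population, raw_bed, heatmap_bed) tuples;
    each sample contributes a raw and a heatmap track stanza, grouped per
    population via superTrack containers.
    """
    names = [s for s, *_ in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names in track hub input")
    outdir = Path(outdir)
    gdir = outdir / genome
    gdir.mkdir(parents=True, exist_ok=True)
    (outdir / "hub.txt").write_text(
        f"hub {hub_name}\n"
        f"shortLabel {hub_name}\n"
        f"longLabel {hub_name} copy-number tracks\n"
        f"genomesFile genomes.txt\n"
        f"email {email}\n"
    )
    (outdir / "genomes.txt").write_text(
        f"genome {genome}\ntrackDb {genome}/trackDb.txt\n"
    )
    stanzas: list[str] = []
    for pop in sorted({p for _, p, *_ in samples}):
        stanzas.append(
            f"track pop_{pop}\n"
            f"superTrack on show\n"
            f"shortLabel {pop}\n"
            f"longLabel {pop} samples\n"
        )
    for sample, pop, raw_bed, heat_bed in samples:
        for kind, src in (("raw", raw_bed), ("heatmap", heat_bed)):
            dest = gdir / f"{sample}.{kind}.bed"
            if Path(src).resolve() != dest.resolve():
                shutil.copyfile(src, dest)
            stanzas.append(
                f"track {sample}_{kind}\n"
                f"parent pop_{pop}\n"
                f"shortLabel {sample} {kind}\n"
                f"longLabel {sample} copy number ({kind})\n"
                f"type bed 9\n"
                f"itemRgb on\n"
                f"bigDataUrl {dest.name}\n"
            )
    (gdir / "trackDb.txt").write_text("\n".join(stanzas) + ("\n" if stanzas else ""))
    return outdir


def _parse_stanzas(text: str) -> list[dict[str, str]]:
    stanzas: list[dict[str, str]] = []
    cur: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            if cur:
                stanzas.append(cur)
                cur = {}
            continue
        key, _, val = line.partition(" ")
        cur[key] = val
    if cur:
        stanzas.append(cur)
    return stanzas


def validate_trackhub(outdir: str | Path) -> list[str]:
    """Offline syntax check; returns a list of problems (empty when valid)."""
    outdir = Path(outdir)
    problems: list[str] = []
    hub = outdir / "hub.txt"
    if not hub.exists():
        return ["hub.txt missing"]
    hub_keys = _parse_stanzas(hub.read_text())
    hub_kv = hub_keys[0] if hub_keys else {}
    for key in ("hub", "shortLabel", "longLabel", "genomesFile", "email"):
        if key not in hub_kv:
            problems.append(f"hub.txt: missing key {key}")
    genomes = outdir / hub_kv.get("genomesFile", "genomes.txt")
    if not genomes.exists():
        problems.append("genomes file missing")
        return problems
    for gst in _parse_stanzas(genomes.read_text()):
        if "genome" not in gst or "trackDb" not in gst:
            problems.append("genomes.txt: stanza missing genome/trackDb")
            continue
        tdb = outdir / gst["trackDb"]
        if not tdb.exists():
            problems.append(f"{gst['trackDb']} missing")
            continue
        seen: set[str] = set()
        for st in _parse_stanzas(tdb.read_text()):
            name = st.get("track")
            if name is None:
                problems.append("trackDb stanza without a track name")
                continue
            if name in seen:
                problems.append(f"duplicate track name {name}")
            seen.add(name)
            is_container = "superTrack" in st or "compositeTrack" in st
            required = ("track", "shortLabel", "longLabel") if is_container else _REQUIRED_TRACK_KEYS
            for key in required:
                if key not in st:
                    problems.append(f"track {name}: missing key {key}")
            if "parent" in st and st["parent"].split()[0] not in seen:
                problems.append(f"track {name}: parent {st['parent']} not defined before use")
            if "bigDataUrl" in st and not (tdb.parent / st["bigDataUrl"]).exists():
                problems.append(f"track {name}: data file {st['bigDataUrl']} missing")
    return problems
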