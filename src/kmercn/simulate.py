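"""Deterministic toy-data generator: references with implanted diverged
duplications, diploid CNV genotypes, GC-biased reads, and truth tracks.

Everything is seeded, so the full pipeline (make -> implant -> genotype ->
simulate -> index -> count -> estimate) is byte-identical across runs, and
no external downloads are needed to exercise any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .indexer import ControlRegions, prepare_control

__all__ = [
    "ReadSimConfig",
    "CnvEvent",
    "Scenario",
    "make_reference",
    "implant_duplication",
    "apply_events",
    "truth_track",
    "genotype_cohort",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth_bed",
    "paralog_scenario",
    "write_scenario",
]

_LUT = np.frombuffer(b"ACTG", dtype=np.uint8)  # index = 2-bit code
_CODE = {"A": 0, "C": 1, "T": 2, "G": 3}


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.01
    gc_bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class CnvEvent:
    """A sample-level event on final reference coordinates.

    kind is 'deletion' or 'duplication' (tandem, one extra copy);
    haplotypes lists the haplotype indices (0/1) carrying the event.
    """

    kind: str
    start: int
    end: int
    haplotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


def make_reference(
    length: int,
    gc_target: float = 0.5,
    seed: int = 0,
    gc_amplitude: float = 0.0,
    gc_period: int | None = None,
) -> str:
    """Random sequence with controllable (optionally position-varying) GC.

    With ``gc_amplitude``/``gc_period`` set, the local GC target follows a
    sinusoid around ``gc_target`` — useful for exercising GC-bias removal
    over a wide GC range.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.arange(length, dtype=np.float64)
    gc = np.full(length, float(gc_target))
    if gc_amplitude and gc_period:
        gc = gc + gc_amplitude * np.sin(2 * np.pi * pos / gc_period)
    gc = np.clip(gc, 0.02, 0.98)
    u = rng.random(length)
    # base codes: A=0, C=1, T=2, G=3 with P(C)=P(G)=gc/2
    t1 = (1 - gc) / 2          # A
    t2 = t1 + gc / 2           # C
    t3 = t2 + (1 - gc) / 2     # T
    codes = (u >= t1).astype(np.uint8) + (u >= t2) + (u >= t3)
    return bytes(_LUT[codes]).decode("ascii")


def implant_duplication(
    seq: str,
    source: tuple[int, int],
    insert_at: int,
    divergence: float = 0.0,
    seed: int = 0,
) -> tuple[str, dict]:
    """Insert a (possibly diverged) copy of ``seq[source]`` at ``insert_at``.

    Returns the modified sequence plus a report with the source and copy
    intervals in the *new* coordinate system and the exact diverged
    positions (absolute, within the copy).
    """
    s, e = source
    if not 0 <= s < e <= len(seq):
        raise ValueError(f"source interval [{s}, {e}) out of bounds")
    if s <= insert_at < e:
        raise ValueError("insertion point lies inside the source interval")
    if not 0 <= insert_at <= len(seq):
        raise ValueError("insertion point out of bounds")
    rng = np.random.default_rng(seed)
    segment = np.frombuffer(seq[s:e].encode("ascii"), dtype=np.uint8).copy()
    codes = (segment >> 1) & 3
    mut = rng.random(codes.size) < divergence
    shift = rng.integers(1, 4, size=codes.size, dtype=np.uint8)
    codes = np.where(mut, (codes + shift) % 4, codes).astype(np.uint8)
    copy = bytes(_LUT[codes]).decode("ascii")
    new_seq = seq[:insert_at] + copy + seq[insert_at:]
    size = e - s
    offset = size if insert_at <= s else 0
    report = {
        "source": (s + offset, e + offset),
        "copy": (insert_at, insert_at + size),
        "diverged_positions": (np.flatnonzero(mut) + insert_at).tolist(),
    }
    return new_seq, report


def apply_events(seq: str, events: Iterable[CnvEvent], haplotype: int) -> str:
    """Realize the events carried by one haplotype on the reference sequence."""
    carried = [ev for ev in events if haplotype in ev.haplotypes]
    for ev in sorted(carried, key=lambda ev: ev.start, reverse=True):
        if ev.kind == "deletion":
            seq = seq[: ev.start] + seq[ev.end :]
        else:  # tandem duplication, one extra copy
            seq = seq[: ev.end] + seq[ev.start : ev.end] + seq[ev.end :]
    return seq


def truth_track(
    events: Iterable[CnvEvent], length: int, chrom: str = "chr1"
) -> list[tuple[str, int, int, int]]:
    """Piecewise-constant true copy number over reference coordinates.

    cn(base) = 2 + copies gained - copies lost, summed over haplotypes.
    """
    delta = np.zeros(length + 1, dtype=np.int64)
    for ev in events:
        change = len(ev.haplotypes) * (1 if ev.kind == "duplication" else -1)
        delta[ev.start] += change
        delta[ev.end] -= change
    cn = 2 + np.cumsum(delta[:-1])
    edges = np.flatnonzero(np.diff(cn)) + 1
    bounds = np.concatenate(([0], edges, [length]))
    return [
        (chrom, int(a), int(b), int(cn[a])) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def genotype_cohort(
    loci: Sequence[dict],
    n_individuals: int,
    frequencies: Sequence[float],
    length: int,
    seed: int = 0,
    chrom: str = "chr1",
) -> list[dict]:
    """Draw per-haplotype genotypes for each locus and derive truth tracks.

    Each locus is a dict with 'kind', 'start', 'end'; the corresponding
    allele frequency is applied independently per haplotype.
    """
    if len(loci) != len(frequencies):
        raise ValueError("loci and frequencies must align")
    if any(not 0 <= f <= 1 for f in frequencies):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_individuals):
        events = []
        for locus, freq in zip(loci, frequencies):
            haps = tuple(h for h in (0, 1) if rng.random() < freq)
            if haps:
                events.append(
                    CnvEvent(locus["kind"], locus["start"], locus["end"], haps)
                )
        cohort.append(
            {
                "individual": f"ind{i}",
                "events": events,
                "truth": truth_track(events, length, chrom),
            }
        )
    return cohort


def _seq_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ((raw & 0xDF) >> 1) & 3


def simulate_reads(
    haplotypes: Sequence[str], config: ReadSimConfig
) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) single-end reads from a diploid genome.

    Start positions are uniform per haplotype, thinned by a GC-dependent
    acceptance probability (1 + A*sin(2*pi*gc)) / (1 + A) computed on the
    error-free fragment; substitution errors are i.i.d.; strands are
    equiprobable.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    ploidy = max(len(haplotypes), 1)
    counter = 0
    for h, seq in enumerate(haplotypes):
        if len(seq) < rl:
            continue
        n_reads = int(round(config.depth / ploidy * len(seq) / rl))
        starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
        codes_seq = _seq_codes(seq)
        idx = starts[:, None] + np.arange(rl)
        codes = codes_seq[idx]
        if config.gc_bias_amplitude:
            gc = ((codes == 1) | (codes == 3)).mean(axis=1)
            amp = config.gc_bias_amplitude
            accept = (1.0 + amp * np.sin(2 * np.pi * gc)) / (1.0 + abs(amp))
            keep = rng.random(n_reads) < np.clip(accept, 0.0, 1.0)
            codes = codes[keep]
        if config.error_rate:
            err = rng.random(codes.shape) < config.error_rate
            shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
            codes = np.where(err, (codes + shift) % 4, codes).astype(np.uint8)
        flip = rng.random(codes.shape[0]) < 0.5
        codes[flip] = (codes[flip, ::-1] ^ 2) & 3  # reverse complement
        chars = _LUT[codes]
        for row in chars:
            yield f"read_h{h}_{counter}", bytes(row).decode("ascii")
            counter += 1


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_truth_bed(truth: Sequence[tuple[str, int, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, cn in truth:
            fh.write(f"{chrom}\t{s}\t{e}\t{cn}\n")


# ---------------------------------------------------------------------------
# Standard demo scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A ready-to-run diploid fixture around one reference chromosome."""

    chrom: str
    reference: dict[str, str]
    haplotypes: list[str]
    events: list[CnvEvent]
    truth: list[tuple[str, int, int, int]]
    control: ControlRegions
    regions: dict[str, tuple[int, int]]
    diverged_positions: list[int]
    read_config: ReadSimConfig

    def reads(self) -> Iterator[tuple[str, str]]:
        return simulate_reads(self.haplotypes, self.read_config)


def paralog_scenario(
    seed: int = 7,
    length: int = 500_000,
    event_size: int = 5_000,
    divergence: float = 0.05,
    depth: float = 20.0,
    error_rate: float = 0.01,
    read_length: int = 100,
    gc_bias_amplitude: float = 0.0,
    gc_amplitude: float = 0.0,
    gc_period: int | None = None,
    control_margin: int = 3_000,
    chrom: str = "chr1",
) -> Scenario:
    """The standard parameter-recovery fixture.

    The reference carries a diverged duplication (source + copy).  The
    simulated diploid has a hemizygous deletion (truth 1), a homozygous
    tandem duplication (truth 4), and a deletion of the duplicated copy on
    one haplotype (truth 1 for the copy's paralog-specific k-mers, 2 for
    the source's).  Control regions are the complement of all event and
    paralog intervals padded by ``control_margin``.
    """
    if event_size > 0.16 * length:
        raise ValueError("event_size must be at most 16% of the genome length")
    base = make_reference(
        length, 0.5, seed=seed, gc_amplitude=gc_amplitude, gc_period=gc_period
    )
    src = (int(length * 0.68), int(length * 0.68) + event_size)
    ins = int(length * 0.84)
    ref, report = implant_duplication(base, src, ins, divergence, seed=seed + 1)
    final_len = len(ref)

    del_iv = (int(length * 0.2), int(length * 0.2) + event_size)
    dup_iv = (int(length * 0.4), int(length * 0.4) + event_size)
    copy_iv = report["copy"]
    events = [
        CnvEvent("deletion", *del_iv, haplotypes=(0,)),
        CnvEvent("duplication", *dup_iv, haplotypes=(0, 1)),
        CnvEvent("deletion", *copy_iv, haplotypes=(0,)),
    ]
    haplotypes = [apply_events(ref, events, h) for h in (0, 1)]

    regions = {
        "hemizygous_deletion": del_iv,
        "homozygous_duplication": dup_iv,
        "paralog_deleted": copy_iv,
        "paralog_partner": report["source"],
    }
    exclude = [
        (chrom, max(0, s - control_margin), min(final_len, e + control_margin))
        for s, e in regions.values()
    ]
    control = ControlRegions.from_intervals(
        prepare_control({chrom: final_len}, exclude).intervals()
    )
    return Scenario(
        chrom=chrom,
        reference={chrom: ref},
        haplotypes=haplotypes,
        events=events,
        truth=truth_track(events, final_len, chrom),
        control=control,
        regions=regions,
        diverged_positions=report["diverged_positions"],
        read_config=ReadSimConfig(
            read_length=read_length,
            depth=depth,
            error_rate=error_rate,
            gc_bias_amplitude=gc_bias_amplitude,
            seed=seed + 2,
        ),
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> Path:
    """Emit the fixture directory: FASTA, FASTQ, control/truth BEDs, gene models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.reference, outdir / "reference.fa")
    write_fastq(scenario.reads(), outdir / "reads.fastq")
    scenario.control.to_bed(outdir / "control.bed")
    write_truth_bed(scenario.truth, outdir / "truth.bed")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tgene\ttranscript\n")
        for name, (s, e) in scenario.regions.items():
            fh.write(f"{scenario.chrom}\t{s}\t{e}\tGENE_{name}\ttx_{name}.1\n")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("#sample\tsex\tpopulation\nsim1\tXX\tSIM\n")
    return outdir
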