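"""Read-level and coverage-level signal processing.

Implements the mCRAC quantification chain: PCR-duplicate collapsing by
(chromosome, strand, start, barcode), reads-per-million coverage, replicate
averaging, per-base log2 phospho/total enrichment with 5 pseudocounts, 20-nt
binning into the 5-mark observation matrix, plus the read-level summary
statistics (spliced/unspliced junction ratio, hierarchical biotype
assignment, 5' density drop).
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Gene
from .tracks import (DEFAULT_BIN_WIDTH, DEFAULT_PSEUDOCOUNT, MARKS,
                     CoverageTrack, EnrichmentMatrix)

READ_COLUMNS = ["chrom", "start", "end", "strand", "barcode", "junction_tag"]


@dataclass(frozen=True)
class JunctionCounts:
    """Counts of junction-spanning reads: exon-exon (spliced), exon-intron
    and intron-exon (unspliced)."""

    ExEx: int
    ExI: int
    IEx: int

    def __post_init__(self) -> None:
        if min(self.ExEx, self.ExI, self.IEx) < 0:
            raise ValueError("junction counts must be non-negative")

    @classmethod
    def from_reads(cls, reads: pd.DataFrame) -> "JunctionCounts":
        c = reads["junction_tag"].value_counts()
        return cls(ExEx=int(c.get("ExEx", 0)), ExI=int(c.get("ExI", 0)),
                   IEx=int(c.get("IEx", 0)))


def collapse_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: keep the first read per distinct
    (chromosome, strand, start, barcode); output preserves input order."""
    if len(reads) == 0:
        return reads.copy()
    return reads.drop_duplicates(
        subset=["chrom", "strand", "start", "barcode"], keep="first"
    ).reset_index(drop=True)


def coverage_from_reads(reads: pd.DataFrame, chrom_sizes: dict[str, int],
                        total_for_rpm: float | None = None) -> CoverageTrack:
    """Strand-specific RPM coverage from full read footprints [start, end)."""
    if total_for_rpm is None:
        if len(reads) == 0:
            raise ValueError("no reads: cannot normalize an empty table to RPM")
        total_for_rpm = float(len(reads))
    if total_for_rpm <= 0:
        raise ValueError("total_for_rpm must be positive")
    track = CoverageTrack.zeros(chrom_sizes, units="counts")
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=False):
        size = chrom_sizes[chrom]
        diff = np.zeros(size + 1)
        starts = grp["start"].to_numpy(dtype=np.int64).clip(0, size)
        ends = grp["end"].to_numpy(dtype=np.int64).clip(0, size)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        track.data[(chrom, strand)] = np.cumsum(diff[:-1])
    rpm = track.map_values(lambda v: v * 1e6 / total_for_rpm)
    rpm.units = "rpm"
    rpm.library_size = total_for_rpm
    return rpm


def average_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of replicate tracks (same genome, same units)."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    keys = set(first.keys())
    for t in tracks[1:]:
        if t.chrom_sizes != first.chrom_sizes or set(t.keys()) != keys:
            raise ValueError("replicate tracks cover different genomes")
        if t.units != first.units:
            raise ValueError("replicate tracks have mixed units")
    out = {k: np.mean([t.data[k] for t in tracks], axis=0) for k in first.keys()}
    return CoverageTrack(chrom_sizes=dict(first.chrom_sizes), data=out,
                         units=first.units, library_size=first.library_size)


def log2_enrichment(phospho: CoverageTrack, total: CoverageTrack,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> CoverageTrack:
    """Per-base log2((phospho + pc) / (total + pc)) on the RPM scale."""
    for t in (phospho, total):
        if t.units != "rpm":
            raise ValueError("enrichment is defined on RPM tracks")
    if set(phospho.keys()) != set(total.keys()):
        raise ValueError("phospho and total tracks cover different genomes")
    data = {}
    for key in phospho.keys():
        p, t = phospho.data[key], total.data[key]
        if p.min() < 0 or t.min() < 0:
            raise ValueError(f"negative coverage values in {key}")
        data[key] = np.log2((p + pseudocount) / (t + pseudocount))
    out = CoverageTrack(chrom_sizes=dict(phospho.chrom_sizes), data=data,
                        units="rpm")
    return out


def bin_track(track: CoverageTrack, bin_width: int = DEFAULT_BIN_WIDTH
              ) -> dict[tuple[str, str], np.ndarray]:
    """Mean per-base value in consecutive bins; trailing partial bin dropped."""
    out = {}
    for key, arr in track.data.items():
        n = (arr.size // bin_width) * bin_width
        out[key] = arr[:n].reshape(-1, bin_width).mean(axis=1)
    return out


def bin_enrichment(per_mark_tracks: "OrderedDict[str, CoverageTrack] | dict",
                   bin_width: int = DEFAULT_BIN_WIDTH,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> EnrichmentMatrix:
    """Bin five per-mark enrichment tracks and stack them into the 5-mark
    observation matrix (mark order fixed as Tyr1, Ser2, Thr4, Ser5, Ser7)."""
    if set(per_mark_tracks) != set(MARKS):
        raise ValueError(f"expected exactly the marks {MARKS}, "
                         f"got {tuple(per_mark_tracks)}")
    binned = {mark: bin_track(per_mark_tracks[mark], bin_width) for mark in MARKS}
    keys = list(binned[MARKS[0]].keys())
    data = {}
    for key in keys:
        cols = [binned[mark][key] for mark in MARKS]
        if len({c.size for c in cols}) != 1:
            raise ValueError(f"marks disagree on bin count for {key}")
        data[key] = np.stack(cols, axis=1)
    return EnrichmentMatrix(data=data, bin_width=bin_width, pseudocount=pseudocount)


def stack_marks(per_mark_matrices: dict[str, EnrichmentMatrix]) -> EnrichmentMatrix:
    """Stack five single-mark binned matrices into one 5-mark matrix."""
    if set(per_mark_matrices) != set(MARKS):
        raise ValueError(f"expected exactly the marks {MARKS}")
    first = per_mark_matrices[MARKS[0]]
    data = {}
    for key in first.keys():
        cols = [np.asarray(per_mark_matrices[m].data[key]).reshape(-1) for m in MARKS]
        data[key] = np.stack(cols, axis=1)
    return EnrichmentMatrix(data=data, bin_width=first.bin_width,
                            pseudocount=first.pseudocount)


def enrichment_from_tracks(total: CoverageTrack,
                           phospho: dict[str, CoverageTrack],
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           bin_width: int = DEFAULT_BIN_WIDTH) -> EnrichmentMatrix:
    """Full chain: RPM -> per-base log2 enrichment -> 20-nt binned matrix."""
    total_rpm = total.to_rpm()
    per_mark = {mark: log2_enrichment(phospho[mark].to_rpm(), total_rpm, pseudocount)
                for mark in MARKS}
    return bin_enrichment(per_mark, bin_width=bin_width, pseudocount=pseudocount)


def spliced_ratio(j: JunctionCounts) -> float:
    """Spliced/unspliced measure (2*ExEx)/(ExI+IEx)."""
    denom = j.ExI + j.IEx
    if denom == 0:
        raise ZeroDivisionError("spliced ratio undefined: no unspliced junction reads")
    return 2.0 * j.ExEx / denom


def assign_biotypes(reads: pd.DataFrame, genes: list[Gene],
                    hierarchy: tuple[str, ...] = ("mRNA", "snoRNA", "CUT", "SUT"),
                    ) -> pd.Series:
    """Assign each read to the first class in ``hierarchy`` whose
    strand-matched annotation it overlaps; unmatched reads are intergenic.

    The hierarchy starts with the most abundant biotypes so that a read
    overlapping several annotations is counted once.  Returns per-class read
    counts (always a partition of the table).
    """
    trees: dict[tuple[str, str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.chrom, g.strand, g.biotype),
                         IntervalTree()).addi(g.start, g.end)
    classes = list(hierarchy) + ["intergenic"]
    counts = {c: 0 for c in classes}
    for chrom, start, end, strand in zip(reads["chrom"], reads["start"],
                                         reads["end"], reads["strand"]):
        for c in hierarchy:
            tree = trees.get((chrom, strand, c))
            if tree is not None and tree.overlap(start, end):
                counts[c] += 1
                break
        else:
            counts["intergenic"] += 1
    return pd.Series(counts, name="reads")


def density_drop(total: CoverageTrack, genes: list[Gene],
                 window5: tuple[int, int] = (50, 150),
                 window3: tuple[int, int] = (450, 500),
                 min_length: int = 800) -> float:
    """Fractional coverage reduction between the +50..150 and +450..500
    windows downstream of the TSS, averaged over genes longer than 800 nt."""
    ratios = []
    for g in genes:
        if g.length <= min_length:
            continue
        arr = total.data[(g.chrom, g.strand)]
        if g.strand == "+":
            w5 = arr[g.start + window5[0]: g.start + window5[1]]
            w3 = arr[g.start + window3[0]: g.start + window3[1]]
        else:
            w5 = arr[g.end - window5[1]: g.end - window5[0]]
            w3 = arr[g.end - window3[1]: g.end - window3[0]]
        m5 = float(np.mean(w5))
        if m5 == 0:
            raise ZeroDivisionError(f"gene {g.name}: zero 5' density")
        ratios.append(float(np.mean(w3)) / m5)
    if not ratios:
        raise ValueError(f"no genes longer than {min_length} nt")
    return 1.0 - float(np.mean(ratios))
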