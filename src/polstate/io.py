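"""File I/O for the standard formats.

bedGraph (per-strand file pairs with `.plus.bedgraph` / `.minus.bedgraph`
suffixes, since bedGraph itself has no strand column), BED6, GFF3 annotation
(via gffutils; 1-based closed coordinates converted to the internal 0-based
half-open convention at this boundary), chrom.sizes, the TSV read table, and
JSON model files.  Writers prepend a comment header with the tool version,
config hash and seed; readers skip `#` lines.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel
from .signal import READ_COLUMNS
from .tracks import CoverageTrack

STRAND_SUFFIX = {"+": "plus", "-": "minus"}


def _header(seed=None, config_hash=None) -> str:
    from . import __version__
    parts = [f"polstate v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts) + "\n"


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config snapshot."""
    s = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            out[chrom] = int(size)
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

class BedGraphError(ValueError):
    pass


def write_bedgraph(track: CoverageTrack, prefix, seed=None, cfg_hash=None) -> list[Path]:
    """Write one bedGraph per strand (`<prefix>.plus.bedgraph` etc.).

    Runs of equal value are merged; zero runs are omitted (imputed as 0 on
    read).  Values that are whole numbers are written as integers.
    """
    prefix = Path(prefix)
    written = []
    for strand, suffix in STRAND_SUFFIX.items():
        path = prefix.parent / f"{prefix.name}.{suffix}.bedgraph"
        with open(path, "w") as fh:
            fh.write(_header(seed=seed, config_hash=cfg_hash))
            for chrom, size in track.chrom_sizes.items():
                arr = track.data.get((chrom, strand))
                if arr is None:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [arr.size]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v == 0:
                        continue
                    sval = f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{sval}\n")
        written.append(path)
    return written


def read_bedgraph(path, chrom_sizes: dict[str, int], strand: str,
                  track: CoverageTrack | None = None,
                  units: str = "counts") -> CoverageTrack:
    """Read one strand's bedGraph into (or onto) a CoverageTrack.

    Intervals must be sorted and non-overlapping per chromosome; an
    overlapping line raises :class:`BedGraphError` with its line number.
    Uncovered positions are 0.
    """
    if track is None:
        track = CoverageTrack.zeros(chrom_sizes, units=units)
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise BedGraphError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < last_end.get(chrom, 0):
                raise BedGraphError(f"{path}:{lineno}: overlapping interval "
                                    f"[{start},{end}) on {chrom}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise BedGraphError(f"{path}:{lineno}: interval outside chromosome")
            last_end[chrom] = end
            track.get(chrom, strand)[start:end] = value
    return track


def read_bedgraph_pair(prefix, chrom_sizes: dict[str, int],
                       units: str = "counts") -> CoverageTrack:
    prefix = Path(prefix)
    track = CoverageTrack.zeros(chrom_sizes, units=units)
    for strand, suffix in STRAND_SUFFIX.items():
        read_bedgraph(prefix.parent / f"{prefix.name}.{suffix}.bedgraph",
                      chrom_sizes, strand, track=track)
    return track


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config_hash=cfg_hash))
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """BED with >= 3 columns; strand defaults to '+' when absent."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "+"
    return df[["chrom", "start", "end", "name", "score", "strand"]]


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def write_gff3(genome: GenomeModel, path, seed=None, cfg_hash=None) -> None:
    """Transcripts (with `biotype=` attribute) and exon children, 1-based
    closed coordinates per the GFF3 convention."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header(seed=seed, config_hash=cfg_hash))
        for chrom, size in genome.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in genome.genes:
            attrs = f"ID={g.name};biotype={g.biotype}"
            fh.write(f"{g.chrom}\tpolstate\ttranscript\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\t{attrs}\n")
            exons = g.exons if g.exons else ((g.start, g.end),)
            for i, (s, e) in enumerate(sorted(exons), start=1):
                fh.write(f"{g.chrom}\tpolstate\texon\t{s + 1}\t{e}\t.\t{g.strand}"
                         f"\t.\tID={g.name}.exon{i};Parent={g.name}\n")


def read_annotation(path) -> list[Gene]:
    """Read a GFF3/GTF annotation into Gene records (0-based half-open).

    Transcript class comes from the `biotype` attribute (falling back to the
    feature type); a missing class tag yields class "unknown" with a warning.
    Introns are derived from exon children.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for f in db.features_of_type("transcript"):
        name = f.attributes.get("ID", [f.id])[0]
        bio = f.attributes.get("biotype", [None])[0]
        if bio is None:
            warnings.warn(f"transcript {name}: missing biotype attribute, "
                          "read with class 'unknown'")
            bio = "unknown"
        exons = tuple(sorted((c.start - 1, c.end)
                             for c in db.children(f, featuretype="exon")))
        genes.append(Gene(name=name, chrom=f.seqid, start=f.start - 1,
                          end=f.end, strand=f.strand, biotype=bio,
                          exons=exons if len(exons) > 1 else ()))
    return genes


# ---------------------------------------------------------------------------
# Read table
# ---------------------------------------------------------------------------

def write_read_table(reads: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config_hash=cfg_hash))
        reads.to_csv(fh, sep="\t", index=False)


def read_read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return df
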