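"""Strand-specific coverage tracks, binned enrichment matrices and state paths.

All three containers are keyed by ``(chromosome, strand)``; iteration order is
insertion order, which downstream code treats as the canonical sequence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed order of the five CTD phospho marks in every 5-vector.
MARKS = ("Tyr1", "Ser2", "Thr4", "Ser5", "Ser7")

DEFAULT_BIN_WIDTH = 20
DEFAULT_PSEUDOCOUNT = 5.0

Key = tuple[str, str]


def _check_key(key: Key) -> None:
    chrom, strand = key
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r} for chromosome {chrom}")


@dataclass
class CoverageTrack:
    """Per-base values per (chromosome, strand).

    ``units`` is either ``"counts"`` or ``"rpm"``.  ``library_size`` is the
    read total used for RPM conversion; by convention the synthetic generator
    uses a fixed nominal library of 1e6 reads so counts and RPM coincide
    numerically.
    """

    chrom_sizes: dict[str, int]
    data: dict[Key, np.ndarray] = field(default_factory=dict)
    units: str = "counts"
    library_size: float | None = None

    def __post_init__(self) -> None:
        if self.units not in ("counts", "rpm"):
            raise ValueError(f"bad units {self.units!r}")
        for key, arr in list(self.data.items()):
            _check_key(key)
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.chrom_sizes[key[0]],):
                raise ValueError(f"track {key}: length {arr.shape} != chromosome size")
            self.data[key] = arr

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], units: str = "counts",
              library_size: float | None = None) -> "CoverageTrack":
        data = {}
        for chrom, size in chrom_sizes.items():
            for strand in ("+", "-"):
                data[(chrom, strand)] = np.zeros(size)
        return cls(chrom_sizes=dict(chrom_sizes), data=data, units=units,
                   library_size=library_size)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.chrom_sizes[chrom])
        return self.data[key]

    def keys(self) -> list[Key]:
        return list(self.data.keys())

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def to_rpm(self, library_size: float | None = None) -> "CoverageTrack":
        """Scale counts to reads-per-million; RPM tracks pass through."""
        if self.units == "rpm":
            return self
        lib = library_size if library_size is not None else self.library_size
        if lib is None or lib <= 0:
            raise ValueError("RPM conversion needs a positive library size")
        scale = 1e6 / lib
        return CoverageTrack(
            chrom_sizes=dict(self.chrom_sizes),
            data={k: v * scale for k, v in self.data.items()},
            units="rpm",
            library_size=lib,
        )

    def map_values(self, fn) -> "CoverageTrack":
        return CoverageTrack(
            chrom_sizes=dict(self.chrom_sizes),
            data={k: fn(v) for k, v in self.data.items()},
            units=self.units,
            library_size=self.library_size,
        )


@dataclass
class EnrichmentMatrix:
    """Binned 5-mark log2-enrichment observations for the HMM.

    ``data[(chrom, strand)]`` is an (n_bins, 5) float array; bin *i* covers
    genomic interval [bin_width*i, bin_width*(i+1)) and the trailing partial
    bin of each chromosome is dropped.  Columns follow :data:`MARKS`.
    """

    data: dict[Key, np.ndarray] = field(default_factory=dict)
    bin_width: int = DEFAULT_BIN_WIDTH
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    marks: tuple[str, ...] = MARKS

    def __post_init__(self) -> None:
        for key, arr in list(self.data.items()):
            _check_key(key)
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.marks):
                raise ValueError(f"matrix {key}: expected (n_bins, {len(self.marks)})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"matrix {key}: non-finite values")
            self.data[key] = arr

    def keys(self) -> list[Key]:
        return list(self.data.keys())

    def sequences(self) -> list[np.ndarray]:
        return [self.data[k] for k in self.keys()]

    @property
    def n_bins(self) -> int:
        return int(sum(v.shape[0] for v in self.data.values()))

    def stacked(self) -> np.ndarray:
        """All bins from all sequences as one (n_bins, 5) array."""
        return np.concatenate(self.sequences(), axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand), arr in self.data.items():
            df = pd.DataFrame(arr, columns=list(self.marks))
            df.insert(0, "bin_start", np.arange(arr.shape[0]) * self.bin_width)
            df.insert(0, "strand", strand)
            df.insert(0, "chrom", chrom)
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["chrom", "strand", "bin_start", *self.marks])
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_width: int = DEFAULT_BIN_WIDTH,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "EnrichmentMatrix":
        data = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
            grp = grp.sort_values("bin_start")
            data[(chrom, strand)] = grp[list(MARKS)].to_numpy(dtype=float)
        return cls(data=data, bin_width=bin_width, pseudocount=pseudocount)

    @classmethod
    def from_tsv(cls, path, **kw) -> "EnrichmentMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"), **kw)


@dataclass
class StatePath:
    """Decoded (or ground-truth) state per bin per (chromosome, strand).

    States are 0-based integers in [0, K); export to labels goes through a
    :class:`dict` labeling (state index -> label string).
    """

    data: dict[Key, np.ndarray] = field(default_factory=dict)
    n_states: int = 0
    bin_width: int = DEFAULT_BIN_WIDTH
    posterior: dict[Key, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for key, arr in list(self.data.items()):
            _check_key(key)
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"path {key}: expected 1-D state sequence")
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_states):
                raise ValueError(f"path {key}: states outside [0, {self.n_states})")
            self.data[key] = arr

    def keys(self) -> list[Key]:
        return list(self.data.keys())

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.data[k] for k in self.keys()])

    def state_frequencies(self) -> np.ndarray:
        """Genome-wide frequency of each state (length K, sums to 1)."""
        counts = np.bincount(self.stacked(), minlength=self.n_states).astype(float)
        return counts / counts.sum()

    def relabeled(self, perm: np.ndarray) -> "StatePath":
        """Apply a state permutation: new_state = perm[old_state]."""
        perm = np.asarray(perm, dtype=np.int64)
        return StatePath(
            data={k: perm[v] for k, v in self.data.items()},
            n_states=self.n_states, bin_width=self.bin_width,
        )
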