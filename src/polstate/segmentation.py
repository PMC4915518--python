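"""Downstream analyses of the decoded state paths.

Converts state paths into BED-style segmentations and reproduces the study's
analyses: state enrichment over window sets, metagene state-frequency and
signal profiles (TSS/pA/splice-site/nucleosome anchored, fixed flank or
ten-bin gene-relative), nucleosome-boundary alignment of state edges,
exon-1 splits, class comparisons with rank-sum tests, expression matching,
I1-exit / EE-entry transition-position curves, and coverage periodicity.

All metagene computations flip minus-strand genes into transcript
orientation before averaging; anchors are single-nt points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .genome import Gene, GenomeModel
from .tracks import CoverageTrack, EnrichmentMatrix, MARKS, StatePath

# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def path_to_segments(path: StatePath, labeling: dict[int, str] | None = None
                     ) -> pd.DataFrame:
    """Run-length encode a labeled state path into BED6 intervals.

    Adjacent intervals on a strand always carry different states and the
    union tiles the binned territory.
    """
    lab = labeling or {}
    bw = path.bin_width
    rows = []
    for (chrom, strand), z in path.data.items():
        if z.size == 0:
            continue
        change = np.flatnonzero(np.diff(z)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [z.size]])
        for s, e in zip(starts, ends):
            state = int(z[s])
            rows.append((chrom, int(s) * bw, int(e) * bw,
                         lab.get(state, str(state)), 0, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def segments_to_path(segments: pd.DataFrame, labeling: dict[int, str],
                     chrom_sizes: dict[str, int], bin_width: int = 20,
                     ) -> StatePath:
    """Inverse of :func:`path_to_segments` (exact round trip)."""
    inv = {v: k for k, v in labeling.items()}
    data = {}
    for (chrom, strand), grp in segments.groupby(["chrom", "strand"], sort=False):
        n = chrom_sizes[chrom] // bin_width
        z = np.zeros(n, dtype=np.int64)
        for _, row in grp.iterrows():
            z[row["start"] // bin_width: row["end"] // bin_width] = inv[row["name"]]
        data[(chrom, strand)] = z
    return StatePath(data=data, n_states=max(labeling) + 1, bin_width=bin_width)


# ---------------------------------------------------------------------------
# State enrichment
# ---------------------------------------------------------------------------

def state_enrichment(path: StatePath, windows: pd.DataFrame,
                     labeling: dict[int, str] | None = None) -> pd.DataFrame:
    """Observed versus expected state counts over a window set.

    Expected counts assume the genome-wide state frequencies apply uniformly:
    n_exp_i = freq_i * (total window bins); the ratio n_obs/n_exp is the
    fold enrichment.  Windows are BED-like (chrom, start, end, strand).
    """
    K = path.n_states
    freqs = path.state_frequencies()
    obs = np.zeros(K)
    total = 0
    bw = path.bin_width
    for _, w in windows.iterrows():
        z = path.data[(w["chrom"], w["strand"])]
        b0 = int(w["start"]) // bw
        b1 = int(np.ceil(w["end"] / bw))
        seg = z[b0:b1]
        obs += np.bincount(seg, minlength=K)
        total += seg.size
    exp = freqs * total
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(exp > 0, obs / exp, np.nan)
    lab = labeling or {}
    return pd.DataFrame({
        "state": [lab.get(k, str(k)) for k in range(K)],
        "n_obs": obs, "n_exp": exp, "ratio": ratio,
        "absent": freqs == 0,
    })


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Per-offset values per state (frequencies) or per mark (signal)."""

    positions: np.ndarray          # bin or nt offsets relative to the anchor
    values: pd.DataFrame           # index aligned to positions
    counts: np.ndarray             # anchors contributing per offset
    kind: str                      # "states" | "signal"
    anchor: str = "tss"
    normalization: str = "none"
    fold: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "position", self.positions)
        df["n_anchors"] = self.counts
        return df


def _gene_anchor(gene: Gene, anchor: str) -> int | None:
    if anchor == "tss":
        return gene.tss
    if anchor == "pa":
        return gene.pa
    if anchor == "5ss":
        return gene.five_prime_ss
    if anchor == "3ss":
        if not gene.has_intron:
            return None
        introns = gene.introns
        return introns[0][1] if gene.strand == "+" else introns[-1][0] - 1
    raise ValueError(f"unknown anchor {anchor!r}")


def anchors_from_genes(genes: list[Gene], anchor: str = "tss") -> pd.DataFrame:
    """Single-nt anchor points (BED-like) from gene annotation."""
    rows = []
    for g in genes:
        p = _gene_anchor(g, anchor)
        if p is not None:
            rows.append((g.chrom, p, p + 1, g.name, 0, g.strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def metagene_states(path: StatePath, genes: list[Gene],
                    anchor: str = "tss", flank: int = 1000,
                    ten_bins: bool = False,
                    labeling: dict[int, str] | None = None) -> MetageneProfile:
    """Frequency of each state per position across genes.

    With ``ten_bins`` each gene's bins are assigned to ten equal-width
    fractions of the transcript, aligning genes of different lengths.
    Frequencies sum to 1 across states at every offset; the ``fold`` table
    divides them by the genome-wide state frequency.
    """
    if not genes:
        raise ValueError("no anchor genes supplied")
    K = path.n_states
    bw = path.bin_width
    if ten_bins:
        counts = np.zeros((10, K))
        for g in genes:
            z = path.data[(g.chrom, g.strand)]
            b0, b1 = g.start // bw, g.end // bw
            zg = z[b0:b1]
            if g.strand == "-":
                zg = zg[::-1]
            if zg.size == 0:
                continue
            frac = np.minimum((np.arange(zg.size) * 10) // zg.size, 9)
            for f, s in zip(frac, zg):
                counts[f, s] += 1
        positions = np.arange(10)
    else:
        n_off = 2 * (flank // bw) + 1
        counts = np.zeros((n_off, K))
        half = flank // bw
        for g in genes:
            z = path.data[(g.chrom, g.strand)]
            a = _gene_anchor(g, anchor)
            if a is None:
                continue
            ab = a // bw
            for i, off in enumerate(range(-half, half + 1)):
                b = ab + (off if g.strand == "+" else -off)
                if 0 <= b < z.size:
                    counts[i, z[b]] += 1
        positions = np.arange(-half, half + 1) * bw
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    lab = labeling or {}
    cols = [lab.get(k, str(k)) for k in range(K)]
    values = pd.DataFrame(freq, columns=cols)
    gw = path.state_frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = pd.DataFrame(np.where(gw > 0, freq / gw, np.nan), columns=cols)
    return MetageneProfile(positions=positions, values=values,
                           counts=totals.ravel(), kind="states",
                           anchor="ten_bins" if ten_bins else anchor,
                           fold=fold)


def metagene_signal(source, anchors: pd.DataFrame, flank: int = 500,
                    norm: str = "none", mrna_gt500: list[Gene] | None = None,
                    mark: str | None = None) -> MetageneProfile:
    """Mean signal per offset across anchor points, strand-flipped for minus.

    ``source`` is a per-base CoverageTrack, or an EnrichmentMatrix with
    ``mark`` naming the column to profile (offsets then step by bin width).
    ``norm="max_mrna_gt500"`` scales the track by its maximum value inside
    protein-coding genes longer than 500 nt before profiling;
    ``norm="per_gene_max"`` rescales each anchor window by its own maximum.
    Flanks running off a chromosome are truncated with count weighting.
    """
    if anchors.empty:
        raise ValueError("no anchors supplied")
    if isinstance(source, EnrichmentMatrix):
        if mark is None:
            raise ValueError("mark required when profiling an EnrichmentMatrix")
        mi = list(source.marks).index(mark)
        step = source.bin_width
        arrays = {k: v[:, mi] for k, v in source.data.items()}
    else:
        step = 1
        arrays = dict(source.data)

    scale = 1.0
    if norm == "max_mrna_gt500":
        if not mrna_gt500:
            raise ValueError("max_mrna_gt500 normalization needs the mRNA gene set")
        best = 0.0
        for g in mrna_gt500:
            if g.length <= 500 or g.biotype != "mRNA":
                continue
            arr = arrays[(g.chrom, g.strand)]
            lo, hi = g.start // step, g.end // step
            if hi > lo:
                best = max(best, float(arr[lo:hi].max()))
        if best <= 0:
            raise ValueError("no positive signal in mRNA>500 set")
        scale = best

    half = flank // step
    sums = np.zeros(2 * half + 1)
    counts = np.zeros(2 * half + 1)
    for _, a in anchors.iterrows():
        arr = arrays[(a["chrom"], a["strand"])]
        c = int(a["start"]) // step
        idx = c + (np.arange(-half, half + 1) if a["strand"] == "+"
                   else -np.arange(-half, half + 1))
        ok = (idx >= 0) & (idx < arr.size)
        vals = arr[idx[ok]] / scale
        if norm == "per_gene_max":
            m = np.abs(vals).max()
            if m > 0:
                vals = vals / m
        sums[ok] += vals
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    name = mark if mark is not None else "signal"
    return MetageneProfile(positions=np.arange(-half, half + 1) * step,
                           values=pd.DataFrame({name: mean}), counts=counts,
                           kind="signal", anchor="points", normalization=norm)


# ---------------------------------------------------------------------------
# Nucleosome-boundary alignment
# ---------------------------------------------------------------------------

@dataclass
class BoundaryAlignment:
    offsets: np.ndarray
    mode: int | None
    n_genes: int
    n_skipped: int

    def histogram(self) -> pd.Series:
        if self.offsets.size == 0:
            return pd.Series(dtype=int)
        vals, cnts = np.unique(self.offsets, return_counts=True)
        return pd.Series(cnts, index=vals)


def boundary_alignment(segments: pd.DataFrame, genes: list[Gene],
                       genome: GenomeModel, state: str = "I1",
                       state_edge: str = "3p", nucleosome_index: int = 1,
                       nucleosome_edge: str = "3p",
                       nucleosomes: dict | None = None) -> BoundaryAlignment:
    """Signed nt offsets between a state edge and a nucleosome boundary.

    For each gene, takes the first run of ``state`` from the TSS and the
    ``nucleosome_index``-th nucleosome of the gene's array; the offset is
    (state edge - nucleosome boundary) in transcript orientation (positive =
    downstream).  Genes lacking the state are skipped and counted.
    """
    offsets = []
    skipped = 0
    for g in genes:
        nucs = (nucleosomes[g.name] if nucleosomes is not None
                else genome.nucleosomes_for_gene(g))
        if g.strand == "-":
            nucs = nucs[::-1]  # transcript order
        if len(nucs) < nucleosome_index:
            skipped += 1
            continue
        ns, ne = nucs[nucleosome_index - 1]
        if g.strand == "+":
            nuc_pos = ne if nucleosome_edge == "3p" else ns
        else:
            nuc_pos = ns if nucleosome_edge == "3p" else ne
        sel = segments[(segments["chrom"] == g.chrom) &
                       (segments["strand"] == g.strand) &
                       (segments["name"] == state) &
                       (segments["end"] > g.start) &
                       (segments["start"] < g.end)]
        if sel.empty:
            skipped += 1
            continue
        # first run from the TSS in transcript orientation
        if g.strand == "+":
            run = sel.loc[sel["start"].idxmin()]
            pos = run["end"] if state_edge == "3p" else run["start"]
            offsets.append(int(pos) - nuc_pos)
        else:
            run = sel.loc[sel["end"].idxmax()]
            pos = run["start"] if state_edge == "3p" else run["end"]
            offsets.append(nuc_pos + 1 - int(pos))
    offs = np.array(offsets, dtype=int)
    mode = None
    if offs.size:
        vals, cnts = np.unique(offs, return_counts=True)
        mode = int(vals[np.argmax(cnts)])
    return BoundaryAlignment(offsets=offs, mode=mode, n_genes=len(genes),
                             n_skipped=skipped)


# ---------------------------------------------------------------------------
# Gene-set splits and class comparisons
# ---------------------------------------------------------------------------

def split_by_exon1(genes: list[Gene]) -> dict[str, list[Gene]]:
    """Intronless top-expression-quartile vs short (<100 nt) vs long
    (>=100 nt) exon-1 intron-containing genes; ties at exactly 100 nt go to
    the long group."""
    mrnas = [g for g in genes if g.biotype == "mRNA"]
    intronless = [g for g in mrnas if not g.has_intron]
    intronless.sort(key=lambda g: (-(g.expression or 0.0), g.name))
    top_q = intronless[: max(1, int(np.ceil(len(intronless) / 4)))] if intronless else []
    short = [g for g in mrnas if g.has_intron and g.exon1_length < 100]
    long_ = [g for g in mrnas if g.has_intron and g.exon1_length >= 100]
    return {"intronless_topQ": top_q, "exon1_lt100": short, "exon1_ge100": long_}


def gene_mean_enrichment(X: EnrichmentMatrix, gene: Gene,
                         first_500_only: bool = False) -> np.ndarray | None:
    """Mean 5-mark enrichment over a gene's bins (optionally first 500 nt)."""
    bw = X.bin_width
    arr = X.data.get((gene.chrom, gene.strand))
    if arr is None:
        return None
    b0, b1 = gene.start // bw, min(gene.end // bw, arr.shape[0])
    if b1 <= b0:
        return None
    vals = arr[b0:b1]
    if gene.strand == "-":
        vals = vals[::-1]
    if first_500_only:
        vals = vals[: 500 // bw]
    return vals.mean(axis=0)


def class_compare(X: EnrichmentMatrix, genes: list[Gene],
                  classes: tuple[str, ...] = ("mRNA", "CUT", "SUT"),
                  first_500_only: bool = False,
                  alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene mean enrichment by class, compared pairwise per mark.

    Uses the two-sided tie-corrected normal-approximation rank-sum test per
    mark per class pair, Bonferroni-corrected over all mark x pair tests run
    in this invocation; significance at corrected P < ``alpha``.  When
    ``first_500_only`` is set, only genes longer than 500 nt contribute and
    means are taken over their first 500 nt.
    """
    per_class: dict[str, np.ndarray] = {}
    for c in classes:
        rows = []
        for g in genes:
            if g.biotype != c:
                continue
            if first_500_only and g.length <= 500:
                continue
            v = gene_mean_enrichment(X, g, first_500_only)
            if v is not None:
                rows.append(v)
        per_class[c] = np.array(rows)
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    recs = []
    for a, b in pairs:
        xa, xb = per_class[a], per_class[b]
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"class pair ({a},{b}) skipped: fewer than 2 genes")
            continue
        for mi, mark in enumerate(MARKS):
            stat, p = mannwhitneyu(xa[:, mi], xb[:, mi],
                                   alternative="two-sided", method="asymptotic")
            recs.append({"mark": mark, "class_a": a, "class_b": b,
                         "n_a": len(xa), "n_b": len(xb),
                         "median_a": float(np.median(xa[:, mi])),
                         "median_b": float(np.median(xb[:, mi])),
                         "statistic": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(recs)
    if not df.empty:
        rej, p_corr, _, _ = multipletests(df["p_raw"], alpha=alpha,
                                          method="bonferroni")
        df["p_bonferroni"] = p_corr
        df["significant"] = rej
    return df


def match_expression(genes: list[Gene], reference_class: str,
                     other_classes: tuple[str, ...],
                     quartile: float = 0.25) -> dict[str, list[Gene]]:
    """Expression-matched gene sets.

    Takes the top expression quartile of the reference class, then greedily
    matches each reference gene (descending expression) to its nearest
    unused candidate by log-expression in every other class.
    """
    by_class: dict[str, list[Gene]] = {}
    for g in genes:
        by_class.setdefault(g.biotype, []).append(g)
    ref = sorted(by_class.get(reference_class, []),
                 key=lambda g: (-(g.expression or 0.0), g.name))
    n_ref = max(1, int(np.ceil(len(ref) * quartile)))
    ref_top = ref[:n_ref]
    out = {reference_class: ref_top}
    for c in other_classes:
        pool = by_class.get(c, [])
        if len(pool) < n_ref:
            raise ValueError(f"class {c}: only {len(pool)} candidates for "
                             f"{n_ref} reference genes")
        avail = {g.name: g for g in pool}
        chosen = []
        for rg in ref_top:
            target = np.log(max(rg.expression, 1e-12))
            best = min(avail.values(),
                       key=lambda g: (abs(np.log(max(g.expression, 1e-12)) - target),
                                      g.name))
            chosen.append(best)
            del avail[best.name]
        out[c] = chosen
    return out


# ---------------------------------------------------------------------------
# Transition positions
# ---------------------------------------------------------------------------

@dataclass
class TransitionPositions:
    table: pd.DataFrame
    median_i1_exit: float | None
    median_ee_entry: float | None
    censored_i1: float
    censored_ee: float
    no_i1: int = 0

    def cumulative(self, column: str) -> pd.DataFrame:
        vals = np.sort(self.table[column].dropna().to_numpy())
        return pd.DataFrame({"position": vals,
                             "fraction": np.arange(1, vals.size + 1) / max(vals.size, 1)})


def state_transition_positions(path: StatePath, genes: list[Gene],
                               labeling: dict[int, str]) -> TransitionPositions:
    """Per-gene I1-exit and EE-entry positions (nt from the TSS).

    I1-exit is the start of the first bin after the TSS-proximal I1 run;
    EE-entry is the first EE bin.  Genes whose I1 run reaches the 3' end
    (or that never show EE) are censored; genes with no I1 at the TSS are
    recorded separately and excluded.  Medians use uncensored genes only.
    """
    inv = {v: k for k, v in labeling.items()}
    i1 = inv.get("I1")
    ee = inv.get("EE")
    bw = path.bin_width
    rows = []
    no_i1 = 0
    for g in genes:
        z = path.data[(g.chrom, g.strand)]
        b0, b1 = g.start // bw, g.end // bw
        zg = z[b0:b1]
        if g.strand == "-":
            zg = zg[::-1]
        if zg.size == 0:
            continue
        if i1 is None or zg[0] != i1:
            no_i1 += 1
            continue
        run = int(np.argmax(zg != i1)) if np.any(zg != i1) else zg.size
        i1_exit = run * bw if run < zg.size else np.nan
        if ee is not None and np.any(zg == ee):
            ee_entry = int(np.argmax(zg == ee)) * bw
        else:
            ee_entry = np.nan
        rows.append({"gene": g.name, "biotype": g.biotype, "length": g.length,
                     "i1_exit": i1_exit, "ee_entry": ee_entry})
    df = pd.DataFrame(rows, columns=["gene", "biotype", "length",
                                     "i1_exit", "ee_entry"])
    n = len(df)
    med_exit = float(df["i1_exit"].median()) if df["i1_exit"].notna().any() else None
    med_entry = float(df["ee_entry"].median()) if df["ee_entry"].notna().any() else None
    return TransitionPositions(
        table=df,
        median_i1_exit=med_exit,
        median_ee_entry=med_entry,
        censored_i1=float(df["i1_exit"].isna().mean()) if n else 0.0,
        censored_ee=float(df["ee_entry"].isna().mean()) if n else 0.0,
        no_i1=no_i1,
    )


# ---------------------------------------------------------------------------
# Periodicity
# ---------------------------------------------------------------------------

@dataclass
class PeriodicityResult:
    period: int | None
    autocorrelation: np.ndarray
    peak_value: float | None
    reliable: bool


def periodicity_of_profile(profile: np.ndarray, min_lag: int = 40,
                           reliability_threshold: float = 0.1) -> PeriodicityResult:
    """Dominant period of a 1-D profile via autocorrelation.

    Returns the lag of the first local autocorrelation maximum beyond
    ``min_lag``; flat profiles yield no period, and weak peaks (normalized
    autocorrelation below ``reliability_threshold``) are flagged unreliable.
    """
    x = np.asarray(profile, dtype=float)
    x = x[np.isfinite(x)]
    x = x - x.mean()
    if x.size < min_lag + 2 or float(np.dot(x, x)) <= 0:
        return PeriodicityResult(None, np.zeros(0), None, False)
    # per-lag Pearson autocorrelation (both overlap segments re-centered):
    # unlike the raw windowed estimate this is free of finite-window edge
    # bias, and an exactly periodic profile correlates to 1 at its period
    n = x.size
    max_lag = n - max(min_lag, 20)
    acf = np.zeros(max_lag)
    acf[0] = 1.0
    for lag in range(1, max_lag):
        a, b = x[: n - lag], x[lag:]
        da, db = a - a.mean(), b - b.mean()
        va, vb = float(da @ da), float(db @ db)
        acf[lag] = (da @ db) / np.sqrt(va * vb) if va > 0 and vb > 0 else 0.0
    peaks, _ = find_peaks(acf[min_lag + 1:])
    if peaks.size == 0:
        return PeriodicityResult(None, acf, None, False)
    lag = int(peaks[0] + min_lag + 1)
    val = float(acf[lag])
    return PeriodicityResult(period=lag, autocorrelation=acf, peak_value=val,
                             reliable=val >= reliability_threshold)


def periodicity(track: CoverageTrack, boundaries: pd.DataFrame,
                flank: int = 450, min_lag: int = 40) -> PeriodicityResult:
    """Dominant spatial period of the nucleosome-boundary-anchored metagene
    of a coverage track."""
    prof = metagene_signal(track, boundaries, flank=flank)
    return periodicity_of_profile(prof.values.iloc[:, 0].to_numpy(),
                                  min_lag=min_lag)


def nucleosome_boundaries_bed(genome: GenomeModel, edge: str = "5p") -> pd.DataFrame:
    """Single-nt nucleosome 5' (or 3') boundary anchors for all genes."""
    rows = []
    for chrom, s, e, strand in genome.nucleosome_intervals():
        if edge == "5p":
            p = s if strand == "+" else e - 1
        else:
            p = e - 1 if strand == "+" else s
        rows.append((chrom, p, p + 1, "nuc", 0, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)
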