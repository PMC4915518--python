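"""Synthetic mCRAC data generator.

Produces a small yeast-like genome (mRNAs, CUTs, SUTs, snoRNAs separated by
intergenic gaps), a ground-truth RNAPII phosphorylation-state layout per 20-nt
bin, strand-specific total-polymerase and five phospho-mark count tracks, and
an aligned-read table with barcodes, PCR duplicates and junction-class tags.

The generator encodes the statistical structure the downstream analyses
assume:

* an 8-state reference emission model (I1, I2, EE, E1, E2, E3, L, N) over the
  five CTD marks (Tyr1, Ser2, Thr4, Ser5, Ser7), with qualitative orderings of
  the learned emission matrix: initiation states carry the highest Ser5
  enrichment (intermediate I1, high I2) with low Ser2/Thr4; early elongation
  (EE) has high Tyr1/Ser2/Ser7 but negative Ser5; E1 carries the highest Thr4;
  L is low in everything; N (untranscribed) is centred at zero with the
  broadest covariance;
* total-polymerase coverage with a 5' boost decaying over the first 500 nt, a
  150-nt nucleosome-periodic modulation, and a ~50% dip over the final 100 nt
  before the poly(A) site;
* per-class state layouts: mRNAs progress I1 -> EE -> E1/E2/E3 -> L (introns
  extend I1 to the 5' splice site), CUTs never leave I1, SUTs reach EE but no
  further, snoRNAs sit in I2, intergenic territory is N.

Everything is deterministic given the config seed.  Coordinates are 0-based
half-open and gene boundaries sit on the 20-nt bin grid so that every bin has
exactly one truth state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel
from .tracks import MARKS, CoverageTrack, EnrichmentMatrix, StatePath

STATE_LABELS = ("I1", "I2", "EE", "E1", "E2", "E3", "L", "N")


class PlacementError(ValueError):
    """Raised when a chromosome is too small for the requested gene set."""


# ---------------------------------------------------------------------------
# Reference emission model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionReference:
    """Per-state 5-mark emission means and covariances (the ground truth)."""

    labels: tuple[str, ...]
    means: np.ndarray        # (K, 5)
    covariances: np.ndarray  # (K, 5, 5)

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        if means.shape != (len(self.labels), len(MARKS)):
            raise ValueError("means must be (K, 5)")
        if covs.shape != (len(self.labels), len(MARKS), len(MARKS)):
            raise ValueError("covariances must be (K, 5, 5)")
        for i, c in enumerate(covs):
            if not np.allclose(c, c.T):
                raise ValueError(f"covariance of state {self.labels[i]} not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"covariance of state {self.labels[i]} not positive-definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def default(cls) -> "EmissionReference":
        means = np.array([
            # Tyr1  Ser2  Thr4  Ser5  Ser7
            [-0.9, -0.7, -0.3,  0.8,  0.0],   # I1: intermediate Ser5, low Ser2/Thr4
            [ 0.2,  0.1, -0.2,  1.0,  1.0],   # I2: high Ser5 and Ser7
            [ 0.8,  0.7, -0.6, -0.4,  0.6],   # EE: Tyr1/Ser2/Ser7 up, Ser5/Thr4 down
            [ 0.3,  0.9,  1.0, -0.6, -0.4],   # E1: highest Thr4
            [-0.7,  0.6,  0.2, -0.9,  0.4],   # E2
            [ 0.7, -0.4,  0.5, -1.0, -0.8],   # E3
            [-0.6, -0.5, -0.9, -0.8, -0.8],   # L: low everything, esp. Ser5/Thr4
            [ 0.0,  0.0,  0.0,  0.0,  0.0],   # N: untranscribed noise
        ])
        covs = np.array([0.25 * np.eye(5)] * 7 + [0.4 * np.eye(5)])
        return cls(labels=STATE_LABELS, means=means, covariances=covs)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "EmissionReference":
        return cls(labels=tuple(d["labels"]),
                   means=np.asarray(d["means"]),
                   covariances=np.asarray(d["covariances"]))


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateLayoutRule:
    """Deterministic truth-state layout per transcript class, in whole bins.

    mRNA: I1 over the first ``i1_bins`` (extended to the 5' splice site on
    intron-containing genes), EE for ``ee_bins``, the remaining interior split
    evenly into E1/E2/E3, and L over the final ``l_bins``.
    CUT: I1 throughout.  SUT: I1 for ``sut_i1_bins`` then EE.  snoRNA: I2
    throughout.  Spans always tile the transcript exactly.
    """

    i1_bins: int = 8        # 160 nt; ends at the nucleosome-1 3' boundary
    ee_bins: int = 14       # 280 nt
    l_bins: int = 8         # 160 nt terminal low-phosphorylation window
    sut_i1_bins: int = 15   # 300 nt

    def spans(self, gene: Gene, bin_width: int = 20) -> list[tuple[str, int]]:
        n = gene.length // bin_width
        if gene.biotype == "CUT":
            return [("I1", n)]
        if gene.biotype == "snoRNA":
            return [("I2", n)]
        if gene.biotype == "SUT":
            i1 = min(self.sut_i1_bins, n)
            return [(s, w) for s, w in [("I1", i1), ("EE", n - i1)] if w > 0]
        # mRNA
        i1 = self.i1_bins
        if gene.has_intron:
            i1 = max(2, round(gene.exon1_length / bin_width))
        i1 = min(i1, n)
        tail = min(self.l_bins, n - i1)
        mid = n - i1 - tail
        ee = min(self.ee_bins, mid)
        rest = mid - ee
        e1 = (rest + 2) // 3
        e3 = rest // 3
        e2 = rest - e1 - e3
        out = [("I1", i1), ("EE", ee), ("E1", e1), ("E2", e2), ("E3", e3), ("L", tail)]
        return [(s, w) for s, w in out if w > 0]

    def transcript_states(self, gene: Gene, reference: EmissionReference,
                          bin_width: int = 20) -> np.ndarray:
        spans = self.spans(gene, bin_width)
        if sum(w for _, w in spans) != gene.length // bin_width:
            raise ValueError(f"layout does not tile gene {gene.name}")
        return np.concatenate([
            np.full(w, reference.index(s), dtype=np.int64) for s, w in spans
        ]) if spans else np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# Config and truth bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Length medians follow the yeast annotation (mRNA 1,500 nt, CUT 377 nt,
    SUT 745 nt); expression is log-normal around 10 crosslinked reads/nt so
    that per-base total RPM sits a few-fold above the pseudocount of 5, the
    regime the enrichment transform assumes.
    """

    n_mrna: int = 30
    n_cut: int = 12
    n_sut: int = 8
    n_snorna: int = 16
    chrom_name: str = "chrS"
    chrom_length: int | None = None      # None: sized to fit the gene set
    median_length: dict = field(default_factory=lambda: {
        "mRNA": 1500, "CUT": 377, "SUT": 745, "snoRNA": 600})
    length_log_sd: dict = field(default_factory=lambda: {
        "mRNA": 0.35, "CUT": 0.30, "SUT": 0.30, "snoRNA": 0.30})
    intron_fraction: float = 0.25
    exon1_median: int = 100
    exon1_log_sd: float = 0.5
    intron_median: int = 300
    intron_log_sd: float = 0.3
    min_intergenic: int = 500
    max_intergenic: int = 1000
    expression_median: float = 10.0
    expression_log_sd: float = 0.6
    bin_width: int = 20
    nucleosome_repeat: int = 150
    first_nucleosome_offset: int = 10
    boost5_level: float = 2.0
    boost5_plateau: int = 150
    boost5_end: int = 500
    nucleosome_amplitude: float = 0.3
    pa_dip: float = 0.5
    pa_dip_span: int = 100
    antisense_fraction: float = 0.02
    depth: float = 1.0
    library_size: float = 1e6
    pseudocount: float = 5.0
    count_noise: bool = True
    duplication_rate: float = 0.2
    reads_per_nt: float = 0.05           # expected unique reads per nt per unit expression
    read_length: int = 30
    junction_fraction: float = 0.1
    junction_proportions: tuple = (1.0, 1.0, 1.0)   # ExEx : ExI : IEx
    seed: int = 0

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["junction_proportions"] = list(d["junction_proportions"])
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["junction_proportions"] = tuple(d["junction_proportions"])
        return cls(**d)


@dataclass
class TruthBundle:
    """Ground truth for recovery tests: per-bin states, per-bin emission
    vectors, per-gene expression, and the generating config/reference."""

    path: StatePath
    emissions: dict[tuple[str, str], np.ndarray]
    expression: dict[str, float]
    labels: tuple[str, ...]
    reference: EmissionReference
    config: SimulationConfig
    layout: StateLayoutRule

    @property
    def labeling(self) -> dict[int, str]:
        return dict(enumerate(self.labels))

    def enrichment_matrix(self) -> EnrichmentMatrix:
        """The drawn bin emissions as an EnrichmentMatrix (noise-free signal
        chain: what a perfect read-out of the tracks would recover)."""
        return EnrichmentMatrix(
            data={k: v.copy() for k, v in self.emissions.items()},
            bin_width=self.config.bin_width,
            pseudocount=self.config.pseudocount,
        )


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _snap(x: float, w: int, minimum: int) -> int:
    return max(minimum, int(round(x / w)) * w)


def _sample_length(rng, cfg: SimulationConfig, biotype: str) -> int:
    med = cfg.median_length[biotype]
    sd = cfg.length_log_sd[biotype]
    return _snap(med * np.exp(rng.normal(0.0, sd)), cfg.bin_width, 3 * cfg.bin_width)


def simulate_genome(config: SimulationConfig | None = None,
                    seed: int | None = None,
                    reference: EmissionReference | None = None,
                    layout: StateLayoutRule | None = None,
                    ) -> tuple[GenomeModel, TruthBundle]:
    """Draw the annotation, truth-state layout and per-bin emission vectors.

    Deterministic given ``config.seed`` (or the ``seed`` override).  Raises
    :class:`PlacementError` naming the first gene that does not fit when a
    fixed ``chrom_length`` is too small.
    """
    cfg = config if config is not None else SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    ref = reference if reference is not None else EmissionReference.default()
    rule = layout if layout is not None else StateLayoutRule()
    rng = np.random.default_rng([cfg.seed, 101])
    bw = cfg.bin_width

    specs: list[tuple[str, str]] = []
    for biotype, n in [("mRNA", cfg.n_mrna), ("CUT", cfg.n_cut),
                       ("SUT", cfg.n_sut), ("snoRNA", cfg.n_snorna)]:
        if n < 0:
            raise ValueError(f"negative count for {biotype}")
        specs += [(f"{biotype}_{i + 1}", biotype) for i in range(n)]
    order = rng.permutation(len(specs))

    genes: list[Gene] = []
    pos = _snap(rng.integers(cfg.min_intergenic, cfg.max_intergenic + 1), bw, bw)
    for idx in order:
        name, biotype = specs[idx]
        length = _sample_length(rng, cfg, biotype)
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        if cfg.chrom_length is not None and end > cfg.chrom_length:
            raise PlacementError(
                f"chromosome {cfg.chrom_name} ({cfg.chrom_length} nt) too small "
                f"to place gene {name} at [{start}, {end})")
        exons: tuple[tuple[int, int], ...] = ()
        if biotype == "mRNA" and rng.random() < cfg.intron_fraction:
            exon1 = _snap(cfg.exon1_median * np.exp(rng.normal(0, cfg.exon1_log_sd)),
                          bw, 2 * bw)
            intron = _snap(cfg.intron_median * np.exp(rng.normal(0, cfg.intron_log_sd)),
                           bw, 3 * bw)
            if exon1 + intron + 2 * bw <= length:
                if strand == "+":
                    exons = ((start, start + exon1),
                             (start + exon1 + intron, end))
                else:
                    exons = ((start, end - exon1 - intron),
                             (end - exon1, end))
        expr = float(cfg.expression_median * np.exp(rng.normal(0, cfg.expression_log_sd)))
        genes.append(Gene(name=name, chrom=cfg.chrom_name, start=start, end=end,
                          strand=strand, biotype=biotype, exons=exons,
                          expression=expr))
        gap = _snap(rng.integers(cfg.min_intergenic, cfg.max_intergenic + 1), bw, bw)
        pos = end + gap

    chrom_length = cfg.chrom_length if cfg.chrom_length is not None else pos
    chrom_length = (chrom_length // bw) * bw
    genome = GenomeModel(chromosomes=[(cfg.chrom_name, chrom_length)],
                         genes=genes,
                         nucleosome_repeat=cfg.nucleosome_repeat,
                         first_nucleosome_offset=cfg.first_nucleosome_offset,
                         seed=cfg.seed)

    n_idx = ref.index("N")
    n_bins = chrom_length // bw
    state_data = {(cfg.chrom_name, s): np.full(n_bins, n_idx, dtype=np.int64)
                  for s in ("+", "-")}
    for g in genes:
        z = rule.transcript_states(g, ref, bw)
        b0, b1 = g.start // bw, g.end // bw
        if g.strand == "+":
            state_data[(g.chrom, "+")][b0:b1] = z
        else:
            state_data[(g.chrom, "-")][b0:b1] = z[::-1]
    path = StatePath(data=state_data, n_states=ref.n_states, bin_width=bw)

    # one emission 5-vector per bin, fixed across replicate tracks
    erng = np.random.default_rng([cfg.seed, 202])
    chols = np.linalg.cholesky(ref.covariances)
    emissions = {}
    for key, z in state_data.items():
        e = np.empty((z.size, len(MARKS)))
        for k in range(ref.n_states):
            m = z == k
            if m.any():
                e[m] = ref.means[k] + erng.standard_normal((int(m.sum()), len(MARKS))) @ chols[k].T
        emissions[key] = e

    truth = TruthBundle(path=path, emissions=emissions,
                        expression={g.name: g.expression for g in genes},
                        labels=ref.labels, reference=ref, config=cfg, layout=rule)
    return genome, truth


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def boost5_profile(length: int, level: float = 2.0, plateau: int = 150,
                   end: int = 500) -> np.ndarray:
    """5' enrichment multiplier: ``level`` over [0, plateau], linear decay to
    1.0 at ``end``, flat afterwards."""
    p = np.arange(length, dtype=float)
    out = np.ones(length)
    out[p <= plateau] = level
    ramp = (p > plateau) & (p < end)
    out[ramp] = level - (level - 1.0) * (p[ramp] - plateau) / (end - plateau)
    return out


def positional_multiplier(gene: Gene, cfg: SimulationConfig) -> np.ndarray:
    """Expected coverage modulation m(p) along the transcript (p from TSS)."""
    L = gene.length
    m = boost5_profile(L, cfg.boost5_level, cfg.boost5_plateau, cfg.boost5_end)
    if cfg.nucleosome_amplitude > 0:
        center = cfg.first_nucleosome_offset + cfg.nucleosome_repeat / 2.0
        p = np.arange(L, dtype=float)
        m = m * (1.0 + cfg.nucleosome_amplitude *
                 np.cos(2 * np.pi * (p - center) / cfg.nucleosome_repeat))
    if cfg.pa_dip_span > 0 and cfg.pa_dip != 1.0:
        m[max(0, L - cfg.pa_dip_span):] *= cfg.pa_dip
    return m


def simulate_total_coverage(genome: GenomeModel, truth: TruthBundle,
                            depth: float | None = None,
                            seed: int | None = None) -> CoverageTrack:
    """Strand-specific total-RNAPII per-base count track.

    Per-base counts are Poisson(expression * depth * m(p)); a uniform Poisson
    background on both strands provides the antisense floor.
    """
    cfg = truth.config
    depth = cfg.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 303])
    track = CoverageTrack.zeros(genome.chrom_sizes, units="counts",
                                library_size=cfg.library_size)
    for g in genome.genes:
        lam = truth.expression[g.name]
        rate = lam * depth * positional_multiplier(g, cfg)
        counts = rng.poisson(rate).astype(float)
        arr = track.get(g.chrom, g.strand)
        if g.strand == "+":
            arr[g.start:g.end] += counts
        else:
            arr[g.start:g.end] += counts[::-1]
    bg = cfg.antisense_fraction * cfg.expression_median * depth
    if bg > 0:
        for key in track.keys():
            arr = track.data[key]
            arr += rng.poisson(bg, size=arr.size)
    return track


def simulate_phospho_tracks(genome: GenomeModel, truth: TruthBundle,
                            total: CoverageTrack,
                            reference: EmissionReference | None = None,
                            seed: int | None = None,
                            ) -> dict[str, CoverageTrack]:
    """Five phospho-mark count tracks consistent with the truth emissions.

    Over transcribed bins (truth state != N) the phospho RPM at every base is
    max(0, (total RPM + pc) * 2**e - pc) for the bin's drawn emission vector
    e, so the downstream log2-enrichment recovers e up to count noise and the
    zero floor.  Untranscribed territory carries only the nonspecific IP
    background (the same uniform Poisson floor as the total track): with no
    polymerase present there is no phospho-specific signal to modulate, and
    the recovered enrichment concentrates near zero, as in real data.
    """
    cfg = truth.config
    ref = reference if reference is not None else truth.reference
    if ref.n_states != truth.reference.n_states:
        raise ValueError("reference state count does not match the truth bundle")
    pc = cfg.pseudocount
    bw = cfg.bin_width
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 404])
    total_rpm = total.to_rpm()
    n_idx = ref.index("N") if "N" in ref.labels else -1
    bg = cfg.antisense_fraction * cfg.expression_median * cfg.depth
    out: dict[str, CoverageTrack] = {}
    for mi, mark in enumerate(MARKS):
        tr = CoverageTrack.zeros(genome.chrom_sizes, units="counts",
                                 library_size=cfg.library_size)
        for key in total_rpm.keys():
            t = total_rpm.data[key]
            e_bins = truth.emissions[key][:, mi]
            z_bins = truth.path.data[key]
            e_base = np.zeros(t.size)
            genic = np.zeros(t.size, dtype=bool)
            n_full = (t.size // bw) * bw
            e_base[:n_full] = np.repeat(e_bins[: n_full // bw], bw)
            genic[:n_full] = np.repeat(z_bins[: n_full // bw] != n_idx, bw)
            p_rpm = np.where(
                genic, np.maximum(0.0, (t + pc) * np.exp2(e_base) - pc), 0.0)
            mean_counts = p_rpm * cfg.library_size / 1e6 + bg
            if cfg.count_noise:
                tr.data[key] = rng.poisson(mean_counts).astype(float)
            else:
                tr.data[key] = mean_counts
        out[mark] = tr
    return out


def simulate_enrichment_matrix(truth: TruthBundle) -> EnrichmentMatrix:
    """Binned 5-mark observations drawn directly from the reference emission
    model over the truth layout (the HMM's idealized input)."""
    return truth.enrichment_matrix()


# ---------------------------------------------------------------------------
# Read table simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_read_table(genome: GenomeModel, truth: TruthBundle,
                        config: SimulationConfig | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Aligned reads with barcodes, exact PCR duplicates and junction tags.

    The emitted table contains a set of reads unique in
    (chrom, strand, start, barcode) plus exact duplicate copies so that
    duplicates make up ``duplication_rate`` of the final table.  On
    intron-containing genes, a fraction of reads is tagged as junction
    spanning, with classes drawn in ``junction_proportions`` (ExEx:ExI:IEx).
    """
    cfg = config if config is not None else truth.config
    if not (0 <= cfg.duplication_rate < 1):
        raise ValueError("duplication rate must be in [0, 1)")
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 505])
    props = np.asarray(cfg.junction_proportions, dtype=float)
    if props.sum() <= 0:
        raise ValueError("junction proportions must sum to > 0")
    props = props / props.sum()

    rows = []
    for g in genome.genes:
        n_unique = int(rng.poisson(truth.expression[g.name] * g.length * cfg.reads_per_nt))
        if n_unique == 0:
            continue
        max_start = max(g.start + 1, g.end - cfg.read_length)
        seen: set[tuple[int, str]] = set()
        tries = 0
        while len(seen) < n_unique and tries < 50:
            need = n_unique - len(seen)
            starts = rng.integers(g.start, max_start, size=need)
            bcs = ["".join(b) for b in _BASES[rng.integers(0, 4, size=(need, 5))]]
            for s, b in zip(starts, bcs):
                seen.add((int(s), b))
            tries += 1
        tagged = sorted(seen)
        is_junction = (g.has_intron and
                       rng.random(len(tagged)) < cfg.junction_fraction)
        tags = np.where(is_junction,
                        np.array(["ExEx", "ExI", "IEx"])[
                            rng.choice(3, size=len(tagged), p=props)],
                        "none")
        for (s, b), tag in zip(tagged, tags):
            rows.append((g.chrom, s, min(s + cfg.read_length, g.end),
                         g.strand, b, str(tag)))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "barcode", "junction_tag"])
    n_unique_total = len(df)
    d = cfg.duplication_rate
    n_dup = int(np.floor(d / (1 - d) * n_unique_total)) if n_unique_total else 0
    if n_dup:
        dup_idx = rng.integers(0, n_unique_total, size=n_dup)
        df = pd.concat([df, df.iloc[dup_idx]], ignore_index=True)
        order = rng.permutation(len(df))
        df = df.iloc[order].reset_index(drop=True)
    return df
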