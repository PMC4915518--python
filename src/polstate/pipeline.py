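"""End-to-end pipeline: simulate (optional) -> enrich -> fit/select-K ->
decode -> label -> segment -> downstream analyses -> reproducibility report.

Every stage logs its seed and parameter snapshot to stderr; outputs carry a
header with the tool version, config hash and seed, and a machine-readable
run manifest is written as JSON.  Given the same config the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .hmm import PhosphoHMM
from .reproducibility import multi_init_agreement
from .segmentation import (anchors_from_genes, class_compare, metagene_states,
                           nucleosome_boundaries_bed, path_to_segments,
                           periodicity, state_enrichment,
                           state_transition_positions)
from .signal import enrichment_from_tracks
from .simulate import (EmissionReference, SimulationConfig, TruthBundle,
                       simulate_genome, simulate_phospho_tracks,
                       simulate_read_table, simulate_total_coverage)
from .tracks import MARKS

log = logging.getLogger("polstate")


@dataclass
class PipelineConfig:
    """Validated defaults for a full run: pseudocount 5, 20-nt bins, K = 8
    chosen from the 3..15 sweep, 10 initializations, 1,000 permutations."""

    out_dir: str = "polstate_out"
    pseudocount: float = 5.0
    bin_width: int = 20
    n_states: int = 8
    k_min: int = 3
    k_max: int = 15
    em_tol: float = 1e-4
    em_max_iter: int = 300
    n_restarts: int = 8
    seed: int = 0
    n_init: int = 10
    n_perm: int = 1000
    run_select_k: bool = False
    run_reproducibility: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.pseudocount <= 0 or self.bin_width <= 0:
            raise ValueError("pseudocount and bin width must be positive")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("bad K range")
        if self.n_states < 1 or self.n_init < 2 or self.n_perm < 1:
            raise ValueError("bad model-selection / reproducibility settings")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["junction_proportions"] = list(
            d["simulation"]["junction_proportions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim.setdefault("junction_proportions", (1.0, 1.0, 1.0))
            sim["junction_proportions"] = tuple(sim["junction_proportions"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns a manifest of outputs.

    A stage failure halts the pipeline with the stage name; outputs of
    completed stages are retained on disk.
    """
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = cfg.to_dict()
    hashed.pop("out_dir", None)  # identical analyses hash identically
    chash = pio.config_hash(hashed)
    manifest = {"config_hash": chash, "seed": cfg.seed, "stages": [], "outputs": {}}

    def stage(name):
        log.info("stage %s (seed=%s, config=%s)", name, cfg.seed, chash)
        manifest["stages"].append(name)

    def emit(key, path):
        manifest["outputs"][key] = str(path)

    def write_tsv(df, path):
        with open(path, "w") as fh:
            fh.write(f"# polstate config={chash} seed={cfg.seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    try:
        stage("simulate")
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed,
                                  bin_width=cfg.bin_width,
                                  pseudocount=cfg.pseudocount)
        genome, truth = simulate_genome(sim)
        total = simulate_total_coverage(genome, truth)
        phospho = simulate_phospho_tracks(genome, truth, total)
        reads = simulate_read_table(genome, truth)
        pio.write_chrom_sizes(genome.chrom_sizes, out / "genome.chrom.sizes")
        pio.write_gff3(genome, out / "annotation.gff3", seed=cfg.seed, cfg_hash=chash)
        nucs = nucleosome_boundaries_bed(genome)
        pio.write_bed(nucs, out / "nucleosome_boundaries.bed", seed=cfg.seed, cfg_hash=chash)
        pio.write_bed(path_to_segments(truth.path, truth.labeling),
                      out / "truth_states.bed", seed=cfg.seed, cfg_hash=chash)
        pio.write_bedgraph(total, out / "total", seed=cfg.seed, cfg_hash=chash)
        for mark in MARKS:
            pio.write_bedgraph(phospho[mark], out / mark, seed=cfg.seed, cfg_hash=chash)
        pio.write_read_table(reads, out / "reads.tsv", seed=cfg.seed, cfg_hash=chash)
        sim.to_json(out / "simulation_config.json")
        emit("annotation", out / "annotation.gff3")

        stage("enrich")
        X = enrichment_from_tracks(total, phospho, pseudocount=cfg.pseudocount,
                                   bin_width=cfg.bin_width)
        write_tsv(X.to_frame(), out / "enrichment.tsv")
        emit("enrichment", out / "enrichment.tsv")

        if cfg.run_select_k and cfg.k_min != cfg.k_max:
            stage("select-k")
            sel = PhosphoHMM(X, n_states=cfg.n_states).select_n_states(
                k_range=range(cfg.k_min, cfg.k_max + 1), seed=cfg.seed,
                tol=cfg.em_tol, max_iter=cfg.em_max_iter)
            write_tsv(sel.to_frame(), out / "mse_by_k.tsv")
            n_states = sel.chosen_k
            emit("mse_by_k", out / "mse_by_k.tsv")
        else:
            log.info("select-k skipped (single K = %d)", cfg.n_states)
            n_states = cfg.n_states

        stage("fit")
        model = PhosphoHMM(X, n_states=n_states)
        res = model.fit(seed=cfg.seed, tol=cfg.em_tol, max_iter=cfg.em_max_iter,
                        n_restarts=cfg.n_restarts)

        stage("label")
        res.label_states(EmissionReference.default())
        res.save(out / "model.json")
        emit("model", out / "model.json")

        stage("decode+segment")
        path = res.decode()
        seg = path_to_segments(path, res.labels)
        pio.write_bed(seg, out / "segmentation.bed", seed=cfg.seed, cfg_hash=chash)
        emit("segmentation", out / "segmentation.bed")

        stage("analyses")
        genes = genome.genes
        mrna = [g for g in genes if g.biotype == "mRNA"]
        windows = anchors_from_genes(mrna, "tss").assign(
            end=lambda d: d["start"] + 500)
        write_tsv(state_enrichment(path, windows, res.labels),
                  out / "state_enrichment_tss500.tsv")
        write_tsv(metagene_states(path, mrna, labeling=res.labels).to_frame(),
                  out / "metagene_states_tss.tsv")
        trans = state_transition_positions(path, mrna, res.labels)
        write_tsv(trans.table, out / "transitions.tsv")
        write_tsv(class_compare(X, genes, first_500_only=False),
                  out / "class_compare.tsv")
        per = periodicity(total.to_rpm(), nucleosome_boundaries_bed(genome))
        emit("transitions", out / "transitions.tsv")

        repro = None
        if cfg.run_reproducibility:
            stage("reproducibility")
            repro = multi_init_agreement(X, K=n_states, n_init=cfg.n_init,
                                         tol=cfg.em_tol,
                                         max_iter=cfg.em_max_iter,
                                         n_restarts=cfg.n_restarts)
            with open(out / "reproducibility.json", "w") as fh:
                json.dump(repro.to_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
            emit("reproducibility", out / "reproducibility.json")

        summary = {
            "config_hash": chash, "seed": cfg.seed, "n_states": int(n_states),
            "n_bins": int(X.n_bins), "loglik": res.loglik, "mse": res.mse,
            "converged": bool(res.converged),
            "median_i1_exit_nt": trans.median_i1_exit,
            "censored_i1": trans.censored_i1,
            "periodicity_nt": per.period,
            "periodicity_reliable": per.reliable,
        }
        if repro is not None:
            summary["mean_agreement"] = repro.mean_agreement
            summary["agreement_baseline"] = repro.baseline
        manifest["summary"] = summary
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline halted at stage '{failed}': {exc}") from exc
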