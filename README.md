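# polstate

Genome segmentation of RNA polymerase II (RNAPII) C-terminal domain (CTD)
phosphorylation states from strand-specific mCRAC-style coverage data.

## The problem

During each transcription cycle the CTD of the largest RNAPII subunit — an
array of Y¹S²P³T⁴S⁵P⁶S⁷ heptads — is reversibly phosphorylated on Tyr1, Ser2,
Thr4, Ser5 and Ser7. Strand-specific UV-crosslinking maps (total RNAPII plus
one IP per phospho-mark) give nucleotide-resolution profiles of each
modification along the nascent transcriptome of budding yeast. `polstate`
turns such per-base coverage into a discrete **phosphorylation-state
segmentation** of the genome and reproduces the downstream analyses built on
it: state metagenes, nucleosome-boundary alignment, ncRNA class comparisons
(mRNA vs CUT vs SUT), initiation-exit position curves and segmentation
reproducibility statistics. A bundled synthetic data generator emulates the
full data-generating process so that every stage can be validated against a
known ground truth.

## Model

For each 20-nt bin *n* of each (chromosome, strand) the observation is the
5-vector of log-enrichments

x_n = ( log₂((P_m + 5)/(T + 5)) )_m,  m ∈ {Tyr1, Ser2, Thr4, Ser5, Ser7},

with P_m and T the per-base phospho and total RNAPII coverage in reads per
million (pseudocount 5, averaged per bin). The sequence {x_n} is modelled by
a K-state hidden Markov model with multivariate Gaussian emissions,

P(x_n | z_n = i) = N(x_n | μ_i, Σ_i),   P(z_n = j | z_{n−1} = i) = A_ij,

learned by Baum–Welch expectation maximisation (K-means initialised,
likelihood-selected restarts) and decoded with the Viterbi algorithm.
Model fit across K is measured by the mean squared error

MSE = (1 / 10N) Σ_s Σ_n ‖ x_n^s − μ_{z_n^s} ‖²,

whose elbow over K = 3…15 selects the working state number (K = 8: two
initiation states I1/I2, early elongation EE, elongation E1–E3, a
low-phosphorylation state L and an untranscribed noise state N).

## Worked example

```python
import polstate as ps
from polstate.segmentation import state_transition_positions

# synthetic study: ~60 genes (mRNA/CUT/SUT/snoRNA), total + 5 phospho tracks
genome, truth = ps.simulate_genome(ps.SimulationConfig(seed=7))
total   = ps.simulate_total_coverage(genome, truth)
phospho = ps.simulate_phospho_tracks(genome, truth, total)
X = ps.enrichment_from_tracks(total, phospho)     # binned 5-mark matrix

res = ps.PhosphoHMM(X, n_states=8).fit(seed=1)    # Baum-Welch + Viterbi
res.label_states(ps.EmissionReference.default())
print(res.summary())
```

prints

```
Phosphorylation-state HMM results
================================================================
states (K):        8
observations:      11780 bins x 5 marks
sequences:         2
log-likelihood:    73921.131
EM iterations:     6 (converged)
MSE (Viterbi):     0.0658
init seed:         1
----------------------------------------------------------------
state  label  occupancy    Tyr1    Ser2    Thr4    Ser5    Ser7
    0      N      0.712   -0.00    0.00   -0.00   -0.00   -0.00
    1     I1      0.052   -0.89   -0.71   -0.30    0.80   -0.02
    2     I2      0.040    0.21    0.15   -0.20    0.97    1.03
    3      L      0.020   -0.51   -0.40   -0.72   -0.67   -0.64
    4     E2      0.040   -0.63    0.54    0.20   -0.80    0.39
    5     EE      0.057    0.78    0.68   -0.58   -0.38    0.59
    6     E3      0.039    0.69   -0.41    0.52   -0.89   -0.71
    7     E1      0.040    0.33    0.91    1.00   -0.57   -0.38
```

Each row is one hidden state: its genomic occupancy and learned mean
log₂-enrichment per mark. The initiation states carry the Ser5P signature
(intermediate I1, high I2 with Ser7P), early elongation gains
Tyr1P/Ser2P/Ser7P while Ser5P drops, E1 peaks in Thr4P, and N sits at zero
over untranscribed territory. Downstream:

```python
path = res.decode()
mrna = [g for g in genome.genes_of_class("mRNA") if not g.has_intron]
tr = state_transition_positions(path, mrna, res.labels)
print(tr.median_i1_exit)        # 160.0  (nt from the TSS; truth switches at +160)
```

On the same run, CUT ncRNAs never leave I1 (censoring fraction 1.00) while
every intronless mRNA exits I1 at a median of 160 nt — well short of the
CUT median length — and the nucleosome-boundary-anchored total-RNAPII
metagene shows a ~150-nt periodicity (147 nt on this seed).

The same stages are scriptable from the shell:

```bash
polstate simulate --out sim --seed 7
polstate enrich --total sim/total --chrom-sizes sim/genome.chrom.sizes \
    --mark Tyr1=sim/Tyr1 --mark Ser2=sim/Ser2 --mark Thr4=sim/Thr4 \
    --mark Ser5=sim/Ser5 --mark Ser7=sim/Ser7 --out enrichment.tsv
polstate fit --matrix enrichment.tsv --k 8 --seed 1 --out model.json
polstate run --out full_run --seed 7       # entire pipeline + reports
```

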