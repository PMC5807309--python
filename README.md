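# splandscape

Parsimonious reconstruction of RNA structure landscapes from chemical
structure-profiling (SP) sequencing data.

Many regulatory RNAs — riboswitches, riboSNitches, thermosensors, folding
intermediates — function through several co-existing structures at different
abundances. SP experiments (SHAPE, DMS) probe such samples in bulk: a reagent
modifies structurally unconstrained nucleotides, and reverse transcription
reports the modifications either by **truncation** (the cDNA stops at the
first modified site) or by **mutation** (the enzyme reads through, leaving
mismatches). The resulting data are ensemble averages, which single-structure
analyses cannot unmix. `splandscape` deconvolves them: given a set of
candidate structures and the binned reads, it selects a small subset of
structures that jointly explain the observed modification patterns and
estimates their relative abundances.

The package is a library: import it, or start from the narrative scripts in
`examples/`.

## Model

Reads are binned into modification *patterns* — a stop index `p ∈ 1..L+1`
(truncation; `L+1` is a complete read) or a set of mutated informative sites
(mutation). Pattern frequencies form the observation vector **y**, modeled as

    y = X ρ + ε

where `ρ` holds the unknown relative abundances of the `S` candidate
structures and `x_ps = Pr(pattern p | structure s)` comes from a generative
read model: each structure is a binary vector of constrained/unconstrained
sites (base pairs, pseudoknots, and tertiary or ligand contacts all count as
constrained); an unconstrained site is modified with probability `η`, and
every site independently suffers a noise event (natural drop-off or
background mutation) with probability `γ_l`, estimated from a mock-treated
control as `γ̂_l = Y_l / C_l−`. Site-wise reactivities follow as
`β̂_l = (X_l/C_l+ − γ̂_l)/(1 − γ̂_l)`, and `η̂` is the median of the β̂ values
exceeding their mean. Sites are numbered from the 3′ priming site inside the
model (truncation products accumulate from there); all files and displayed
coordinates are conventional 5′→3′.

Candidates plainly inconsistent with the data (constraining more than
`max(1, |H|/2)` of the highly reactive sites `H = {l : β̂_l > η̂}`) are
removed, abundances are estimated by non-negative least squares
(`ρ̂ = argmin_{ρ≥0} ‖y − Xρ‖₂`), and structures whose normalized abundance
exceeds a threshold (default 1%) are selected and renormalized. Post-
processing turns the selected ensemble into pairing-probability matrices
`P_ij`, per-site Shannon entropies `H_i = −Σ_j P_ij log₂ P_ij`, motif-defined
cluster trajectories, and a non-negative linear fit linking cluster
abundances to functional readouts.

A full simulator closes the loop: exact pattern distributions from a declared
ground truth, seeded multinomial read draws, Gaussian count noise, decoy
structures, multinomial bootstrap, and recovery scoring.

## Worked example

```python
import splandscape as sp

seq, hairpin5, hairpin3 = sp.bistable_example()
truth = sp.GroundTruth(structures=[hairpin5, hairpin3], abundances=[0.7, 0.3],
                       eta=0.2, gamma=0.02, mode="truncation")
reads = sp.draw_reads(sp.pattern_distribution(truth), N=200_000, seed=7)

candidates = sp.CandidateSet(
    structures=[hairpin5, hairpin3]
    + sp.sample_random_structures(seq, 8, seed=9, id_prefix="decoy")
).dedup()
result, profile = sp.fit_pattern_counts(candidates, reads)
print(result.selected)
```

With a simulated mock-treated control (see `examples/02_fit_truncation_mixture.py`)
this prints:

```
estimated eta = 0.198 (true 0.200)
selected ensemble (truth: hairpin5p 0.70, hairpin3p 0.30):
  hairpin5p  0.676
  hairpin3p  0.301
  decoy4     0.023
residual ||y - X rho|| = 1.99e-03
```

The two true folds are recovered at close to their generating abundances; the
one decoy that survives selection sits near the threshold. `result.selected`
is the renormalized abundance of each selected structure — the reconstructed
landscape. The other examples cover pseudoknot parsing and motif queries,
DMS mutational profiling and the mutation→truncation projection, entropy and
cluster trajectories, and the file-based workflow with provenance.

## Acceptance script

`scripts/acceptance.py` re-runs the package's closed-loop validation from
scratch: it simulates reads from 20 seeded ground-truth ensembles on an
engineered 33-nt landscape (2–4 true folds, 10 decoy structures populating
10% of the ensemble, 10⁵ reads), runs the full blind reconstruction pipeline
on each, and prints the recovery summary, along with a single-structure
η-recovery check. Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
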