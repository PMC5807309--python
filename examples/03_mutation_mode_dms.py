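"""DMS mutational profiling: fit read-level mutation patterns directly.

Mutation-detected reads carry several modifications each, so they resolve
joint pairing states of sites within single molecules.  This example
simulates DMS-MaPseq-style reads over the engineered 33-nt landscape (only
A/C sites are informative), fits them in mutation mode, and then repeats the
fit after projecting every read onto its first modification — the in-silico
truncation data set.  The comparison shows where the two detection
paradigms part ways: single-modification patterns suffice for a two-fold
candidate set, but against the full four-fold set the projected data are
under-determined (read-through to the 5' stem is rare, so its pairing state
is weakly constrained) and the fit drifts to a marginal-equivalent mixture.
"""

import splandscape as sp

seq, folds = sp.two_hairpin_landscape()
informative = sp.informative_sites_for(seq, "DMS")

truth = sp.GroundTruth(
    structures=[folds["FA"], folds["FB"]],
    abundances=[0.6, 0.4],
    eta=0.15,
    gamma=0.0,  # no control available: noise set to zero
    mode="mutation",
    informative_sites=informative,
)
reads = sp.draw_reads(sp.pattern_distribution(truth), N=100_000, seed=21)
print(f"{len(reads.counts)} distinct mutation patterns over "
      f"{len(informative)} informative A/C sites "
      f"(2^{len(informative)} = {2**len(informative)} theoretically possible)")
print(f"mean modifications per read: {sp.mean_modifications_per_read(reads):.3f}")

candidates = sp.CandidateSet(
    structures=list(folds.values()), informative_sites=informative
)

res_mut, _ = sp.fit_pattern_counts(
    candidates, reads, restrict_eta_to_informative=True
)
print("mutation-mode fit (truth: FA 0.60, FB 0.40):")
for sid, ab in res_mut.selected.sort_values(ascending=False).items():
    print(f"  {sid:4s} {ab:.3f}")

projected = sp.project_mutation_to_truncation(reads)
two_fold = sp.CandidateSet(
    structures=[folds["FA"], folds["FB"]], informative_sites=informative
)
res_two, _ = sp.fit_pattern_counts(
    two_fold, projected, restrict_eta_to_informative=True
)
print("projected to truncation patterns, two-fold candidate set:")
for sid, ab in res_two.selected.sort_values(ascending=False).items():
    print(f"  {sid:4s} {ab:.3f}")

res_four, _ = sp.fit_pattern_counts(
    candidates, projected, restrict_eta_to_informative=True
)
print("projected, full four-fold candidate set (under-determined):")
for sid, ab in res_four.selected.sort_values(ascending=False).items():
    print(f"  {sid:4s} {ab:.3f}")
# Mutation mode recovers 0.60/0.40 against all four folds.  The projected
# single-modification data still resolve FA vs FB, but with the open (F0)
# and double-hairpin (FD) folds also on offer they admit an almost equally
# good marginal-level explanation - the joint information discarded by the
# projection is exactly what ruled those folds out.
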