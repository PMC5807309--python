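"""Read simulation from a known ground-truth ensemble, and recovery scoring.

A ground truth is a small set of structures with abundances on the simplex,
plus the modification probability eta and per-site noise gamma.  The exact
pattern distribution is the abundance mixture of the model's per-structure
pattern probabilities; sequencing is a multinomial draw at a chosen depth.
Two noise mechanisms mirror realistic degradation: additive Gaussian
perturbation of pattern counts (measurement noise) and decoy structures
populating a fixed fraction of the ensemble (unmodeled structural dynamics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import model as _model
from .patterns import (
    MUTATION,
    TRUNCATION,
    PatternCounts,
    ReadPattern,
)
from .structures import CandidateSet, Structure, parse_dotbracket

logger = logging.getLogger(__name__)

#: Full-enumeration limit for the mutation pattern space (2^K patterns).
MAX_ENUM_SITES = 20


class SimulationError(ValueError):
    pass


@dataclass
class GroundTruth:
    """A stated world: structures, abundances, eta, gamma, mode, chemistry."""

    structures: list[Structure]
    abundances: np.ndarray
    eta: float
    gamma: np.ndarray | float
    mode: str = TRUNCATION
    informative_sites: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.structures):
            raise SimulationError("abundances/structures length mismatch")
        if np.any(self.abundances < 0) or abs(self.abundances.sum() - 1.0) > 1e-9:
            raise SimulationError("abundances must be a simplex vector")

    @property
    def L(self) -> int:
        return len(self.structures[0])

    def candidate_set(self) -> CandidateSet:
        return CandidateSet(
            structures=list(self.structures),
            informative_sites=self.informative_sites,
        )


@dataclass
class Distribution:
    """Exact pattern distribution implied by a ground truth."""

    patterns: list[ReadPattern]
    probs: np.ndarray
    mode: str
    L: int
    informative_sites: tuple[int, ...] | None = None


def pattern_distribution(truth: GroundTruth) -> Distribution:
    """Mixture distribution sum_s rho_s * Pr(pattern | s) over the full
    pattern space (L+1 truncation patterns, or all 2^K mutation subsets).

    Raises for mutation mode beyond ``MAX_ENUM_SITES`` informative sites;
    use :func:`draw_reads_per_site` there instead.
    """
    cands = truth.candidate_set()
    if truth.mode == TRUNCATION:
        X = _model.build_design_truncation(cands, truth.eta, truth.gamma)
    else:
        info = truth.informative_sites or tuple(range(1, truth.L + 1))
        if len(info) > MAX_ENUM_SITES:
            raise SimulationError(
                f"{len(info)} informative sites: full enumeration infeasible, "
                "use draw_reads_per_site"
            )
        pats = _model.enumerate_mutation_patterns(info)
        X = _model.build_design_mutation(cands, truth.eta, truth.gamma, pats)
    probs = X.values @ truth.abundances
    return Distribution(
        patterns=X.pattern_index,
        probs=probs,
        mode=truth.mode,
        L=truth.L,
        informative_sites=truth.informative_sites,
    )


def draw_reads(
    dist: Distribution, N: int, seed: int | np.random.Generator
) -> PatternCounts:
    """Multinomial draw of N reads from an exact pattern distribution."""
    if N < 1:
        raise SimulationError("need at least one read")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(N, dist.probs / dist.probs.sum())
    counts = {
        pat: int(c) for pat, c in zip(dist.patterns, draws) if c > 0
    }
    return PatternCounts(
        mode=dist.mode, L=dist.L, counts=counts,
        informative_sites=dist.informative_sites,
    )


def draw_reads_per_site(
    truth: GroundTruth, N: int, seed: int | np.random.Generator
) -> PatternCounts:
    """Per-read sampling path for mutation mode with many informative sites.

    Distributionally identical to the enumerated mixture: per read, a
    structure is drawn from the abundances, then each informative site
    mutates independently (unconstrained: 1-(1-eta)(1-gamma_l); constrained:
    gamma_l).
    """
    if truth.mode != MUTATION:
        raise SimulationError("per-site sampling is a mutation-mode path")
    rng = np.random.default_rng(seed)
    L = truth.L
    info = np.asarray(truth.informative_sites or range(1, L + 1), dtype=int)
    gamma = np.asarray(truth.gamma, dtype=float)
    if gamma.ndim == 0:
        gamma = np.full(L, float(gamma))
    which = rng.choice(len(truth.structures), size=N, p=truth.abundances)
    counts: dict[ReadPattern, int] = {}
    for s_idx, n_s in zip(*np.unique(which, return_counts=True)):
        s = truth.structures[s_idx]
        unconstrained = s.state[info - 1] == 0
        p_mut = np.where(
            unconstrained,
            1.0 - (1.0 - truth.eta) * (1.0 - gamma[info - 1]),
            gamma[info - 1],
        )
        hits = rng.random((n_s, len(info))) < p_mut
        for row in hits:
            pat = ReadPattern(MUTATION, tuple(info[row]))
            counts[pat] = counts.get(pat, 0) + 1
    return PatternCounts(
        mode=MUTATION, L=L, counts=counts,
        informative_sites=truth.informative_sites,
    )


def add_count_noise(
    pc: PatternCounts, sigma: float, seed: int | np.random.Generator
) -> PatternCounts:
    """Perturb each pattern count by Gaussian noise with sd = sigma * count,
    rounding and flooring at zero; totals are recomputed."""
    if sigma < 0:
        raise SimulationError("sigma must be >= 0")
    if sigma == 0:
        return PatternCounts(
            mode=pc.mode, L=pc.L, counts=dict(pc.counts),
            informative_sites=pc.informative_sites,
        )
    rng = np.random.default_rng(seed)
    counts: dict[ReadPattern, int] = {}
    for pat, c in pc.counts.items():
        noisy = int(round(c + rng.normal(0.0, sigma * c)))
        if noisy > 0:
            counts[pat] = noisy
    if not counts:
        raise SimulationError("noise wiped out every pattern count")
    return PatternCounts(
        mode=pc.mode, L=pc.L, counts=counts,
        informative_sites=pc.informative_sites,
    )


def add_decoys(
    truth: GroundTruth, decoys: Sequence[Structure], fraction: float = 0.10
) -> GroundTruth:
    """Scale true abundances by (1 - fraction) and share ``fraction`` of the
    ensemble equally among the decoy structures."""
    if not (0.0 <= fraction < 1.0):
        raise SimulationError("fraction must be in [0, 1)")
    if fraction == 0 or not decoys:
        return truth
    abund = np.concatenate(
        [
            truth.abundances * (1.0 - fraction),
            np.full(len(decoys), fraction / len(decoys)),
        ]
    )
    return replace(
        truth,
        structures=list(truth.structures) + list(decoys),
        abundances=abund,
    )


def bootstrap_counts(
    pc: PatternCounts, replicates: int, seed: int | np.random.Generator
) -> list[PatternCounts]:
    """Multinomial resamples at the observed depth — in-silico technical
    replicates for gauging estimate spread at a given sequencing depth."""
    if replicates < 1:
        raise SimulationError("need at least one replicate")
    rng = np.random.default_rng(seed)
    pats = pc.patterns()
    n = pc.total_reads
    p = np.array([pc.counts[q] for q in pats], dtype=float) / n
    out = []
    for _ in range(replicates):
        draws = rng.multinomial(n, p)
        out.append(
            PatternCounts(
                mode=pc.mode, L=pc.L,
                counts={q: int(c) for q, c in zip(pats, draws) if c > 0},
                informative_sites=pc.informative_sites,
            )
        )
    return out


@dataclass
class RecoveryScore:
    """How well a fit recovered a ground truth.

    A selected structure matches a truth structure when their binary state
    vectors agree at every informative site — the resolution limit of the
    data.  ``l1_error`` sums |estimated - true| over truth structures plus
    the abundance of selected structures matching no truth.
    """

    l1_error: float
    precision: float
    recall: float
    per_structure_error: dict[str, float]


def score_recovery(
    fit: "_model.FitResult",
    truth: GroundTruth,
    candidates: CandidateSet,
) -> RecoveryScore:
    info = np.asarray(
        truth.informative_sites or range(1, truth.L + 1), dtype=int
    )
    by_id = {s.id: s for s in candidates}
    matched_truth: set[int] = set()
    est = np.zeros(len(truth.structures))
    spurious = 0.0
    n_matching_selected = 0
    for sid, ab in fit.selected.items():
        s = by_id[sid]
        hit = False
        for t_idx, t in enumerate(truth.structures):
            if np.array_equal(s.state[info - 1], t.state[info - 1]):
                est[t_idx] += ab
                matched_truth.add(t_idx)
                hit = True
        if hit:
            n_matching_selected += 1
        else:
            spurious += ab
    n_sel = len(fit.selected)
    per_err = {
        t.id: abs(est[i] - truth.abundances[i])
        for i, t in enumerate(truth.structures)
    }
    return RecoveryScore(
        l1_error=float(sum(per_err.values()) + spurious),
        precision=n_matching_selected / n_sel if n_sel else 0.0,
        recall=len(matched_truth) / len(truth.structures),
        per_structure_error=per_err,
    )


# ---------------------------------------------------------------------------
# Engineered fixtures and random structure generation
# ---------------------------------------------------------------------------

def bistable_example() -> tuple[str, Structure, Structure]:
    """A 34-nt engineered two-hairpin RNA with two mutually compatible but
    clearly distinguishable folds (5' and 3' hairpins), for tests/examples."""
    stem_a, stem_b = "GGCAGC", "CCGGAC"
    seq = stem_a + "ACAA" + "GCUGCC" + "AA" + stem_b + "AACA" + "GUCCGG"
    db_a = "((((((....))))))" + "." * 18
    db_b = "." * 18 + "((((((....))))))"
    a = parse_dotbracket(db_a, seq, id="hairpin5p", source="manual")
    b = parse_dotbracket(db_b, seq, id="hairpin3p", source="manual")
    return seq, a, b


def two_hairpin_landscape() -> tuple[str, dict[str, Structure]]:
    """A 33-nt toy landscape with four alternative folds, designed for
    DMS-style mutational profiling.

    The sequence carries informative A/C sites both on the 5' arms of two
    hairpin stems (so the folds are pairwise distinguishable at informative
    sites) and in the loops, linker and tail (7 sites unpaired in every fold,
    which the eta heuristic needs).  Stems close with G-U/G-C partners so the
    3' arms stay uninformative.  Folds: ``FA`` (5' hairpin), ``FB``
    (3' hairpin), ``FD`` (both), ``F0`` (open).
    """
    seq = "ACACA" + "AAGG" + "UGUGU" + "A" + "CACAC" + "CAGG" + "GUGUG" + "GUAA"
    h = "(((((....)))))"
    dbs = {
        "FA": h + "." * 19,
        "FB": "." * 15 + h + "....",
        "FD": h + "." + h + "....",
        "F0": "." * 33,
    }
    return seq, {
        name: parse_dotbracket(db, seq, id=name, source="manual")
        for name, db in dbs.items()
    }


def sample_random_structures(
    sequence: str,
    n: int,
    seed: int | np.random.Generator,
    *,
    min_stem: int = 3,
    max_stem: int = 6,
    min_loop: int = 3,
    max_helices: int = 3,
    id_prefix: str = "rand",
) -> list[Structure]:
    """Random nested secondary structures over ``sequence``.

    A crude stand-in for a thermodynamic sampler: each structure places a
    random number of non-overlapping, non-crossing helices of random stem
    length.  Useful for decoys and candidate padding in simulations; makes
    no thermodynamic claims.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    out: list[Structure] = []
    for k in range(n):
        pairs: set[tuple[int, int]] = set()
        occupied = np.zeros(L + 1, dtype=bool)
        n_helices = int(rng.integers(1, max_helices + 1))
        for _ in range(n_helices):
            for _attempt in range(20):
                stem = int(rng.integers(min_stem, max_stem + 1))
                span = 2 * stem + min_loop
                if span > L:
                    continue
                i = int(rng.integers(1, L - span + 2))
                j = i + span - 1 + int(rng.integers(0, max(1, (L - span) // 4)))
                j = min(j, L)
                if j - i + 1 < span:
                    continue
                helix = [(i + t, j - t) for t in range(stem)]
                sites = [s for p in helix for s in p]
                if any(occupied[s] for s in sites):
                    continue
                crosses = any(
                    (a < i < b < j - stem + 1) or (i + stem - 1 < a < j < b)
                    for a, b in pairs
                )
                if crosses:
                    continue
                pairs.update(helix)
                occupied[sites] = True
                break
        out.append(
            Structure(
                id=f"{id_prefix}{k}",
                sequence=sequence,
                pairs=frozenset(pairs),
                source="sampled",
            )
        )
    return out
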