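"""The linear read-pattern model and its NNLS fit.

Observed pattern frequencies are modeled as a linear superposition of the
candidate structures' pattern-generation probabilities,

    y = X rho + eps,

where ``x_ps = Pr(pattern p | structure s)`` and rho holds the unknown
relative abundances.  Each column of X is computed from the generative read
model: an unconstrained site is modified with probability eta, every site l
additionally triggers a noise event (natural drop-off, or background
mutation) with probability gamma_l, and sites act independently.

In truncation mode the reverse transcriptase stops at the first site with any
event; with sites numbered 1..L from the 3' priming site, the probability of
stopping at p is the product of read-through factors over sites 1..p-1 times
the stop factor at p, and the complete-read pattern takes the remaining mass,
so every column is an exact probability distribution over the L+1 patterns.
In mutation mode each informative site contributes an independent
mutated/unmutated factor, so columns sum to 1 over a full pattern enumeration
and to the "captured mass" over the observed-pattern subset actually fitted.

Abundances are estimated by non-negative least squares, which in practice
yields sparse solutions; structures above a user threshold are selected and
renormalized to sum to 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .patterns import MUTATION, TRUNCATION, PatternError, ReadPattern
from .structures import CandidateSet, Structure, UNCONSTRAINED

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """P x S matrix of structure->pattern probabilities."""

    values: np.ndarray
    pattern_index: list[ReadPattern]
    structure_index: list[str]
    mode: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_sums(self) -> np.ndarray:
        """Per-structure probability mass captured by the included patterns."""
        return self.values.sum(axis=0)


def _site_factors(
    structure: Structure,
    eta: float,
    gamma: np.ndarray,
    informative: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(no-event, event) probability per site, in internal order.

    Only informative sites can be modified (base-selective chemistries);
    elsewhere — and at constrained sites — the only event source is noise.
    """
    modifiable = structure.state == UNCONSTRAINED
    if informative is not None:
        modifiable = modifiable & informative
    no_event = np.where(modifiable, (1.0 - eta) * (1.0 - gamma), 1.0 - gamma)
    return no_event, 1.0 - no_event


def _informative_mask(candidates: CandidateSet) -> np.ndarray | None:
    if candidates.informative_sites is None:
        return None
    mask = np.zeros(candidates.L, dtype=bool)
    mask[np.asarray(candidates.informative_sites, dtype=int) - 1] = True
    return mask


def _check_params(eta: float, gamma: np.ndarray, L: int) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim == 0:
        gamma = np.full(L, float(gamma))
    if len(gamma) != L:
        raise ModelError(f"gamma length {len(gamma)} != L={L}")
    if not (0.0 <= eta < 1.0) or np.any(gamma < 0) or np.any(gamma >= 1.0):
        raise ModelError("need eta in [0,1) and gamma in [0,1) at every site")
    return gamma


def truncation_pattern_space(L: int) -> list[ReadPattern]:
    """All L+1 truncation patterns: stop at 1..L plus the complete read."""
    return [ReadPattern(TRUNCATION, (p,)) for p in range(1, L + 2)]


def build_design_truncation(
    candidates: CandidateSet, eta: float, gamma: np.ndarray | float
) -> DesignMatrix:
    """Design matrix over the full truncation pattern space (P = L+1).

    For stop pattern p, ``x_ps = prod_{l<p} t_l * (1 - t_p)`` where ``t_l`` is
    the read-through probability of site l under structure s —
    ``(1-eta)(1-gamma_l)`` if l is unconstrained, ``1-gamma_l`` if constrained;
    the complete-read row is ``prod_l t_l``.  Columns sum to 1 exactly.

    If the candidate set declares informative sites (base-selective
    chemistry, or mutation data projected onto truncation patterns),
    non-informative sites cannot be modified and contribute noise only.
    """
    L = candidates.L
    gamma = _check_params(eta, gamma, L)
    info_mask = _informative_mask(candidates)
    X = np.empty((L + 1, len(candidates)))
    for s_idx, s in enumerate(candidates):
        through, stop = _site_factors(s, eta, gamma, info_mask)
        # cumulative read-through up to (not including) each site
        cum = np.concatenate(([1.0], np.cumprod(through)))
        X[:L, s_idx] = cum[:L] * stop
        X[L, s_idx] = cum[L]
    return DesignMatrix(
        values=X,
        pattern_index=truncation_pattern_space(L),
        structure_index=[s.id for s in candidates],
        mode=TRUNCATION,
    )


def enumerate_mutation_patterns(
    informative_sites: Sequence[int], max_sites: int = 20
) -> list[ReadPattern]:
    """All 2^K subsets of the informative sites, empty pattern first."""
    sites = sorted(informative_sites)
    if len(sites) > max_sites:
        raise ModelError(
            f"full enumeration over {len(sites)} informative sites is infeasible"
        )
    pats = [ReadPattern(MUTATION, ())]
    for k in range(1, len(sites) + 1):
        pats.extend(ReadPattern(MUTATION, c) for c in combinations(sites, k))
    return pats


def build_design_mutation(
    candidates: CandidateSet,
    eta: float,
    gamma: np.ndarray | float,
    patterns: Sequence[ReadPattern],
) -> DesignMatrix:
    """Design matrix over a given list of mutation patterns.

    Each entry is a product of independent per-site factors over the
    informative sites: a mutated unconstrained site contributes
    ``1-(1-eta)(1-gamma_l)``, an unmutated unconstrained site
    ``(1-eta)(1-gamma_l)``, a mutated constrained site ``gamma_l`` and an
    unmutated constrained site ``1-gamma_l``.
    """
    L = candidates.L
    gamma = _check_params(eta, gamma, L)
    if candidates.informative_sites is None:
        info = np.arange(1, L + 1)
    else:
        info = np.asarray(candidates.informative_sites, dtype=int)
    info_set = frozenset(int(i) for i in info)
    for pat in patterns:
        if pat.mode != MUTATION:
            raise ModelError("mutation design needs mutation patterns")
        if not set(pat.sites) <= info_set:
            raise ModelError(f"pattern {pat.sites} outside informative sites")
    X = np.empty((len(patterns), len(candidates)))
    idx = info - 1
    # membership mask per pattern over the informative sites, computed once
    pos = {int(site): k for k, site in enumerate(info)}
    masks = np.zeros((len(patterns), len(info)), dtype=bool)
    for p_idx, pat in enumerate(patterns):
        for site in pat.sites:
            masks[p_idx, pos[site]] = True
    for s_idx, s in enumerate(candidates):
        clean, mutated = _site_factors(s, eta, gamma)
        factors = np.where(masks, mutated[idx], clean[idx])
        X[:, s_idx] = factors.prod(axis=1)
    return DesignMatrix(
        values=X,
        pattern_index=list(patterns),
        structure_index=[s.id for s in candidates],
        mode=MUTATION,
    )


def prefilter(
    candidates: CandidateSet, beta: np.ndarray, eta: float
) -> tuple[CandidateSet, dict[str, list[int]]]:
    """Remove candidates markedly inconsistent with the reactivity profile.

    Highly reactive sites (beta_l > eta) are expected to be predominantly
    unpaired in the ensemble.  Because eta/beta estimates are noisy and high
    reactivities have the highest variance, a structure is removed only when
    it constrains more than ``max(1, |H|/2)`` of the highly reactive set H —
    i.e. more than a single nucleotide and more than half of H.

    Returns the filtered set and a map of removed id -> violating sites.
    """
    beta = np.asarray(beta, dtype=float)
    if candidates.informative_sites is not None:
        mask = np.zeros(candidates.L, dtype=bool)
        mask[np.asarray(candidates.informative_sites, dtype=int) - 1] = True
    else:
        mask = np.ones(candidates.L, dtype=bool)
    with np.errstate(invalid="ignore"):
        high = np.flatnonzero((beta > eta) & mask & np.isfinite(beta)) + 1
    if high.size == 0:
        logger.warning("no highly reactive sites: prefilter is a no-op")
        return candidates, {}
    allowed = max(1.0, high.size / 2.0)
    kept: list[Structure] = []
    removed: dict[str, list[int]] = {}
    for s in candidates:
        violating = [int(l) for l in high if s.state[l - 1]]
        if len(violating) > allowed:
            removed[s.id] = violating
        else:
            kept.append(s)
    if removed:
        logger.info(
            "prefilter removed %d structure(s) constrained at too many of the "
            "%d highly reactive sites", len(removed), high.size,
        )
    if not kept:
        raise ModelError("prefilter removed every candidate structure")
    from dataclasses import replace

    return replace(candidates, structures=kept), removed


@dataclass
class FitResult:
    """NNLS abundance estimates and the selected (thresholded) ensemble."""

    rho: pd.Series
    selected: pd.Series
    residual: float
    threshold: float
    diagnostics: dict = field(default_factory=dict)

    def selected_ids(self) -> list[str]:
        return list(self.selected.index)


def fit(X: DesignMatrix, y: np.ndarray, threshold: float = 0.01) -> FitResult:
    """Solve ``min ||y - X rho||_2 s.t. rho >= 0``, select and normalize.

    The abundance vector is first normalized by its own sum; structures whose
    normalized abundance strictly exceeds ``threshold`` (default 1%) are
    selected and renormalized to sum to 1.  All-zero columns are dropped with
    a warning; exactly duplicate columns (structures the data cannot
    distinguish) are merged, the merged abundance being reported on the first
    member of each group.
    """
    if not (0.0 <= threshold < 1.0):
        raise ModelError("threshold must be in [0, 1)")
    A = np.asarray(X.values, dtype=float)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != len(y):
        raise ModelError("design matrix rows do not match observation vector")
    ids = list(X.structure_index)
    if len(set(ids)) != len(ids):
        raise ModelError("duplicate structure ids in design matrix")
    if np.count_nonzero(y) <= 1:
        logger.warning("only one observed pattern: system severely under-determined")

    keep = np.flatnonzero(A.any(axis=0))
    dropped = [ids[j] for j in range(len(ids)) if j not in set(keep)]
    if dropped:
        logger.warning("dropping all-zero design column(s): %s", dropped)
    A = A[:, keep]
    kept_ids = [ids[j] for j in keep]

    # merge exactly duplicate columns: the solver would split their abundance
    # arbitrarily, an information-theoretic limit of the data, not a bug
    groups: dict[bytes, list[int]] = {}
    for j in range(A.shape[1]):
        groups.setdefault(A[:, j].tobytes(), []).append(j)
    merged_groups = [
        [kept_ids[j] for j in members]
        for members in groups.values()
        if len(members) > 1
    ]
    reps = [members[0] for members in groups.values()]
    A_fit = A[:, reps]
    rep_ids = [kept_ids[j] for j in reps]
    if merged_groups:
        logger.warning(
            "merged indistinguishable structure column group(s): %s", merged_groups
        )

    rho_fit, rnorm = nnls(A_fit, y)
    if not np.all(np.isfinite(rho_fit)):
        cond = np.linalg.cond(A_fit)
        raise ModelError(f"NNLS failed to converge (condition number {cond:.3g})")

    rho = pd.Series(0.0, index=ids)
    rho.loc[rep_ids] = rho_fit
    total = rho.sum()
    if total <= 0:
        raise ModelError("all abundances estimated at zero")
    normalized = rho / total
    selected = normalized[normalized > threshold]
    selected = selected / selected.sum()

    return FitResult(
        rho=rho,
        selected=selected,
        residual=float(rnorm),
        threshold=threshold,
        diagnostics={
            "dropped_columns": dropped,
            "merged_groups": merged_groups,
            "captured_mass": dict(zip(ids, np.asarray(X.values).sum(axis=0))),
            "n_patterns": len(y),
            "n_structures": len(ids),
        },
    )


def ideal_profile(
    structures: Sequence[Structure], abundances: np.ndarray, eta: float
) -> np.ndarray:
    """Model-implied reactivity profile of the reconstructed ensemble.

    beta_ideal_l = eta * sum_s rho_s * [l unconstrained in s]; intended for
    visual comparison against the measured profile, to flag situations where
    a key structure is likely missing from the candidate set.
    """
    abundances = np.asarray(abundances, dtype=float)
    L = len(structures[0])
    out = np.zeros(L)
    for s, rho in zip(structures, abundances):
        out += rho * (s.state == UNCONSTRAINED)
    return eta * out


def write_result_json(
    result: FitResult,
    structures: Sequence[Structure],
    path: str | Path,
) -> None:
    """Result JSON: selected structures (5'->3' dot-bracket) with abundances."""
    by_id = {s.id: s for s in structures}
    payload = {
        "selected": [
            {
                "id": sid,
                "dotbracket": by_id[sid].to_dotbracket(),
                "abundance": float(ab),
            }
            for sid, ab in result.selected.items()
        ],
        "residual": result.residual,
        "threshold": result.threshold,
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if k != "captured_mass"
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
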