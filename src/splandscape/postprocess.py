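"""Ensemble summaries: pairing probabilities, entropy, clusters, function fit.

The selected structures and their abundances define a small reconstructed
ensemble.  Per site i, the abundance-weighted frequency of each base pair
(i,j) plus the probability of being unpaired form a distribution over pairing
outcomes, whose Shannon entropy H_i (bits) quantifies local structural
diversity; the mean over sites compares ensembles across transcript lengths.
Because only selected structures enter, the entropy of the true ensemble is
systematically underestimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .structures import Structure, motif_contains

logger = logging.getLogger(__name__)


class PostprocessError(ValueError):
    pass


@dataclass
class EnsembleSummary:
    """Pairing-probability matrix, per-site entropies (bits) and their mean."""

    pairing: np.ndarray
    entropy: np.ndarray
    mean_entropy: float


def pairing_probabilities(
    structures: Sequence[Structure], abundances: np.ndarray, tol: float = 1e-6
) -> np.ndarray:
    """L x L matrix with P_ij = abundance-weighted frequency of pair (i,j)
    and P_ii = probability that site i is unpaired (internal coordinates).

    Each row is a probability distribution over the pairing outcomes of one
    site; off-diagonal entries are symmetric.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(structures) != len(abundances):
        raise PostprocessError("structures/abundances length mismatch")
    if abs(abundances.sum() - 1.0) > tol:
        raise PostprocessError(
            f"abundances sum to {abundances.sum():.6f}, expected 1"
        )
    L = len(structures[0])
    P = np.zeros((L, L))
    for s, rho in zip(structures, abundances):
        paired = np.zeros(L, dtype=bool)
        for i, j in s.pairs:
            P[i - 1, j - 1] += rho
            P[j - 1, i - 1] += rho
            paired[i - 1] = paired[j - 1] = True
        P[np.diag_indices(L)] += rho * (~paired)
    return P


def entropy(pairing: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Per-site Shannon entropies H_i = -sum_j P_ij log2 P_ij, and their mean.

    Rows must be probability distributions (0 log 0 := 0).
    """
    P = np.asarray(pairing, dtype=float)
    if np.any(P < -tol):
        raise PostprocessError("pairing matrix has negative entries")
    rowsums = P.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-6):
        raise PostprocessError("pairing matrix rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    H = -terms.sum(axis=1)
    H[H < 0] = 0.0  # -0.0 guard
    return H, float(H.mean())


def summarize_ensemble(
    structures: Sequence[Structure], abundances: np.ndarray
) -> EnsembleSummary:
    P = pairing_probabilities(structures, abundances)
    H, mean_H = entropy(P)
    return EnsembleSummary(pairing=P, entropy=H, mean_entropy=mean_H)


def smooth(series: np.ndarray, window: int = 3, edges: str = "shrink") -> np.ndarray:
    """Centered moving-mean filter (default window 3).

    ``edges="shrink"`` averages over the neighbors actually available at the
    boundaries; ``edges="valid"`` returns NaN where the full window does not
    fit.
    """
    if window % 2 == 0 or window < 1:
        raise PostprocessError("window must be odd and positive")
    x = np.asarray(series, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        if edges == "valid" and hi - lo < window:
            out[i] = np.nan
        else:
            out[i] = x[lo:hi].mean()
    return out


@dataclass
class MotifSpec:
    """A named motif predicate: a set of base pairs (internal coordinates)
    and the fraction of them a structure must realize to match."""

    name: str
    pairs: frozenset
    min_fraction: float = 1.0


def cluster_abundances(
    fits: Mapping[object, tuple[Sequence[Structure], np.ndarray]],
    motifs: Sequence[MotifSpec],
) -> pd.DataFrame:
    """Summed abundance per motif-defined cluster, per condition/length.

    ``motifs`` are evaluated in declared priority order: a structure joins the
    first cluster whose motif it contains; unmatched structures fall into
    ``OTHER``.  Rows sum to 1.
    """
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise PostprocessError("duplicate motif names (priority would be ambiguous)")
    rows = {}
    for key, (structures, abundances) in fits.items():
        row = dict.fromkeys(names + ["OTHER"], 0.0)
        for s, rho in zip(structures, np.asarray(abundances, dtype=float)):
            for m in motifs:
                if motif_contains(s, m.pairs, m.min_fraction):
                    row[m.name] += rho
                    break
            else:
                row["OTHER"] += rho
        rows[key] = row
    return pd.DataFrame.from_dict(rows, orient="index")[names + ["OTHER"]]


@dataclass
class FunctionFit:
    """Non-negative linear link between cluster abundances and a functional
    readout (e.g. reporter protein level), with normalized contributions."""

    alpha: float
    beta: float
    residual: float

    @property
    def contributions(self) -> tuple[float, float]:
        total = self.alpha + self.beta
        if total <= 0:
            raise PostprocessError("degenerate fit: alpha + beta = 0")
        return self.alpha / total, self.beta / total


def fit_function_model(
    on_abundance: np.ndarray,
    defoff_abundance: np.ndarray,
    measured_levels: np.ndarray,
) -> FunctionFit:
    """Fit ``level = alpha * ON+ + beta * DEF-OFF+`` by non-negative least
    squares across mutants/conditions; report normalized contributions."""
    a = np.asarray(on_abundance, dtype=float)
    b = np.asarray(defoff_abundance, dtype=float)
    y = np.asarray(measured_levels, dtype=float)
    if not (len(a) == len(b) == len(y)) or len(y) < 2:
        raise PostprocessError("need >= 2 aligned observations")
    A = np.column_stack([a, b])
    if np.linalg.matrix_rank(A) < 2:
        raise PostprocessError("rank-deficient design: clusters are collinear")
    coef, rnorm = nnls(A, y)
    return FunctionFit(alpha=float(coef[0]), beta=float(coef[1]), residual=float(rnorm))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_pairing_tsv(pairing: np.ndarray, path: str | Path, tol: float = 1e-12) -> None:
    """Sparse (i, j, P) TSV in 5'->3' indices; i=j rows carry the unpaired
    probability."""
    L = pairing.shape[0]
    rows = []
    for i in range(L):
        for j in range(i, L):
            if pairing[i, j] > tol:
                di, dj = sorted((L - i, L - j))
                rows.append((di, dj, pairing[i, j]))
    df = pd.DataFrame(sorted(rows), columns=["i", "j", "P"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_entropy_tsv(H: np.ndarray, path: str | Path) -> None:
    L = len(H)
    df = pd.DataFrame({"site": np.arange(1, L + 1), "entropy_bits": H[::-1]})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
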