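"""Closed-form reactivity and noise estimation.

The per-site noise rate gamma_l (natural reverse-transcriptase drop-off, or
background mutation) is estimated from a mock-treated control as the
maximum-likelihood ratio ``Y_l / C_l-``.  The per-site reactivity beta_l —
the ensemble-averaged probability that site l is modified — follows from the
treated sample as ``(X_l/C_l+ - gamma_l) / (1 - gamma_l)``.

The generative model assumes every structurally unconstrained site shares one
modification probability eta; a site that is unconstrained in all abundant
structures therefore shows beta_l ≈ eta, which motivates the robust rule used
here: eta-hat is the median of the beta values strictly exceeding their mean.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import CountProfile

logger = logging.getLogger(__name__)


class ReactivityError(ValueError):
    pass


@dataclass
class ReactivityProfile:
    """Site-wise estimates: beta (reactivity), gamma (noise), scalar eta.

    Vectors are in internal (3'->5') order; entries are probabilities in
    [0, 1] after clamping, NaN where coverage was zero (site missing).
    """

    beta: np.ndarray
    gamma: np.ndarray
    eta: float
    mode: str = "truncation"
    n_clamped: int = 0

    @property
    def L(self) -> int:
        return len(self.beta)


def estimate_gamma(control: CountProfile | None, L: int | None = None) -> np.ndarray:
    """Per-site noise rates from a mock-treated control.

    With no control available, noise cannot be estimated and gamma is set to
    zero (the treated signal is then interpreted as pure modification).
    Zero-coverage sites get gamma=0 with a warning.
    """
    if control is None:
        if L is None:
            raise ReactivityError("need L to build a zero gamma vector")
        logger.warning("no control sample: setting gamma to 0 at all sites")
        return np.zeros(L)
    Y = control.events.astype(float)
    C = control.coverage.astype(float)
    gamma = np.zeros_like(Y)
    covered = C > 0
    if np.any(~covered & (Y > 0)):
        raise ReactivityError("control events at zero-coverage site")
    if np.any(~covered):
        logger.warning(
            "%d control site(s) with zero coverage: gamma set to 0 there",
            int(np.sum(~covered)),
        )
    gamma[covered] = Y[covered] / C[covered]
    return gamma


def estimate_beta(treated: CountProfile, gamma: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-site reactivities from the treated sample, noise-corrected.

    Returns ``(beta, n_clamped)``.  Sites where noise exceeds signal produce
    negative maximum-likelihood values; these are clamped to 0 (the model
    needs probabilities) and the clamp count is returned and logged as a
    data-quality signal.  Zero-coverage sites are flagged missing (NaN).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma >= 1.0):
        raise ReactivityError("gamma must be < 1 at every site")
    X = treated.events.astype(float)
    C = treated.coverage.astype(float)
    beta = np.full(len(X), np.nan)
    covered = C > 0
    if np.any(~covered):
        logger.warning(
            "%d treated site(s) with zero coverage flagged missing",
            int(np.sum(~covered)),
        )
    rate = X[covered] / C[covered]
    beta[covered] = (rate - gamma[covered]) / (1.0 - gamma[covered])
    n_clamped = int(np.nansum(beta < 0))
    if n_clamped:
        logger.info("clamped %d negative reactivity value(s) to 0", n_clamped)
    beta = np.where(beta < 0, 0.0, beta)
    return beta, n_clamped


def estimate_eta(
    beta: np.ndarray, informative_sites: tuple[int, ...] | None = None
) -> float:
    """Modification probability of an unconstrained site.

    Sorting the reactivities from high to low, eta-hat is the median of those
    strictly exceeding their mean — a robust stand-in for "the typical
    reactivity of a mostly-unpaired site".  For base-selective chemistries
    (DMS) pass ``informative_sites`` to restrict to assayable sites.

    Degenerate case: if no value strictly exceeds the mean (e.g. a constant
    vector) the rule is empty; we fall back to max(beta) with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    if informative_sites is not None:
        beta = beta[np.asarray(informative_sites, dtype=int) - 1]
    beta = beta[np.isfinite(beta)]
    if beta.size == 0 or np.all(beta <= 0):
        raise ReactivityError("no positive reactivities: cannot estimate eta")
    mean = beta.mean()
    high = beta[beta > mean]
    if high.size == 0:
        logger.warning("no reactivity strictly exceeds the mean; eta = max(beta)")
        return float(beta.max())
    return float(np.median(high))


def estimate_profile(
    treated: CountProfile,
    control: CountProfile | None = None,
    informative_sites: tuple[int, ...] | None = None,
) -> ReactivityProfile:
    """Convenience: gamma, beta and eta in one pass."""
    gamma = estimate_gamma(control, L=treated.L)
    beta, n_clamped = estimate_beta(treated, gamma)
    eta = estimate_eta(beta, informative_sites)
    return ReactivityProfile(
        beta=beta, gamma=gamma, eta=eta, mode=treated.mode, n_clamped=n_clamped
    )


def normalize_2_8(reactivities: np.ndarray) -> np.ndarray:
    """2-8% display normalization.

    The top 2% of values are set aside as outliers and every value is divided
    by the mean of the next 8%.  Display-only: never used inside the model.
    Counts round up (ceil), so the rule needs at least 13 values to be
    meaningful (1 outlier, ≥1 normalizer distinct from it).
    """
    v = np.asarray(reactivities, dtype=float)
    finite = np.isfinite(v)
    vals = v[finite]
    n = vals.size
    if n < 13:
        raise ReactivityError("2-8% normalization needs at least 13 values")
    if np.all(vals == 0):
        raise ReactivityError("all-zero reactivities cannot be normalized")
    order = np.sort(vals)[::-1]
    n_out = math.ceil(0.02 * n)
    n_norm = math.ceil(0.08 * n)
    denom = order[n_out : n_out + n_norm].mean()
    if denom <= 0:
        raise ReactivityError("2-8% normalizer window has zero mean")
    out = np.full_like(v, np.nan)
    out[finite] = vals / denom
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_reactivity_tsv(
    profile: ReactivityProfile, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Reactivity TSV in 5'->3' site order, plus a JSON sidecar with eta/mode."""
    L = profile.L
    df = pd.DataFrame(
        {
            "site": np.arange(1, L + 1),
            "beta": profile.beta[::-1],
            "gamma": profile.gamma[::-1],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if sidecar is None:
        sidecar = str(path) + ".json"
    Path(sidecar).write_text(
        json.dumps(
            {"eta": profile.eta, "mode": profile.mode, "n_clamped": profile.n_clamped},
            indent=2,
        )
    )
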