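"""Independent brute-force oracles for the generative read model.

These deliberately avoid the implementation's telescoping-product and
complement-product arithmetic: per-site event probabilities are formed by
inclusion-exclusion (eta + gamma - eta*gamma), and distributions are obtained
by enumerating all per-site event vectors rather than by closed form.
"""

from itertools import product

import numpy as np


def site_event_probs(state: np.ndarray, eta: float, gamma: np.ndarray) -> np.ndarray:
    """Probability of a detection event (modification or noise) per site:
    unconstrained sites by inclusion-exclusion of the two independent events,
    constrained sites by noise alone."""
    gamma = np.asarray(gamma, dtype=float)
    return np.where(
        np.asarray(state) == 0, eta + gamma - eta * gamma, gamma
    )


def truncation_distribution_oracle(
    state: np.ndarray, eta: float, gamma: np.ndarray
) -> np.ndarray:
    """Stop distribution over patterns (stop@1..L, complete) by enumerating
    every binary event vector; the read stops at the first event site."""
    L = len(state)
    p = site_event_probs(state, eta, gamma)
    out = np.zeros(L + 1)
    for events in product((0, 1), repeat=L):
        prob = 1.0
        for l in range(L):
            prob *= p[l] if events[l] else 1.0 - p[l]
        stop = next((l for l in range(L) if events[l]), None)
        out[stop if stop is not None else L] += prob
    return out


def mutation_pattern_prob_oracle(
    state: np.ndarray,
    eta: float,
    gamma: np.ndarray,
    informative_sites: tuple[int, ...],
    mutated: frozenset,
) -> float:
    """Probability of one mutation pattern as a product of independent
    per-site Bernoulli outcomes over the informative sites."""
    p = site_event_probs(state, eta, gamma)
    prob = 1.0
    for site in informative_sites:
        prob *= p[site - 1] if site in mutated else 1.0 - p[site - 1]
    return prob
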