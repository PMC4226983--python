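"""Independent brute-force oracles used by the test suite.

These deliberately avoid the recursions used by the package: the HMM
oracle sums over every template-pair path explicitly, and the maximal-r2
oracle scans a dense grid of admissible disequilibrium values.
"""

import numpy as np

from imputeval.sim import MISSING


def _pair_emission(m1, m2, g):
    """P(observed unphased genotype g | template allele-1 probs m1, m2)."""
    table = [
        (1 - m1) * (1 - m2),
        m1 * (1 - m2) + (1 - m1) * m2,
        m1 * m2,
    ]
    return table[g]


def enumerate_posteriors(ref_alleles, positions_morgan, observed, rho, error_rate):
    """Posterior genotype probabilities by explicit path summation.

    Enumerates all ``(H^2)^L`` ordered template-pair paths, accumulating
    each path's joint probability with the observations, then averages
    the per-state genotype distribution over paths.  Exponential in L —
    only for tiny instances.
    """
    ref = np.asarray(ref_alleles)
    H, L = ref.shape
    S = H * H
    e = error_rate
    m = ref * (1.0 - e) + (1 - ref) * e  # (H, L)

    i_idx, j_idx = np.divmod(np.arange(S), H)

    # emission vector per site over pair states
    E = np.ones((L, S))
    for l in range(L):
        g = int(observed[l])
        if g != MISSING:
            E[l] = _pair_emission(m[i_idx, l], m[j_idx, l], g)

    # per-chromosome transition, then the pair (Kronecker) kernel
    T_pair = []
    for l in range(L - 1):
        d = positions_morgan[l + 1] - positions_morgan[l]
        s = 1.0 - np.exp(-rho * d)
        t = (1.0 - s) * np.eye(H) + s / H
        T_pair.append(np.kron(t, t))

    probs = np.full(S, 1.0 / S) * E[0]
    last = np.arange(S)  # last state of each enumerated path prefix
    for l in range(1, L):
        n_prev = len(probs)
        probs = (probs[:, None] * T_pair[l - 1][last] * E[l][None, :]).ravel()
        last = np.tile(np.arange(S), n_prev)
    total = probs.sum()

    n = np.arange(S**L)
    post = np.zeros((L, 3))
    for l in range(L):
        digit = (n // S ** (L - 1 - l)) % S
        for g in range(3):
            pg = _pair_emission(m[i_idx, l], m[j_idx, l], g)
            post[l, g] = (probs * pg[digit]).sum() / total
    return post


def max_r2_grid(maf_a, maf_b, n_grid=20001):
    """Brute-force maximal r2 over a dense grid of admissible D."""
    p, q = maf_a, maf_b
    lo = -min(p * q, (1 - p) * (1 - q))
    hi = min(p * (1 - q), q * (1 - p))
    d = np.linspace(lo, hi, n_grid)
    r2 = d**2 / (p * (1 - p) * q * (1 - q))
    return float(r2.max())
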