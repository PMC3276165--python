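"""Independent brute-force oracles for the copying-HMM tests.

These enumerate every hidden-state path explicitly, so they are exact (up
to float rounding) and entirely independent of the dynamic-programming
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def path_prior(path: tuple[int, ...], K: int, p_switch: np.ndarray) -> float:
    pr = 1.0 / K
    for j in range(1, len(path)):
        p = p_switch[j - 1]
        pr *= (1.0 - p) * (path[j] == path[j - 1]) + p / K
    return pr


def haploid_posterior_enumeration(obs, H, p_switch, lam):
    """State marginals by summing over all K^S paths.

    obs entries in {0, 1, -1(missing)}; H is (S, K).
    """
    H = np.asarray(H)
    S, K = H.shape
    marg = np.zeros((S, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=S):
        pr = path_prior(path, K, p_switch)
        for j in range(S):
            if obs[j] >= 0:
                pr *= (1.0 - lam) if H[j, path[j]] == obs[j] else lam
        total += pr
        for j in range(S):
            marg[j, path[j]] += pr
    return marg / total


def allele_posterior_enumeration(obs, H, p_switch, lam):
    """P(true allele = 1) per site, by path enumeration."""
    gamma = haploid_posterior_enumeration(obs, H, p_switch, lam)
    e1 = lam + (1.0 - 2.0 * lam) * np.asarray(H, dtype=float)
    return (gamma * e1).sum(axis=1)


def diploid_config_posterior(genotypes, H, p_switch, lam):
    """Exact posterior over ordered allele configurations.

    Enumerates every ordered template-pair path and every allele
    configuration consistent with the genotypes.  Returns a dict mapping
    the tuple of haplotype-1 alleles (one entry per site) to its
    probability; haplotype 2 is determined by the genotype at non-missing
    sites and enumerated at missing ones (keyed by the full pair there).
    """
    H = np.asarray(H)
    S, K = H.shape

    def site_options(g):
        if g == 0:
            return [(0, 0)]
        if g == 2:
            return [(1, 1)]
        if g == 1:
            return [(1, 0), (0, 1)]
        return [(0, 0), (0, 1), (1, 0), (1, 1)]  # missing

    def emit(a, z, j):
        return (1.0 - lam) if H[j, z] == a else lam

    options = [site_options(g) for g in genotypes]
    post: dict[tuple, float] = {}
    total = 0.0
    for path1 in itertools.product(range(K), repeat=S):
        pr1 = path_prior(path1, K, p_switch)
        for path2 in itertools.product(range(K), repeat=S):
            pr12 = pr1 * path_prior(path2, K, p_switch)
            for config in itertools.product(*options):
                pr = pr12
                for j, (a1, a2) in enumerate(config):
                    pr *= emit(a1, path1[j], j) * emit(a2, path2[j], j)
                post[config] = post.get(config, 0.0) + pr
                total += pr
    return {c: p / total for c, p in post.items()}


def hudson_fst_per_snp(p1, p2, n1, n2):
    """Hudson F_ST numerator/denominator for one SNP (direct formula)."""
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den
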