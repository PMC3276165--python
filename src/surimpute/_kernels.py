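"""Numerical kernels for the copying HMM (numba-compiled).

All randomness is injected as precomputed uniform deviates so that results
are governed entirely by the caller's numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=False)
def _emission_haploid(hap_allele: np.uint8, obs: np.int8, lam: float) -> float:
    if obs < 0:
        return 1.0
    if hap_allele == obs:
        return 1.0 - lam
    return lam


@njit
def haploid_forward_backward(obs, templates, p_switch, lam):
    """Scaled forward-backward for one haploid chain.

    Parameters
    ----------
    obs : int8[S]        observed alleles, -1 for missing
    templates : uint8[S, K]
    p_switch : float64[S-1]   per-interval switch probability 1-exp(-rho/K)
    lam : float               per-site copying mismatch probability

    Returns
    -------
    gamma : float64[S, K]  posterior state marginals (rows sum to 1)
    loglik : float
    """
    S, K = templates.shape
    gamma = np.empty((S, K))
    fwd = np.empty((S, K))
    loglik = 0.0

    # forward
    c = 0.0
    for z in range(K):
        v = _emission_haploid(templates[0, z], obs[0], lam) / K
        fwd[0, z] = v
        c += v
    for z in range(K):
        fwd[0, z] /= c
    loglik += np.log(c)

    for j in range(1, S):
        p = p_switch[j - 1]
        q = p / K
        c = 0.0
        for z in range(K):
            v = _emission_haploid(templates[j, z], obs[j], lam) * (
                (1.0 - p) * fwd[j - 1, z] + q)
            fwd[j, z] = v
            c += v
        for z in range(K):
            fwd[j, z] /= c
        loglik += np.log(c)

    # backward, combined into gamma on the fly
    bwd = np.ones(K)
    s = 0.0
    for z in range(K):
        gamma[S - 1, z] = fwd[S - 1, z]
        s += gamma[S - 1, z]
    for z in range(K):
        gamma[S - 1, z] /= s

    for j in range(S - 2, -1, -1):
        p = p_switch[j]
        q = p / K
        tot = 0.0
        for z in range(K):
            e = _emission_haploid(templates[j + 1, z], obs[j + 1], lam)
            bwd[z] = e * bwd[z]
            tot += bwd[z]
        newb = np.empty(K)
        s = 0.0
        for z in range(K):
            newb[z] = (1.0 - p) * bwd[z] + q * tot
            s += newb[z]
        for z in range(K):
            bwd[z] = newb[z] / s
        s = 0.0
        for z in range(K):
            v = fwd[j, z] * bwd[z]
            gamma[j, z] = v
            s += v
        for z in range(K):
            gamma[j, z] /= s

    return gamma, loglik


@njit
def _diploid_emission(E, h_row, g, lam):
    """Fill E[K, K] with the diploid emission for genotype g at one site."""
    K = h_row.shape[0]
    if g < 0:
        for a in range(K):
            for b in range(K):
                E[a, b] = 1.0
        return
    for a in range(K):
        e1a = lam + (1.0 - 2.0 * lam) * h_row[a]
        for b in range(K):
            e1b = lam + (1.0 - 2.0 * lam) * h_row[b]
            if g == 0:
                E[a, b] = (1.0 - e1a) * (1.0 - e1b)
            elif g == 2:
                E[a, b] = e1a * e1b
            else:
                E[a, b] = e1a * (1.0 - e1b) + (1.0 - e1a) * e1b


@njit
def diploid_sample_path(genotypes, templates, p_switch, lam, u_path):
    """Forward filter / backward sample the ordered template-pair chain.

    Parameters
    ----------
    genotypes : int8[S]      unphased genotypes, -1 for missing
    templates : uint8[S, K]
    p_switch : float64[S-1]
    lam : float
    u_path : float64[S]      uniforms, one per site, for path sampling

    Returns
    -------
    path : int64[S, 2]  sampled template indices for the two chains
    """
    S, K = templates.shape
    F = np.empty((S, K, K))
    E = np.empty((K, K))
    h = np.empty(K)

    for z in range(K):
        h[z] = templates[0, z]
    _diploid_emission(E, h, genotypes[0], lam)
    c = 0.0
    for a in range(K):
        for b in range(K):
            F[0, a, b] = E[a, b]
            c += E[a, b]
    for a in range(K):
        for b in range(K):
            F[0, a, b] /= c

    row = np.empty(K)
    col = np.empty(K)
    for j in range(1, S):
        p = p_switch[j - 1]
        q = p / K
        for a in range(K):
            r = 0.0
            for b in range(K):
                r += F[j - 1, a, b]
            row[a] = r
        for b in range(K):
            r = 0.0
            for a in range(K):
                r += F[j - 1, a, b]
            col[b] = r
        for z in range(K):
            h[z] = templates[j, z]
        _diploid_emission(E, h, genotypes[j], lam)
        c = 0.0
        for a in range(K):
            for b in range(K):
                pred = ((1.0 - p) * (1.0 - p) * F[j - 1, a, b]
                        + (1.0 - p) * q * row[a]
                        + q * (1.0 - p) * col[b]
                        + q * q)
                v = E[a, b] * pred
                F[j, a, b] = v
                c += v
        for a in range(K):
            for b in range(K):
                F[j, a, b] /= c

    path = np.empty((S, 2), dtype=np.int64)

    # sample final state pair
    u = u_path[S - 1]
    acc = 0.0
    za, zb = K - 1, K - 1
    done = False
    for a in range(K):
        if done:
            break
        for b in range(K):
            acc += F[S - 1, a, b]
            if u <= acc:
                za, zb = a, b
                done = True
                break
    path[S - 1, 0] = za
    path[S - 1, 1] = zb

    W = np.empty((K, K))
    for j in range(S - 2, -1, -1):
        p = p_switch[j]
        q = p / K
        za = path[j + 1, 0]
        zb = path[j + 1, 1]
        tot = 0.0
        for a in range(K):
            ta = q + ((1.0 - p) if a == za else 0.0)
            for b in range(K):
                tb = q + ((1.0 - p) if b == zb else 0.0)
                w = F[j, a, b] * ta * tb
                W[a, b] = w
                tot += w
        u = u_path[j] * tot
        acc = 0.0
        wa, wb = K - 1, K - 1
        done = False
        for a in range(K):
            if done:
                break
            for b in range(K):
                acc += W[a, b]
                if u <= acc:
                    wa, wb = a, b
                    done = True
                    break
        path[j, 0] = wa
        path[j, 1] = wb

    return path


@njit
def assign_alleles(genotypes, templates, path, lam, u_alleles):
    """Draw the per-site allele pair consistent with genotype and path.

    u_alleles : float64[S, 2] uniforms (second column used at missing sites).
    Returns uint8[2, S] haplotype pair.
    """
    S = genotypes.shape[0]
    haps = np.empty((2, S), dtype=np.uint8)
    for j in range(S):
        g = genotypes[j]
        za = path[j, 0]
        zb = path[j, 1]
        e1a = lam + (1.0 - 2.0 * lam) * templates[j, za]
        e1b = lam + (1.0 - 2.0 * lam) * templates[j, zb]
        if g == 0:
            haps[0, j] = 0
            haps[1, j] = 0
        elif g == 2:
            haps[0, j] = 1
            haps[1, j] = 1
        elif g == 1:
            w10 = e1a * (1.0 - e1b)
            w01 = (1.0 - e1a) * e1b
            if u_alleles[j, 0] * (w10 + w01) <= w10:
                haps[0, j] = 1
                haps[1, j] = 0
            else:
                haps[0, j] = 0
                haps[1, j] = 1
        else:  # missing: alleles independent given states
            haps[0, j] = 1 if u_alleles[j, 0] <= e1a else 0
            haps[1, j] = 1 if u_alleles[j, 1] <= e1b else 0
    return haps
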