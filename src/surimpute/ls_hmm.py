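"""The Li & Stephens haplotype-copying HMM.

Study haplotypes are modelled as imperfect mosaics of K template haplotypes.
The hidden state at each SNP is the template being copied; between adjacent
SNPs the chain switches template with probability

    p_switch = 1 - exp(-rho / K),      rho = 4 * Ne * d,

where ``d`` is the genetic distance in Morgans between the SNPs and ``Ne``
is the effective population size.  Conditional on a switch the new template
is uniform on all K states, so the per-interval transition matrix is

    T = (1 - p_switch) * I + (p_switch / K) * J.

Emission allows a per-site copying error ("mismatch") with probability
``lambda``: the observed allele equals the template allele with probability
1 - lambda.  Missing observations emit 1 for every state, which is also how
untyped SNPs enter the model: they are included in the site grid as
missing-observation columns, so the forward-backward pass yields exact state
marginals (and hence allele posteriors) at every untyped position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .io_formats import GeneticMap, HaplotypePanel

__all__ = [
    "ModelParams",
    "TransitionSchedule",
    "CopyingPosterior",
    "watterson_mismatch",
    "build_transitions",
    "haploid_forward_backward",
    "allele_posterior",
    "impute_untyped",
    "diploid_sample_phase",
]


def watterson_mismatch(K: int) -> float:
    """Default copying-error rate lambda for K templates.

    Uses the Watterson-style convention lambda = theta / (2 (theta + K))
    with theta = 1 / sum_{i=1}^{K-1} 1/i, so the mismatch rate shrinks as
    more templates become available.
    """
    if K < 2:
        theta = 1.0
    else:
        theta = 1.0 / np.sum(1.0 / np.arange(1, K))
    return float(theta / (2.0 * (theta + K)))


@dataclass
class ModelParams:
    """Tuning parameters of the imputation MCMC.

    Attributes
    ----------
    Ne : effective population size; scales genetic distances into switch
        rates (20000 is a good universal value for human data).
    k : number of template haplotypes per phasing update.
    k_hap : number of Hamming-nearest reference haplotypes per haploid
        imputation update ("surrogate family" size).
    iterations, burnin : total MCMC sweeps and the number discarded.
    lambda_mismatch : per-site copying-error probability; when None it is
        derived from the active template count via :func:`watterson_mismatch`.
    seed : RNG seed for the whole run.
    """

    Ne: float = 20000.0
    k: int = 80
    k_hap: int = 500
    iterations: int = 30
    burnin: int = 10
    lambda_mismatch: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.k_hap < 1:
            raise ValueError("k_hap must be at least 1")
        if not (0 < self.burnin < self.iterations):
            raise ValueError("need 0 < burnin < iterations")
        if self.lambda_mismatch is not None and not (0 < self.lambda_mismatch < 0.5):
            raise ValueError("lambda_mismatch must lie in (0, 0.5)")

    def mismatch_rate(self, K: int) -> float:
        """Copying-error rate for an active template count K."""
        if self.lambda_mismatch is not None:
            return self.lambda_mismatch
        return watterson_mismatch(K)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class TransitionSchedule:
    """Per-interval scaled recombination parameters for a site grid."""

    rho: np.ndarray  # length n_sites - 1, rho_j = 4 Ne d_j
    K: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")
        if self.K < 1:
            raise ValueError("K must be positive")

    @property
    def p_switch(self) -> np.ndarray:
        return 1.0 - np.exp(-self.rho / self.K)

    def transition_matrix(self, interval: int) -> np.ndarray:
        """Dense K x K transition matrix for one interval (for small K)."""
        p = self.p_switch[interval]
        return (1.0 - p) * np.eye(self.K) + (p / self.K) * np.ones((self.K, self.K))


@dataclass
class CopyingPosterior:
    """Marginal copying-state posteriors gamma (sites x K)."""

    gamma: np.ndarray
    loglik: float = 0.0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        rowsum = self.gamma.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("gamma rows must sum to 1 within 1e-9")
        if np.any(self.gamma < -1e-15) or np.any(self.gamma > 1 + 1e-12):
            raise ValueError("gamma entries must lie in [0,1]")


def _as_template_matrix(templates) -> np.ndarray:
    if isinstance(templates, HaplotypePanel):
        return np.ascontiguousarray(templates.alleles, dtype=np.uint8)
    return np.ascontiguousarray(np.asarray(templates), dtype=np.uint8)


def build_transitions(gmap: GeneticMap, positions: Sequence[int], Ne: float,
                      K: int) -> TransitionSchedule:
    """Scaled recombination schedule for a grid of site positions.

    rho_j = 4 * Ne * d_j with d_j the interpolated genetic distance in
    Morgans between sites j and j+1 (linear interpolation of the map's
    cumulative cM, constant extrapolation beyond its ends).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    cm = gmap.cm_at(positions)
    d_morgans = np.diff(cm) / 100.0
    rho = 4.0 * Ne * d_morgans
    return TransitionSchedule(rho=rho, K=K)


def haploid_forward_backward(observed_hap, templates, schedule: TransitionSchedule,
                             params: ModelParams) -> CopyingPosterior:
    """Exact copying-state marginals for one haploid observation vector.

    ``observed_hap`` entries are 0/1 alleles or -1 (missing, emits 1 for all
    states).  O(S*K) using the single-switch-rate transition structure.
    """
    H = _as_template_matrix(templates)
    obs = np.ascontiguousarray(observed_hap, dtype=np.int8)
    S, K = H.shape
    if obs.shape[0] != S:
        raise ValueError("observation length does not match template sites")
    if schedule.K != K:
        raise ValueError("schedule K does not match template count")
    if schedule.rho.shape[0] != S - 1:
        raise ValueError("schedule length does not match site count")
    lam = params.mismatch_rate(K)
    gamma, loglik = _kernels.haploid_forward_backward(
        obs, H, schedule.p_switch, lam)
    if not np.all(np.isfinite(gamma)):
        raise FloatingPointError("forward-backward produced non-finite values")
    return CopyingPosterior(gamma=gamma, loglik=float(loglik))


def allele_posterior(gamma: np.ndarray, templates, lam: float) -> np.ndarray:
    """P(allele 1) per site given state posteriors and template alleles."""
    H = _as_template_matrix(templates).astype(np.float64)
    e1 = lam + (1.0 - 2.0 * lam) * H  # P(true allele 1 | state)
    return np.einsum("sk,sk->s", np.asarray(gamma), e1)


def impute_untyped(observed_typed, templates_full, typed_index,
                   gmap: GeneticMap, params: ModelParams,
                   K: int | None = None) -> np.ndarray:
    """Analytic haploid imputation at untyped SNPs.

    Parameters
    ----------
    observed_typed : 0/1/-1 vector over the typed sites only.
    templates_full : HaplotypePanel or matrix over ALL sites (typed and
        untyped) in the active region, in position order.
    typed_index : indices of the typed sites within the full site grid.
    gmap, params : genetic map and model parameters.

    Returns
    -------
    P(allele 1) at every site of the full grid (in [0,1]); slice with the
    untyped indices for the imputed alleles.  Untyped SNPs enter the
    forward-backward pass as missing-observation columns, so the result is
    exact within the model.
    """
    if isinstance(templates_full, HaplotypePanel):
        positions = templates_full.positions
    else:
        raise TypeError("templates_full must be a HaplotypePanel "
                        "(site positions are required)")
    H = _as_template_matrix(templates_full)
    S, Kact = H.shape
    typed_index = np.asarray(typed_index, dtype=np.int64)
    obs = np.full(S, -1, dtype=np.int8)
    obs[typed_index] = np.asarray(observed_typed, dtype=np.int8)
    schedule = build_transitions(gmap, positions, params.Ne, Kact)
    lam = params.mismatch_rate(Kact if K is None else K)
    gamma, _ = _kernels.haploid_forward_backward(obs, H, schedule.p_switch, lam)
    p1 = allele_posterior(gamma, H, lam)
    return np.clip(p1, 0.0, 1.0)


def diploid_sample_phase(genotypes, templates, schedule: TransitionSchedule,
                         params: ModelParams, rng: np.random.Generator
                         ) -> np.ndarray:
    """Sample a phase configuration for one individual at typed SNPs.

    Forward filtering over the template-pair state space followed by
    backward sampling of a state-pair path; per-site alleles are then drawn
    from the emission-consistent assignment posterior.  The returned (2, S)
    haplotype pair is genotype-consistent at every non-missing site.
    """
    H = _as_template_matrix(templates)
    g = np.ascontiguousarray(genotypes, dtype=np.int8)
    S, K = H.shape
    if g.shape[0] != S:
        raise ValueError("genotype length does not match template sites")
    if schedule.K != K:
        raise ValueError("schedule K does not match template count")
    lam = params.mismatch_rate(K)
    u_path = rng.random(S)
    u_alleles = rng.random((S, 2))
    path = _kernels.diploid_sample_path(g, H, schedule.p_switch, lam, u_path)
    return _kernels.assign_alleles(g, H, path, lam, u_alleles)
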