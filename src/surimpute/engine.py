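"""The imputation engine.

The model alternates two Gibbs-style steps over a number of MCMC sweeps:

1. *Phasing.*  Each study individual samples a new haplotype pair at the
   typed SNPs, conditional on k template haplotypes drawn (by local Hamming
   distance) from the other study individuals' current haplotypes plus the
   reference panel.
2. *Haploid imputation.*  Each newly sampled haplotype is treated as
   independent given the reference panel: its k_hap Hamming-nearest
   reference haplotypes form a custom template panel, and the copying HMM
   analytically yields P(allele 1) at every untyped SNP.  The two
   haplotypes' allele probabilities combine under conditional independence
   into a genotype triple.

Triples from post-burn-in sweeps are averaged with equal weight.  Analysis
regions are split into non-overlapping chunks (default 5 Mb) with a buffer
(default 250 kb) on each side; only core-interval results are reported,
which absorbs HMM edge effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .io_formats import (GeneticMap, GenotypeMatrix, HaplotypePanel, MISSING,
                         VariantSite, match_sites, write_gen)
from .ls_hmm import ModelParams, TransitionSchedule, allele_posterior, build_transitions
from .surrogate import (candidate_pool, hamming_distances, phasing_candidates,
                        select_from_distances)

__all__ = [
    "Chunk",
    "ImputationResult",
    "make_chunks",
    "stitch",
    "initialize_phase",
    "run_mcmc",
    "Imputer",
    "ImputationResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chunk:
    """A core analysis interval [start, end) plus its buffered extent."""

    core_start: int
    core_end: int
    buffer_start: int
    buffer_end: int

    def __post_init__(self) -> None:
        if self.core_end <= self.core_start:
            raise ValueError("core interval must be non-empty")
        if self.buffer_start > self.core_start or self.buffer_end < self.core_end:
            raise ValueError("buffer must contain the core interval")

    def core_contains(self, position: int) -> bool:
        return self.core_start <= position < self.core_end


def make_chunks(region: tuple[int, int], chunk_size: int = 5_000_000,
                buffer: int = 250_000) -> list[Chunk]:
    """Tile [start, end) with non-overlapping cores plus clipped buffers."""
    start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")
    if chunk_size <= 0 or buffer < 0:
        raise ValueError("chunk_size must be positive and buffer non-negative")
    chunks = []
    lo = start
    while lo < end:
        hi = min(lo + chunk_size, end)
        chunks.append(Chunk(core_start=lo, core_end=hi,
                            buffer_start=max(start, lo - buffer),
                            buffer_end=min(end, hi + buffer)))
        lo = hi
    return chunks


@dataclass
class ImputationResult:
    """Posterior genotype summaries for one analysis region or chunk.

    ``triples`` covers the untyped SNPs: per site and individual the
    averaged P(G=0), P(G=1), P(G=2).  ``typed_haplotypes`` is the final
    sweep's sampled phase at the typed SNPs.  Typed SNPs at which an
    individual's input genotype was missing are imputed too and reported
    separately in ``typed_missing_triples`` (NaN wherever the genotype was
    observed).
    """

    untyped_sites: list[VariantSite]
    triples: np.ndarray  # (U, N, 3)
    typed_sites: list[VariantSite]
    typed_haplotypes: np.ndarray  # (T, 2N) uint8
    typed_missing_triples: np.ndarray  # (T, N, 3), NaN where observed
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=np.float64)
        if self.triples.size:
            sums = self.triples.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("genotype triples must sum to 1 within 1e-6")

    @property
    def dosages(self) -> np.ndarray:
        """Posterior mean genotype per untyped site and individual, in [0,2]."""
        return self.triples[:, :, 1] + 2.0 * self.triples[:, :, 2]

    @property
    def untyped_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.untyped_sites], dtype=np.int64)


def stitch(chunk_results: list[ImputationResult], chunks: list[Chunk]
           ) -> ImputationResult:
    """Merge per-chunk results, keeping each site from its core chunk."""
    if len(chunk_results) != len(chunks):
        raise ValueError("one result required per chunk")
    u_sites: list[VariantSite] = []
    u_triples: list[np.ndarray] = []
    t_sites: list[VariantSite] = []
    t_haps: list[np.ndarray] = []
    t_miss: list[np.ndarray] = []
    ids: list[str] = []
    for res, chunk in zip(chunk_results, chunks):
        if res is None:
            continue
        ids = res.individual_ids
        keep_u = [i for i, s in enumerate(res.untyped_sites)
                  if chunk.core_contains(s.position)]
        u_sites.extend(res.untyped_sites[i] for i in keep_u)
        u_triples.append(res.triples[keep_u])
        keep_t = [i for i, s in enumerate(res.typed_sites)
                  if chunk.core_contains(s.position)]
        t_sites.extend(res.typed_sites[i] for i in keep_t)
        t_haps.append(res.typed_haplotypes[keep_t])
        t_miss.append(res.typed_missing_triples[keep_t])
    n = len(ids)
    return ImputationResult(
        untyped_sites=u_sites,
        triples=(np.concatenate(u_triples) if u_triples
                 else np.zeros((0, n, 3))),
        typed_sites=t_sites,
        typed_haplotypes=(np.concatenate(t_haps) if t_haps
                          else np.zeros((0, 2 * n), dtype=np.uint8)),
        typed_missing_triples=(np.concatenate(t_miss) if t_miss
                               else np.zeros((0, n, 3))),
        individual_ids=ids,
    )


def initialize_phase(genotypes: np.ndarray, rng: np.random.Generator,
                     allele_freq: np.ndarray | None = None) -> np.ndarray:
    """Random genotype-consistent starting haplotypes.

    Heterozygous sites are phased by a fair coin; missing sites draw both
    alleles independently from the site allele frequency (0.5 when no
    frequency is supplied).

    Parameters
    ----------
    genotypes : (sites x individuals) array in {0,1,2,MISSING}.

    Returns
    -------
    (sites x 2*individuals) uint8 matrix; columns 2i, 2i+1 belong to
    individual i.
    """
    G = np.asarray(genotypes)
    S, N = G.shape
    freq = np.full(S, 0.5) if allele_freq is None else np.asarray(allele_freq)
    haps = np.zeros((S, 2 * N), dtype=np.uint8)
    for i in range(N):
        g = G[:, i]
        h0 = np.zeros(S, dtype=np.uint8)
        h1 = np.zeros(S, dtype=np.uint8)
        hom2 = g == 2
        h0[hom2] = 1
        h1[hom2] = 1
        het = g == 1
        coin = rng.random(int(het.sum())) < 0.5
        h0[het] = coin
        h1[het] = ~coin
        miss = g == MISSING
        nm = int(miss.sum())
        if nm:
            h0[miss] = rng.random(nm) < freq[miss]
            h1[miss] = rng.random(nm) < freq[miss]
        haps[:, 2 * i] = h0
        haps[:, 2 * i + 1] = h1
    return haps


def _combine_haploid(p1a: np.ndarray, p1b: np.ndarray) -> np.ndarray:
    """Genotype triple from two independent haploid allele-1 probabilities."""
    out = np.empty(p1a.shape + (3,))
    out[..., 0] = (1.0 - p1a) * (1.0 - p1b)
    out[..., 1] = p1a * (1.0 - p1b) + (1.0 - p1a) * p1b
    out[..., 2] = p1a * p1b
    return out


def run_mcmc(study: GenotypeMatrix, reference: HaplotypePanel,
             gmap: GeneticMap, params: ModelParams, chunk: Chunk,
             rng: np.random.Generator | None = None
             ) -> ImputationResult | None:
    """Run the two-step MCMC on one buffered chunk.

    Returns None (with a warning) when the chunk contains no typed SNP
    shared between study and reference.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)

    ref_pos = reference.positions
    in_chunk = (ref_pos >= chunk.buffer_start) & (ref_pos < chunk.buffer_end)
    ref_c = reference.subset_sites(in_chunk)
    st_pos = study.positions
    st_in = (st_pos >= chunk.buffer_start) & (st_pos < chunk.buffer_end)
    st_c = study.subset_sites(st_in)

    ref_idx, st_idx, flip = match_sites(ref_c, st_c)
    if ref_idx.size == 0:
        logger.warning("chunk [%d,%d): no typed SNPs shared with the "
                       "reference; skipped", chunk.core_start, chunk.core_end)
        return None

    S_full = ref_c.n_sites
    typed_index = ref_idx  # positions of typed SNPs in the full ref grid
    untyped_mask = np.ones(S_full, dtype=bool)
    untyped_mask[typed_index] = False
    untyped_index = np.flatnonzero(untyped_mask)

    # study genotypes aligned to the reference allele coding
    G = st_c.genotypes[st_idx].copy()
    for col in range(G.shape[1]):
        obs = G[:, col] != MISSING
        swap = flip & obs
        G[swap, col] = 2 - G[swap, col]
    N = G.shape[1]
    T = typed_index.size

    ref_full = np.ascontiguousarray(ref_c.alleles, dtype=np.uint8)
    ref_typed = np.ascontiguousarray(ref_full[typed_index])
    n_ref = ref_typed.shape[1]

    k_hap_eff = min(params.k_hap, n_ref)
    if k_hap_eff < params.k_hap:
        logger.warning("k_hap reduced to the %d available reference haplotypes",
                       n_ref)

    typed_positions = ref_c.positions[typed_index]
    rho_typed = build_transitions(gmap, typed_positions, params.Ne, 1).rho
    rho_full = build_transitions(gmap, ref_c.positions, params.Ne, 1).rho

    freq = ref_typed.mean(axis=1)
    cur_haps = initialize_phase(G, rng, allele_freq=freq)

    accum = np.zeros((S_full, N, 3))
    n_avg = params.iterations - params.burnin
    lam_full = params.mismatch_rate(k_hap_eff)
    p_switch_full = 1.0 - np.exp(-rho_full / k_hap_eff)

    for it in range(1, params.iterations + 1):
        for i in range(N):
            # Step 1: sample a new phase configuration at typed SNPs
            g_i = np.ascontiguousarray(G[:, i], dtype=np.int8)
            sel = phasing_candidates(i, cur_haps, ref_typed, params.k, rng)
            pool = candidate_pool(i, cur_haps, ref_typed)
            templates = np.ascontiguousarray(pool[:, sel.indices])
            K = templates.shape[1]
            sched = TransitionSchedule(rho=rho_typed, K=K)
            lam = params.mismatch_rate(K)
            u_path = rng.random(T)
            u_all = rng.random((T, 2))
            path = _kernels.diploid_sample_path(
                g_i, templates, sched.p_switch, lam, u_path)
            pair = _kernels.assign_alleles(g_i, templates, path, lam, u_all)
            cur_haps[:, 2 * i] = pair[0]
            cur_haps[:, 2 * i + 1] = pair[1]

            # Step 2: custom-panel haploid imputation for each new haplotype
            if it <= params.burnin:
                continue
            obs_missing = g_i == MISSING
            p1 = np.empty((2, S_full))
            for h in (0, 1):
                hap = cur_haps[:, 2 * i + h]
                d = hamming_distances(hap, ref_typed)
                sel_h = select_from_distances(d, k_hap_eff, rng)
                templates_full = np.ascontiguousarray(ref_full[:, sel_h.indices])
                obs = np.full(S_full, -1, dtype=np.int8)
                obs[typed_index] = hap
                # typed SNPs with a missing input genotype are imputed for
                # this individual: mask the sampled allele there
                obs[typed_index[obs_missing]] = -1
                gamma, _ = _kernels.haploid_forward_backward(
                    obs, templates_full, p_switch_full, lam_full)
                p1[h] = np.clip(
                    allele_posterior(gamma, templates_full, lam_full), 0.0, 1.0)
            accum[:, i, :] += _combine_haploid(p1[0], p1[1])

    triples_full = accum / n_avg
    typed_missing = np.full((T, N, 3), np.nan)
    miss_mask = G == MISSING
    typed_triples = triples_full[typed_index]
    typed_missing[miss_mask] = typed_triples[miss_mask]

    return ImputationResult(
        untyped_sites=[ref_c.sites[i] for i in untyped_index],
        triples=triples_full[untyped_index],
        typed_sites=[ref_c.sites[i] for i in typed_index],
        typed_haplotypes=cur_haps,
        typed_missing_triples=typed_missing,
        individual_ids=list(st_c.individual_ids),
    )


class Imputer:
    """Genotype-imputation model for one genomic region.

    Built from unphased study genotypes, a phased reference panel and
    (optionally) a genetic map; :meth:`fit` runs the MCMC over buffered
    chunks and returns an :class:`ImputationResults` object.

    Parameters
    ----------
    study : GenotypeMatrix
        Unphased genotypes at the typed SNPs.
    reference : HaplotypePanel
        Phased reference haplotypes at all SNPs (typed and untyped).
    genetic_map : GeneticMap, optional
        bp -> cM map; when omitted a constant 1 cM/Mb map over the region
        is used (and logged).
    params : ModelParams, optional
    region : (start, end) in bp, optional; defaults to the reference span.
    chunk_size, buffer : chunking geometry in bp.
    """

    def __init__(self, study: GenotypeMatrix, reference: HaplotypePanel,
                 genetic_map: GeneticMap | None = None,
                 params: ModelParams | None = None,
                 region: tuple[int, int] | None = None,
                 chunk_size: int = 5_000_000, buffer: int = 250_000) -> None:
        self.study = study
        self.reference = reference
        self.params = params or ModelParams()
        if region is None:
            pos = reference.positions
            region = (int(pos.min()), int(pos.max()) + 1)
        self.region = region
        self.chunk_size = chunk_size
        self.buffer = buffer
        if genetic_map is None:
            genetic_map = GeneticMap.constant_rate(region[0], region[1], 1.0)
            logger.info("no genetic map supplied; using a constant 1 cM/Mb map")
        self.genetic_map = genetic_map

    @classmethod
    def from_files(cls, gen_path, sample_path, hap_path, legend_path,
                   map_path=None, **kwargs) -> "Imputer":
        """Build the model from IMPUTE-style input files."""
        from .io_formats import (read_gen, read_genetic_map, read_hap_legend,
                                 read_sample)
        study, _ = read_gen(gen_path)
        if sample_path is not None:
            study.individual_ids = read_sample(sample_path)
            if len(study.individual_ids) != study.n_individuals:
                raise ValueError("sample file does not match .gen individuals")
        reference = read_hap_legend(hap_path, legend_path)
        gmap = read_genetic_map(map_path) if map_path else None
        return cls(study, reference, genetic_map=gmap, **kwargs)

    def fit(self, seed: int | None = None) -> "ImputationResults":
        """Run the MCMC over all chunks and stitch core results."""
        if seed is None:
            seed = self.params.seed
        chunks = make_chunks(self.region, self.chunk_size, self.buffer)
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(chunks))
        results = []
        for chunk, child in zip(chunks, children):
            rng = np.random.default_rng(child)
            res = run_mcmc(self.study, self.reference, self.genetic_map,
                           self.params, chunk, rng)
            results.append(res)
            if res is not None:
                logger.info("chunk [%d,%d): %d typed, %d untyped SNPs",
                            chunk.core_start, chunk.core_end,
                            len(res.typed_sites), len(res.untyped_sites))
        kept = [(r, c) for r, c in zip(results, chunks)]
        stitched = stitch([r for r, _ in kept], [c for _, c in kept])
        return ImputationResults(self, stitched, chunks, seed)


class ImputationResults:
    """Fitted imputation results: posterior triples, dosages, phased haps."""

    def __init__(self, model: Imputer, result: ImputationResult,
                 chunks: list[Chunk], seed: int | None) -> None:
        self.model = model
        self._result = result
        self.chunks = chunks
        self.seed = seed

    # -- pass-through views -------------------------------------------------
    @property
    def untyped_sites(self) -> list[VariantSite]:
        return self._result.untyped_sites

    @property
    def typed_sites(self) -> list[VariantSite]:
        return self._result.typed_sites

    @property
    def triples(self) -> np.ndarray:
        return self._result.triples

    @property
    def dosages(self) -> np.ndarray:
        return self._result.dosages

    @property
    def typed_haplotypes(self) -> np.ndarray:
        return self._result.typed_haplotypes

    @property
    def typed_missing_triples(self) -> np.ndarray:
        return self._result.typed_missing_triples

    @property
    def individual_ids(self) -> list[str]:
        return self._result.individual_ids

    # -- summaries ----------------------------------------------------------
    def info_table(self) -> pd.DataFrame:
        """Per-untyped-SNP summary: MAF, mean dosage and certainty.

        MAF is the estimated minor-allele frequency from the dosages;
        certainty is the mean (over individuals) of the highest genotype
        probability.
        """
        d = self.dosages
        tri = self.triples
        freq = d.mean(axis=1) / 2.0 if d.size else np.zeros(0)
        maf = np.minimum(freq, 1.0 - freq)
        certainty = tri.max(axis=2).mean(axis=1) if tri.size else np.zeros(0)
        return pd.DataFrame({
            "id": [s.id for s in self.untyped_sites],
            "position": [s.position for s in self.untyped_sites],
            "maf": maf,
            "mean_dosage": d.mean(axis=1) if d.size else np.zeros(0),
            "certainty": certainty,
        })

    def summary(self) -> str:
        p = self.model.params
        info = self.info_table()
        lines = [
            "Imputation results",
            "==================",
            f"individuals:        {len(self.individual_ids)}",
            f"typed SNPs:         {len(self.typed_sites)}",
            f"imputed SNPs:       {len(self.untyped_sites)}",
            f"chunks:             {len(self.chunks)} "
            f"(size {self.model.chunk_size} bp, buffer {self.model.buffer} bp)",
            f"Ne={p.Ne:g}  k={p.k}  k_hap={p.k_hap}  "
            f"iterations={p.iterations}  burnin={p.burnin}",
            f"seed:               {self.seed}",
        ]
        if len(info):
            lines.append(f"mean certainty:     {info['certainty'].mean():.4f}")
            lines.append(f"mean imputed MAF:   {info['maf'].mean():.4f}")
        return "\n".join(lines)

    def write(self, prefix: str) -> None:
        """Write ``<prefix>.gen`` posterior triples and ``<prefix>.info`` TSV."""
        write_gen(f"{prefix}.gen", self.untyped_sites, self.triples)
        self.info_table().to_csv(f"{prefix}.info", sep="\t", index=False,
                                 float_format="%.6f")
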