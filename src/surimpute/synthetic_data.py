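"""Synthetic multi-population haplotype panels for testing and benchmarks.

The generator produces the structure the imputation model exploits without
a full forward or coalescent simulation:

* ancestral allele frequencies are drawn from a symmetric Beta (U-shaped,
  mimicking a site-frequency spectrum rich in low-frequency variants);
* a shared pool of ancestral founder haplotypes is drawn from those
  frequencies; each population perturbs the pool by resampling founder
  alleles from a Balding-Nichols frequency draw at a rate equal to its
  drift parameter ("split depth"), so F_ST between populations grows with
  the split depths while haplotype backbones remain shared in proportion
  to 1 - F — the cross-population allele sharing that lets a cosmopolitan
  reference panel help at low-frequency variants;
* haplotypes within a population are imperfect mosaics of its founder
  pool, giving realistic local haplotype sharing and LD decay with
  distance.

Two ascertainment schemes mirror how real typed-SNP sets arise: MAF-biased
thinning to a target density (SNP arrays) and allele-count-dependent
discovery probabilities applied independently per SNP per population
(low-coverage sequencing), with a discovered-anywhere union rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneticMap, GenotypeMatrix, HaplotypePanel, VariantSite

__all__ = [
    "SimConfig",
    "DiscoveryModel",
    "SimulatedPanels",
    "simulate_panels",
    "ascertain_array",
    "ascertain_discovery",
    "make_study",
    "SimulatedDataset",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Synthetic-panel generator settings.

    Defaults describe a desk-scale three-population panel: 200 haplotypes
    per population over 2 Mb at ~5 SNPs/kb before ascertainment, with
    nested split depths so the populations have a clear divergence order.
    """

    n_populations: int = 3
    haplotypes_per_population: int = 200
    region_length: int = 2_000_000
    snps_per_kb: float = 5.0
    split_depths: tuple[float, ...] = (0.01, 0.05, 0.15)
    recombination_rate: float = 1.0  # cM/Mb
    mosaic_switch_rate: float = 1e-5  # per bp (expected segment ~100 kb)
    mosaic_mismatch_rate: float = 0.002  # per site
    n_founders: int = 20
    ancestral_beta_shape: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.haplotypes_per_population < 1:
            raise ValueError("population counts must be positive")
        if self.region_length < 1 or self.snps_per_kb <= 0:
            raise ValueError("region and SNP density must be positive")
        if len(self.split_depths) < self.n_populations:
            raise ValueError("need one split depth per population")
        if any(f < 0 or f >= 1 for f in self.split_depths):
            raise ValueError("split depths must lie in [0, 1)")
        if (self.mosaic_switch_rate < 0 or self.mosaic_mismatch_rate < 0
                or self.recombination_rate < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class DiscoveryModel:
    """Discovery probability as a function of variant-allele count.

    ``probabilities[c]`` is the chance that a SNP with c copies of the
    variant allele in a population sample is discovered there; counts
    beyond the table use the last entry.  Probabilities must be
    non-decreasing in the count and zero at count 0.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        p = self.probabilities
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probabilities must be a 1-D array")
        if p[0] != 0.0:
            raise ValueError("discovery probability at count 0 must be 0")
        if np.any(np.diff(p) < 0):
            raise ValueError("discovery probability must be non-decreasing")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def step(cls, min_count: int, p: float = 1.0) -> "DiscoveryModel":
        """Discover with probability p iff the count reaches min_count."""
        probs = np.zeros(min_count + 1)
        probs[min_count] = p
        return cls(probs)

    @classmethod
    def from_mapping(cls, mapping: dict[int, float]) -> "DiscoveryModel":
        top = max(mapping)
        probs = np.zeros(top + 1)
        last = 0.0
        for c in range(top + 1):
            last = mapping.get(c, last)
            probs[c] = last
        return cls(probs)

    def __call__(self, counts) -> np.ndarray:
        c = np.minimum(np.asarray(counts, dtype=np.int64),
                       self.probabilities.size - 1)
        return self.probabilities[c]


@dataclass
class SimulatedPanels:
    """Per-population haplotype panels plus generator truth."""

    panels: dict[str, HaplotypePanel]
    ancestral_freq: np.ndarray
    population_freq: dict[str, np.ndarray]
    founders: dict[str, np.ndarray]
    gmap: GeneticMap
    config: SimConfig

    @property
    def sites(self) -> list[VariantSite]:
        return next(iter(self.panels.values())).sites

    def combined(self, names: list[str] | None = None) -> HaplotypePanel:
        """Cosmopolitan panel concatenating the named populations."""
        names = names or list(self.panels)
        alleles = np.concatenate([self.panels[n].alleles for n in names], axis=1)
        ids = [f"{n}:{h}" for n in names for h in self.panels[n].haplotype_ids]
        return HaplotypePanel(sites=list(self.sites), alleles=alleles,
                              haplotype_ids=ids)


def _mosaic_haplotypes(founders: np.ndarray, n_haps: int, positions: np.ndarray,
                       switch_rate: float, mismatch_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Imperfect-mosaic haplotypes copied from founder haplotypes."""
    n_sites, n_founders = founders.shape
    p_int = 1.0 - np.exp(-switch_rate * np.diff(positions))
    out = np.empty((n_sites, n_haps), dtype=np.uint8)
    for h in range(n_haps):
        switches = np.empty(n_sites, dtype=bool)
        switches[0] = True
        switches[1:] = rng.random(n_sites - 1) < p_int
        seg = np.cumsum(switches) - 1
        seg_founder = rng.integers(0, n_founders, size=seg[-1] + 1)
        hap = founders[np.arange(n_sites), seg_founder[seg]]
        if mismatch_rate > 0:
            flips = rng.random(n_sites) < mismatch_rate
            hap = hap ^ flips
        out[:, h] = hap
    return out


def simulate_panels(config: SimConfig,
                    rng: np.random.Generator | None = None) -> SimulatedPanels:
    """Generate one haplotype panel per population on a shared site grid."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sites = max(2, round(config.region_length / 1000 * config.snps_per_kb))
    positions = np.sort(rng.choice(
        np.arange(1, config.region_length + 1), size=n_sites, replace=False))
    a = config.ancestral_beta_shape
    p_anc = rng.beta(a, a, size=n_sites)
    p_anc = np.clip(p_anc, 1e-4, 1 - 1e-4)

    sites = [VariantSite(f"snp{j}", int(positions[j]), "A", "G")
             for j in range(n_sites)]
    anc_founders = (rng.random((n_sites, config.n_founders))
                    < p_anc[:, None]).astype(np.uint8)
    panels: dict[str, HaplotypePanel] = {}
    pop_freq: dict[str, np.ndarray] = {}
    pop_founders: dict[str, np.ndarray] = {}
    for i in range(config.n_populations):
        name = f"pop{i}"
        F = config.split_depths[i]
        if F == 0:
            p_pop = p_anc.copy()
            founders = anc_founders
        else:
            scale = (1.0 - F) / F
            p_pop = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
            # drift acts on the shared founder pool: each founder allele is
            # resampled from the population frequency with probability F
            resample = rng.random((n_sites, config.n_founders)) < F
            novel = (rng.random((n_sites, config.n_founders))
                     < p_pop[:, None]).astype(np.uint8)
            founders = np.where(resample, novel, anc_founders).astype(np.uint8)
        alleles = _mosaic_haplotypes(
            founders, config.haplotypes_per_population, positions,
            config.mosaic_switch_rate, config.mosaic_mismatch_rate, rng)
        panels[name] = HaplotypePanel(
            sites=list(sites), alleles=alleles,
            haplotype_ids=[f"{name}_h{h}"
                           for h in range(config.haplotypes_per_population)])
        pop_freq[name] = p_pop
        pop_founders[name] = founders

    gmap = GeneticMap.constant_rate(1, config.region_length,
                                    config.recombination_rate)
    return SimulatedPanels(panels=panels, ancestral_freq=p_anc,
                           population_freq=pop_freq, founders=pop_founders,
                           gmap=gmap, config=config)


def ascertain_array(panel: HaplotypePanel, target_density: float,
                    maf_floor: float, rng: np.random.Generator,
                    flat_weights: bool = False) -> np.ndarray:
    """SNP-array-like thinning: MAF-weighted sampling to a target density.

    Returns the sorted indices of the selected ("typed") sites.  Sampling
    is without replacement with weight proportional to MAF (or uniform
    with ``flat_weights``), restricted to sites with MAF >= ``maf_floor``.
    """
    maf = panel.minor_allele_frequencies()
    eligible = np.flatnonzero((maf >= maf_floor) & (maf > 0))
    if eligible.size == 0:
        raise ValueError("no site passes the MAF floor")
    span_kb = (panel.positions.max() - panel.positions.min() + 1) / 1000.0
    n_target = max(1, round(target_density * span_kb))
    if n_target >= eligible.size:
        return eligible
    if flat_weights:
        w = None
    else:
        w = maf[eligible]
        w = w / w.sum()
    chosen = rng.choice(eligible, size=n_target, replace=False, p=w)
    return np.sort(chosen)


def ascertain_discovery(panels: HaplotypePanel | dict[str, HaplotypePanel],
                        model: DiscoveryModel,
                        rng: np.random.Generator) -> np.ndarray:
    """Low-coverage discovery ascertainment across one or more panels.

    In each panel, every SNP is discovered independently with the model's
    probability at that panel's variant (minor) allele count; the retained
    set is the union over panels, and retained SNPs keep all panels'
    genotypes.  Returns sorted indices of retained sites.
    """
    if isinstance(panels, HaplotypePanel):
        panels = {"panel": panels}
    n_sites = next(iter(panels.values())).n_sites
    discovered = np.zeros(n_sites, dtype=bool)
    for panel in panels.values():
        if panel.n_sites != n_sites:
            raise ValueError("panels must share a site grid")
        count1 = panel.alleles.sum(axis=1)
        counts = np.minimum(count1, panel.n_haplotypes - count1)
        probs = model(counts)
        discovered |= rng.random(n_sites) < probs
    return np.flatnonzero(discovered)


def make_study(panel: HaplotypePanel, n_individuals: int, typed_sites,
               rng: np.random.Generator
               ) -> tuple[GenotypeMatrix, HaplotypePanel]:
    """Pair haplotypes into unphased study individuals at typed sites.

    Haplotypes are drawn and paired uniformly at random without
    replacement; genotypes are the allele sums at the typed sites.  The
    paired truth haplotypes (at all sites) are returned for evaluation.
    """
    if 2 * n_individuals > panel.n_haplotypes:
        raise ValueError(
            f"need {2 * n_individuals} haplotypes, panel has {panel.n_haplotypes}")
    typed_sites = np.asarray(typed_sites)
    if typed_sites.dtype == bool:
        typed_sites = np.flatnonzero(typed_sites)
    cols = rng.choice(panel.n_haplotypes, size=2 * n_individuals, replace=False)
    truth = panel.subset_haplotypes(cols)
    geno = (truth.alleles[typed_sites, 0::2]
            + truth.alleles[typed_sites, 1::2]).astype(np.int8)
    study = GenotypeMatrix(
        sites=[panel.sites[i] for i in typed_sites], genotypes=geno,
        individual_ids=[f"study{i}" for i in range(n_individuals)])
    return study, truth


@dataclass
class SimulatedDataset:
    """A ready-to-impute experiment: reference, study, truth, map."""

    sim: SimulatedPanels
    reference: HaplotypePanel
    reference_labels: list[str]
    study: GenotypeMatrix
    truth: HaplotypePanel
    typed_index: np.ndarray
    untyped_index: np.ndarray
    gmap: GeneticMap

    def truth_genotypes(self, site_index) -> np.ndarray:
        """True genotypes of the study individuals at the given sites."""
        idx = np.asarray(site_index)
        return (self.truth.alleles[idx, 0::2]
                + self.truth.alleles[idx, 1::2]).astype(np.int8)


def simulate_dataset(config: SimConfig | None = None,
                     n_study: int = 25,
                     typed_density: float = 0.15,
                     typed_maf_floor: float = 0.05,
                     study_population: str = "pop0",
                     seed: int | None = None) -> SimulatedDataset:
    """Simulate panels and carve out a study sample plus typed-SNP set.

    The study individuals come from ``study_population``; their haplotypes
    are removed from that population's contribution to the (cosmopolitan)
    reference panel.  Typed sites are chosen by array-like MAF-weighted
    thinning at ``typed_density`` SNPs/kb; all other simulated SNPs are
    untyped and imputed.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    sim = simulate_panels(config, rng)

    pool = sim.panels[study_population]
    study_cols = rng.choice(pool.n_haplotypes, size=2 * n_study, replace=False)
    truth = pool.subset_haplotypes(study_cols)
    ref_parts = []
    labels: list[str] = []
    for name, panel in sim.panels.items():
        if name == study_population:
            keep = np.setdiff1d(np.arange(panel.n_haplotypes), study_cols)
            panel = panel.subset_haplotypes(keep)
        ref_parts.append(panel.alleles)
        labels.extend([name] * panel.n_haplotypes)
    reference = HaplotypePanel(sites=list(sim.sites),
                               alleles=np.concatenate(ref_parts, axis=1))

    typed_index = ascertain_array(reference, typed_density, typed_maf_floor, rng)
    untyped_index = np.setdiff1d(np.arange(reference.n_sites), typed_index)
    geno = (truth.alleles[typed_index, 0::2]
            + truth.alleles[typed_index, 1::2]).astype(np.int8)
    study = GenotypeMatrix(
        sites=[reference.sites[i] for i in typed_index], genotypes=geno,
        individual_ids=[f"study{i}" for i in range(n_study)])

    return SimulatedDataset(sim=sim, reference=reference,
                            reference_labels=labels, study=study, truth=truth,
                            typed_index=typed_index,
                            untyped_index=untyped_index, gmap=sim.gmap)
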