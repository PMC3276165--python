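"""Imputation-accuracy harness.

Accuracy at a masked SNP is the squared Pearson correlation (R²) between
the true genotypes in {0,1,2} and the imputed allele dosages in [0,2];
when the correlation is undefined (either vector constant) R² is set to 0,
capturing the intuition that such a SNP carries no association power.
Per-SNP values are summarized as the mean R², overall and within MAF bins.

Two masking protocols are provided: leave-one-out over the individuals of
a phased panel (each individual in turn is reduced to unphased genotypes
at the typed SNPs and imputed from everyone else's haplotypes), and
every-Nth-SNP sliding-window masking of a study dataset (n passes, each
SNP masked exactly once).

Panels can be ordered by divergence from a target panel via Hudson's F_ST
estimator (ratio of averages across SNPs); only the ordering is used
downstream, which limits sensitivity to the choice of estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Imputer
from .io_formats import (GeneticMap, GenotypeMatrix, HaplotypePanel, MISSING,
                         VariantSite)
from .ls_hmm import ModelParams

__all__ = [
    "EvalReport",
    "dosage",
    "snp_r2",
    "leave_one_out",
    "every_nth_mask",
    "maf_binned_summary",
    "pairwise_fst",
    "order_panels_by_fst",
    "khap_grid",
]


def dosage(triple) -> np.ndarray | float:
    """Allele dosage sum_x P(G=x)*x for one or many probability triples."""
    t = np.asarray(triple, dtype=np.float64)
    if t.shape[-1] != 3:
        raise ValueError("a genotype triple has 3 entries")
    if np.any(t < 0):
        raise ValueError("genotype probabilities must be non-negative")
    sums = t.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("genotype triples must sum to 1")
    d = t[..., 1] + 2.0 * t[..., 2]
    return float(d) if d.ndim == 0 else d


def snp_r2(true_genotypes, dosages) -> float:
    """Squared Pearson correlation between truth and dosage at one SNP.

    Individuals with missing truth are dropped pairwise.  Returns 0 when
    the correlation is undefined (a constant vector) or fewer than two
    complete pairs remain.
    """
    g = np.asarray(true_genotypes, dtype=np.float64)
    d = np.asarray(dosages, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError("truth and dosage vectors must have equal length")
    keep = ~(np.isnan(g) | (g == MISSING) | np.isnan(d))
    g, d = g[keep], d[keep]
    if g.size < 2:
        warnings.warn("fewer than 2 complete pairs; R^2 set to 0", stacklevel=2)
        return 0.0
    sg = g.std()
    sd = d.std()
    if sg == 0.0 or sd == 0.0:
        return 0.0
    r = np.corrcoef(g, d)[0, 1]
    return float(min(r * r, 1.0))


@dataclass
class EvalReport:
    """Per-SNP accuracy table plus experiment metadata.

    ``table`` columns: id, position, maf, r2, degenerate (True when both
    the truth and the dosages were constant at that SNP).
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def mean_r2(self) -> float:
        return float(self.table["r2"].mean()) if len(self.table) else float("nan")

    @property
    def n_degenerate(self) -> int:
        return int(self.table["degenerate"].sum())

    def mean_r2_below_maf(self, maf_cut: float, maf_floor: float = 0.0) -> float:
        t = self.table
        sel = (t["maf"] < maf_cut) & (t["maf"] >= maf_floor)
        return float(t.loc[sel, "r2"].mean()) if sel.any() else float("nan")

    def binned(self, bin_width: float = 0.05,
               min_maf: float | None = None) -> pd.DataFrame:
        return maf_binned_summary(self, bin_width, min_maf=min_maf)


def _report_from_collected(sites: list[VariantSite], truth: np.ndarray,
                           dosages: np.ndarray, metadata: dict) -> EvalReport:
    """Per-SNP R² and MAF from (snps x individuals) truth/dosage arrays."""
    rows = []
    for j, site in enumerate(sites):
        g = truth[j].astype(np.float64)
        valid = g != MISSING
        freq = g[valid].mean() / 2.0 if valid.any() else np.nan
        maf = min(freq, 1.0 - freq) if np.isfinite(freq) else np.nan
        r2 = snp_r2(g, dosages[j])
        degen = bool(valid.sum() >= 2
                     and np.ptp(g[valid]) == 0
                     and np.ptp(dosages[j][valid]) == 0)
        rows.append((site.id, site.position, maf, r2, degen))
    table = pd.DataFrame(rows, columns=["id", "position", "maf", "r2",
                                        "degenerate"])
    return EvalReport(table=table, metadata=metadata)


def _default_imputer(gmap: GeneticMap | None, params: ModelParams | None,
                     **imputer_kwargs):
    def run(study: GenotypeMatrix, reference: HaplotypePanel, seed):
        model = Imputer(study, reference, genetic_map=gmap, params=params,
                        **imputer_kwargs)
        return model.fit(seed=seed)
    return run


def _dosages_at(results, positions: np.ndarray) -> np.ndarray:
    """Imputed dosages aligned to the requested positions."""
    res_pos = {s.position: i for i, s in enumerate(results.untyped_sites)}
    idx = []
    for p in positions:
        if p not in res_pos:
            raise ValueError(f"position {p} was not imputed")
        idx.append(res_pos[p])
    return results.dosages[idx]


def leave_one_out(panel: HaplotypePanel, typed_mask, imputer=None,
                  params: ModelParams | None = None,
                  gmap: GeneticMap | None = None, seed: int | None = None,
                  **imputer_kwargs) -> EvalReport:
    """Leave-one-out cross-validation over the individuals of a phased panel.

    Each individual (haplotype columns 2i, 2i+1) in turn is reduced to
    unphased genotypes at the ``typed_mask`` SNPs; the remaining SNPs are
    masked and imputed from all other individuals' haplotypes.  Per-SNP R²
    is computed across individuals once everyone has been imputed.
    """
    typed_mask = np.asarray(typed_mask)
    if typed_mask.dtype != bool:
        m = np.zeros(panel.n_sites, dtype=bool)
        m[typed_mask] = True
        typed_mask = m
    if not typed_mask.any():
        raise ValueError("typed_mask must select at least one SNP")
    if panel.n_haplotypes % 2 or panel.n_haplotypes < 4:
        raise ValueError("panel must hold >= 2 individuals (even haplotypes)")
    if imputer is None:
        imputer = _default_imputer(gmap, params, **imputer_kwargs)

    n_ind = panel.n_haplotypes // 2
    masked_index = np.flatnonzero(~typed_mask)
    masked_sites = [panel.sites[i] for i in masked_index]
    masked_pos = np.array([s.position for s in masked_sites])
    typed_sites = [panel.sites[i] for i in np.flatnonzero(typed_mask)]

    truth = np.empty((masked_index.size, n_ind), dtype=np.int8)
    dosages = np.empty((masked_index.size, n_ind))
    for i in range(n_ind):
        own = [2 * i, 2 * i + 1]
        keep = np.setdiff1d(np.arange(panel.n_haplotypes), own)
        reference = panel.subset_haplotypes(keep)
        g_typed = (panel.alleles[typed_mask, own[0]]
                   + panel.alleles[typed_mask, own[1]]).astype(np.int8)
        study = GenotypeMatrix(sites=typed_sites, genotypes=g_typed[:, None],
                               individual_ids=[f"loo{i}"])
        res = imputer(study, reference, [seed, i] if seed is not None else None)
        truth[:, i] = (panel.alleles[masked_index, own[0]]
                       + panel.alleles[masked_index, own[1]])
        dosages[:, i] = _dosages_at(res, masked_pos)[:, 0]

    meta = {"protocol": "leave_one_out", "n_individuals": n_ind,
            "n_typed": int(typed_mask.sum()), "n_masked": masked_index.size,
            "params": params}
    return _report_from_collected(masked_sites, truth, dosages, meta)


def every_nth_mask(study: GenotypeMatrix, n: int, reference: HaplotypePanel,
                   imputer=None, params: ModelParams | None = None,
                   gmap: GeneticMap | None = None, seed: int | None = None,
                   **imputer_kwargs) -> EvalReport:
    """Mask and impute every n-th SNP, sliding so each SNP is masked once.

    Pass j (j = 0..n-1) masks the SNPs at indices congruent to j modulo n;
    the masked sets are pairwise disjoint and cover all SNPs.  Masked SNPs
    must be present in the reference panel.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if imputer is None:
        imputer = _default_imputer(gmap, params, **imputer_kwargs)

    S = study.n_sites
    N = study.n_individuals
    truth = study.genotypes
    dosages = np.full((S, N), np.nan)
    for j in range(min(n, S)):
        masked = np.arange(j, S, n)
        keep = np.setdiff1d(np.arange(S), masked)
        if keep.size == 0:
            raise ValueError("masking removed every typed SNP")
        study_pass = study.subset_sites(keep)
        res = imputer(study_pass, reference,
                      [seed, j] if seed is not None else None)
        masked_pos = study.positions[masked]
        dosages[masked] = _dosages_at(res, masked_pos)

    meta = {"protocol": "every_nth_mask", "n": n, "n_individuals": N,
            "n_masked": S, "params": params}
    return _report_from_collected(list(study.sites), truth, dosages, meta)


def maf_binned_summary(report: EvalReport, bin_width: float = 0.05,
                       min_maf: float | None = None) -> pd.DataFrame:
    """Mean R² within half-open MAF bins (lo, hi] covering (0, 0.5].

    SNPs with MAF below ``min_maf`` (e.g. 0.01, where estimates are too
    noisy to be reliable) can be excluded.  Empty bins are absent from the
    output rather than reported as zero.
    """
    n_bins = round(0.5 / bin_width)
    if abs(n_bins * bin_width - 0.5) > 1e-12:
        raise ValueError("bin_width must divide 0.5")
    t = report.table
    maf = t["maf"].to_numpy()
    r2 = t["r2"].to_numpy()
    keep = maf > 0
    if min_maf is not None:
        keep &= maf >= min_maf
    rows = []
    for b in range(n_bins):
        lo = b * bin_width
        hi = lo + bin_width
        sel = keep & (maf > lo) & (maf <= hi + 1e-15)
        if sel.any():
            rows.append((lo, hi, int(sel.sum()), float(r2[sel].mean())))
    return pd.DataFrame(rows, columns=["maf_lo", "maf_hi", "n", "mean_r2"])


def _shared_frequencies(panelA: HaplotypePanel, panelB: HaplotypePanel
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Allele-1 frequencies of A and B at shared sites, on A's coding."""
    by_pos = {s.position: i for i, s in enumerate(panelB.sites)}
    fa, fb = [], []
    for i, s in enumerate(panelA.sites):
        j = by_pos.get(s.position)
        if j is None:
            continue
        r = panelB.sites[j]
        if (s.allele0, s.allele1) == (r.allele0, r.allele1):
            flip = False
        elif (s.allele0, s.allele1) == (r.allele1, r.allele0):
            flip = True
        else:
            continue
        pa = panelA.alleles[i].mean()
        pb = panelB.alleles[j].mean()
        fa.append(pa)
        fb.append(1.0 - pb if flip else pb)
    return np.array(fa), np.array(fb)


def pairwise_fst(panelA: HaplotypePanel, panelB: HaplotypePanel) -> float:
    """Hudson's F_ST between two haplotype panels (ratio of averages).

    Per shared SNP the estimator is

        num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    with haplotype-frequency p and haplotype count n per panel; SNPs
    monomorphic in both panels are skipped, numerators and denominators are
    summed across SNPs before dividing, and the final ratio is clamped to
    [0, 1].
    """
    p1, p2 = _shared_frequencies(panelA, panelB)
    if p1.size == 0:
        raise ValueError("panels share no sites")
    n1 = panelA.n_haplotypes
    n2 = panelB.n_haplotypes
    poly = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    if not poly.any():
        raise ValueError("panels share no polymorphic SNPs")
    p1, p2 = p1[poly], p2[poly]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = num.sum() / den.sum()
    return float(min(max(fst, 0.0), 1.0))


def order_panels_by_fst(target: HaplotypePanel,
                        panels: dict[str, HaplotypePanel]) -> list[str]:
    """Panel names sorted by increasing pairwise F_ST to the target."""
    scored = sorted(panels, key=lambda name: pairwise_fst(target, panels[name]))
    return scored


#: The standard k_hap evaluation grid (clamped to panel size downstream).
_KHAP_BASE = [15, 30, 60, 90, 120, 150, 200, 250, 300, 350, 400]


def khap_grid(panel_size: int) -> list[int]:
    """k_hap evaluation grid clamped to the panel, plus the all-haps point."""
    grid = [g for g in _KHAP_BASE if g <= panel_size]
    grid += [g for g in range(500, panel_size, 100)]
    if panel_size not in grid:
        grid.append(panel_size)
    return sorted(set(grid))
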