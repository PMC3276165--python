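import numpy as np
import pandas as pd
import pytest

from surimpute import (EvalReport, GeneticMap, GenotypeMatrix,
                       HaplotypePanel, ModelParams, SimConfig, VariantSite,
                       dosage, every_nth_mask, khap_grid, leave_one_out,
                       maf_binned_summary, order_panels_by_fst, pairwise_fst,
                       simulate_panels, snp_r2)
from conftest import random_panel
from oracles import hudson_fst_per_snp


class TestDosage:
    @pytest.mark.parametrize("triple, expected", [
        ((0, 0, 1), 2.0),
        ((0.25, 0.5, 0.25), 1.0),
        ((0.1, 0.2, 0.7), 1.6),
    ])
    def test_formula(self, triple, expected):
        assert dosage(triple) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            dosage((-0.1, 0.6, 0.5))


class TestSnpR2:
    def test_perfect_dosages(self):
        assert snp_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_constant_dosage_convention(self):
        assert snp_r2([0, 1, 2, 1], [1.0, 1.0, 1.0, 1.0]) == 0.0
        assert snp_r2([1, 1, 1, 1], [0.1, 0.9, 1.2, 0.3]) == 0.0

    def test_matches_direct_formula(self):
        g = np.array([0, 1, 2, 1], dtype=float)
        d = np.array([0.2, 0.9, 1.8, 1.1])
        num = ((g - g.mean()) * (d - d.mean())).sum()
        expected = num**2 / (((g - g.mean())**2).sum() * ((d - d.mean())**2).sum())
        assert snp_r2(g, d) == pytest.approx(expected, abs=1e-12)

    def test_missing_truth_dropped_pairwise(self):
        r2 = snp_r2([0, 1, 2, -1], [0.0, 1.0, 2.0, 0.42])
        assert r2 == pytest.approx(1.0)

    def test_too_few_pairs_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert snp_r2([1, -1, -1], [0.5, 0.4, 0.3]) == 0.0

    def test_null_mean_matches_one_over_n_minus_one(self):
        rng = np.random.default_rng(6)
        n = 30
        vals = []
        for _ in range(400):
            g = rng.integers(0, 3, size=n)
            d = rng.random(n) * 2
            vals.append(snp_r2(g, d))
        null_mean = 1 / (n - 1)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - null_mean) < 3 * se


def _report(mafs, r2s):
    table = pd.DataFrame({
        "id": [f"s{i}" for i in range(len(mafs))],
        "position": np.arange(1, len(mafs) + 1) * 100,
        "maf": mafs, "r2": r2s, "degenerate": False})
    return EvalReport(table=table)


class TestMafBins:
    def test_single_bin_equals_overall(self):
        rep = _report([0.26, 0.29, 0.28], [0.5, 0.7, 0.6])
        bins = maf_binned_summary(rep, 0.05)
        assert len(bins) == 1
        assert bins["mean_r2"].iloc[0] == pytest.approx(rep.mean_r2)

    def test_assignment_example(self):
        rep = _report([0.02, 0.04, 0.07], [0.1, 0.2, 0.3])
        bins = maf_binned_summary(rep, 0.05)
        assert list(bins["n"]) == [2, 1]
        assert bins["maf_lo"].tolist() == [0.0, 0.05]

    def test_weighted_bin_means_recover_overall_mean(self, rng):
        mafs = rng.uniform(0.001, 0.5, size=200)
        r2s = rng.random(200)
        rep = _report(mafs, r2s)
        bins = maf_binned_summary(rep, 0.05)
        recombined = (bins["n"] * bins["mean_r2"]).sum() / bins["n"].sum()
        assert recombined == pytest.approx(rep.mean_r2, abs=1e-12)

    def test_min_maf_exclusion_and_bad_width(self):
        rep = _report([0.005, 0.2], [0.1, 0.9])
        bins = maf_binned_summary(rep, 0.05, min_maf=0.01)
        assert bins["n"].sum() == 1
        with pytest.raises(ValueError, match="divide"):
            maf_binned_summary(rep, 0.07)


class _RecordingImputer:
    """Fake imputer capturing protocol calls; dosages from a seeded RNG."""

    def __init__(self, all_sites):
        self.all_sites = {s.position: s for s in all_sites}
        self.calls = []

    def __call__(self, study, reference, seed):
        typed = {s.position for s in study.sites}
        untyped = [s for p, s in sorted(self.all_sites.items())
                   if p not in typed]
        self.calls.append({
            "typed": typed,
            "n_ref_haps": reference.n_haplotypes,
            "n_study": study.n_individuals,
        })
        rng = np.random.default_rng(abs(hash(tuple(sorted(typed)))) % 2**31)

        class R:
            untyped_sites = untyped
            dosages = rng.random((len(untyped), study.n_individuals)) * 2
        return R()


class TestEveryNthMask:
    def test_each_snp_masked_exactly_once(self, rng):
        panel = random_panel(rng, n_sites=100, n_haps=10)
        study = GenotypeMatrix(
            sites=list(panel.sites),
            genotypes=(panel.alleles[:, 0::2] + panel.alleles[:, 1::2]
                       ).astype(np.int8))
        fake = _RecordingImputer(panel.sites)
        report = every_nth_mask(study, 25, panel, imputer=fake)
        assert len(fake.calls) == 25
        masked_sets = [set(s.position for s in panel.sites) - c["typed"]
                       for c in fake.calls]
        assert all(len(m) == 4 for m in masked_sets)
        union = set().union(*masked_sets)
        assert union == {s.position for s in panel.sites}
        assert sum(len(m) for m in masked_sets) == len(union)  # disjoint
        assert len(report.table) == 100

    @pytest.mark.parametrize("n_sites, n", [(10, 2), (7, 3), (5, 9)])
    def test_disjoint_cover_property(self, rng, n_sites, n):
        panel = random_panel(rng, n_sites=n_sites, n_haps=6)
        study = GenotypeMatrix(
            sites=list(panel.sites),
            genotypes=(panel.alleles[:, 0::2] + panel.alleles[:, 1::2]
                       ).astype(np.int8))
        fake = _RecordingImputer(panel.sites)
        every_nth_mask(study, n, panel, imputer=fake)
        masked = [set(s.position for s in panel.sites) - c["typed"]
                  for c in fake.calls]
        assert sum(len(m) for m in masked) == n_sites
        assert set().union(*masked) == {s.position for s in panel.sites}

    def test_rejects_stride_one(self, rng):
        panel = random_panel(rng, n_sites=4, n_haps=4)
        study = GenotypeMatrix(
            sites=list(panel.sites),
            genotypes=np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="at least 2"):
            every_nth_mask(study, 1, panel, imputer=lambda *a: None)


class TestLeaveOneOut:
    def test_each_individual_imputed_once_from_others(self, rng):
        panel = random_panel(rng, n_sites=20, n_haps=8)
        typed = np.zeros(20, dtype=bool)
        typed[::2] = True
        fake = _RecordingImputer(panel.sites)
        report = leave_one_out(panel, typed, imputer=fake)
        assert len(fake.calls) == 4
        # the masked individual's haplotypes never sit in its reference
        assert all(c["n_ref_haps"] == 6 and c["n_study"] == 1
                   for c in fake.calls)
        assert len(report.table) == 10  # covers every masked SNP

    def test_complete_ld_fixture_imputes_perfectly(self):
        # four founder haplotypes, each present in several copies: every
        # held-out haplotype keeps an exact match in its reference, and the
        # masked SNPs are carried on those shared haplotypes
        rng = np.random.default_rng(44)
        S = 24
        founders = rng.integers(0, 2, size=(S, 4)).astype(np.uint8)
        arrangement = [0, 0, 0, 1, 1, 2, 2, 2, 3, 3, 3, 0]
        alleles = founders[:, arrangement]
        positions = 500 * (np.arange(S) + 1)
        sites = [VariantSite(f"s{j}", int(positions[j]), "A", "G")
                 for j in range(S)]
        panel = HaplotypePanel(sites=sites, alleles=alleles)
        typed = np.ones(S, dtype=bool)
        typed[[5, 17]] = False
        params = ModelParams(k=4, k_hap=10, iterations=4, burnin=2,
                             lambda_mismatch=1e-4)
        gmap = GeneticMap.constant_rate(1, 13_000, 1.0)
        report = leave_one_out(panel, typed, params=params, gmap=gmap, seed=0)
        tagged = report.table.set_index("id").loc[["s5", "s17"], "r2"]
        degenerate = report.table.set_index("id").loc[["s5", "s17"],
                                                      "degenerate"]
        assert all(r > 0.99 or d for r, d in zip(tagged, degenerate))

    def test_empty_typed_mask_rejected(self, rng):
        panel = random_panel(rng, n_sites=6, n_haps=4)
        with pytest.raises(ValueError, match="at least one"):
            leave_one_out(panel, np.zeros(6, dtype=bool),
                          imputer=lambda *a: None)


class TestPairwiseFst:
    def test_identical_panels_give_zero(self, small_panel):
        assert pairwise_fst(small_panel, small_panel) == 0.0

    def test_fixed_differences_give_one(self):
        sites = [VariantSite(f"s{j}", 100 * (j + 1), "A", "G")
                 for j in range(5)]
        a = HaplotypePanel(sites=sites,
                           alleles=np.zeros((5, 6), dtype=np.uint8))
        b = HaplotypePanel(sites=sites,
                           alleles=np.ones((5, 6), dtype=np.uint8))
        assert pairwise_fst(a, b) == 1.0

    def test_matches_per_snp_oracle(self, rng):
        a = random_panel(rng, n_sites=40, n_haps=14)
        b = HaplotypePanel(sites=list(a.sites),
                           alleles=rng.integers(0, 2, size=(40, 22)
                                                ).astype(np.uint8))
        p1 = a.allele_frequencies()
        p2 = b.allele_frequencies()
        nums, dens = [], []
        for j in range(40):
            if (p1[j] == 0 and p2[j] == 0) or (p1[j] == 1 and p2[j] == 1):
                continue
            num, den = hudson_fst_per_snp(p1[j], p2[j], 14, 22)
            nums.append(num)
            dens.append(den)
        expected = min(max(sum(nums) / sum(dens), 0.0), 1.0)
        assert pairwise_fst(a, b) == pytest.approx(expected, abs=1e-12)

    def test_no_shared_polymorphic_sites_rejected(self):
        sites = [VariantSite("s0", 100, "A", "G")]
        a = HaplotypePanel(sites=sites,
                           alleles=np.zeros((1, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_fst(a, a)

    def test_ordering_recovers_divergence_schedule(self):
        cfg = SimConfig(n_populations=3, haplotypes_per_population=80,
                        region_length=500_000, snps_per_kb=1.0,
                        split_depths=(0.01, 0.05, 0.2))
        sim = simulate_panels(cfg, np.random.default_rng(77))
        order = order_panels_by_fst(sim.panels["pop0"],
                                    {n: sim.panels[n] for n in
                                     ("pop1", "pop2")})
        assert order == ["pop1", "pop2"]


def test_khap_grid_clamps_and_includes_panel_size():
    grid = khap_grid(170)
    assert grid[-1] == 170
    assert all(g <= 170 for g in grid)
    assert 15 in grid and 150 in grid
    big = khap_grid(2020)
    assert 500 in big and 1900 in big and big[-1] == 2020
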