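import numpy as np
import pytest

from surimpute import (Chunk, GeneticMap, GenotypeMatrix, HaplotypePanel,
                       ImputationResult, Imputer, MISSING, ModelParams,
                       SimConfig, VariantSite, initialize_phase, make_chunks,
                       run_mcmc, simulate_dataset, snp_r2, stitch)


class TestMakeChunks:
    def test_arithmetic_example(self):
        chunks = make_chunks((0, 12_000_000), 5_000_000, 250_000)
        cores = [(c.core_start, c.core_end) for c in chunks]
        assert cores == [(0, 5_000_000), (5_000_000, 10_000_000),
                         (10_000_000, 12_000_000)]
        assert (chunks[1].buffer_start, chunks[1].buffer_end) == \
            (4_750_000, 10_250_000)
        # buffers clipped at the region bounds
        assert chunks[0].buffer_start == 0
        assert chunks[2].buffer_end == 12_000_000

    def test_small_region_single_chunk(self):
        chunks = make_chunks((100, 2000), 5_000_000, 250_000)
        assert len(chunks) == 1
        assert (chunks[0].core_start, chunks[0].core_end) == (100, 2000)

    def test_cores_tile_region_disjointly(self, rng):
        for _ in range(30):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(1, 5_000_000))
            size = int(rng.integers(1, 2_000_000))
            chunks = make_chunks((start, end), size, 10_000)
            assert chunks[0].core_start == start
            assert chunks[-1].core_end == end
            for a, b in zip(chunks, chunks[1:]):
                assert a.core_end == b.core_start

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            make_chunks((0, 100), 0, 10)
        with pytest.raises(ValueError):
            make_chunks((100, 100), 10, 10)


def _fake_result(positions, n_ind=2):
    sites = [VariantSite(f"s{p}", p, "A", "G") for p in positions]
    U = len(sites)
    triples = np.zeros((U, n_ind, 3))
    triples[:, :, 0] = 1.0
    return ImputationResult(
        untyped_sites=sites, triples=triples, typed_sites=[],
        typed_haplotypes=np.zeros((0, 2 * n_ind), dtype=np.uint8),
        typed_missing_triples=np.zeros((0, n_ind, 3)),
        individual_ids=[f"i{j}" for j in range(n_ind)])


class TestStitch:
    def test_single_chunk_identity(self):
        chunk = Chunk(0, 100, 0, 100)
        res = _fake_result([10, 20, 30])
        out = stitch([res], [chunk])
        assert [s.position for s in out.untyped_sites] == [10, 20, 30]

    def test_boundary_site_goes_to_right_chunk(self):
        chunks = [Chunk(0, 50, 0, 60), Chunk(50, 100, 40, 100)]
        left = _fake_result([10, 50, 55])   # 50, 55 are buffer-only copies
        right = _fake_result([45, 50, 70])  # 45 is buffer-only
        out = stitch([left, right], chunks)
        assert [s.position for s in out.untyped_sites] == [10, 50, 70]

    def test_every_site_exactly_once(self, rng):
        chunks = make_chunks((0, 300), 100, 50)
        positions = np.sort(rng.choice(np.arange(1, 300), 40, replace=False))
        results = []
        for c in chunks:
            in_buf = [int(p) for p in positions
                      if c.buffer_start <= p < c.buffer_end]
            results.append(_fake_result(in_buf))
        out = stitch(results, chunks)
        np.testing.assert_array_equal(
            [s.position for s in out.untyped_sites], positions)


class TestInitializePhase:
    def test_homozygous_individual_is_deterministic(self, rng):
        g = np.array([[0], [2], [2], [0]], dtype=np.int8)
        haps = initialize_phase(g, rng)
        np.testing.assert_array_equal(haps[:, 0], haps[:, 1])
        np.testing.assert_array_equal(haps[:, 0], [0, 1, 1, 0])

    def test_genotype_consistent_everywhere(self, rng):
        g = rng.choice([0, 1, 2, MISSING], size=(40, 6)).astype(np.int8)
        haps = initialize_phase(g, rng)
        for i in range(6):
            obs = g[:, i] != MISSING
            np.testing.assert_array_equal(
                haps[obs, 2 * i] + haps[obs, 2 * i + 1], g[obs, i])

    def test_same_seed_same_initialization(self):
        g = np.random.default_rng(0).choice(
            [0, 1, 2, MISSING], size=(30, 4)).astype(np.int8)
        a = initialize_phase(g, np.random.default_rng(42))
        b = initialize_phase(g, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)


def _perfect_match_setup():
    rng = np.random.default_rng(17)
    S = 60
    positions = 200 * (np.arange(S) + 1)
    target = rng.integers(0, 2, size=S).astype(np.uint8)
    alleles = rng.integers(0, 2, size=(S, 10)).astype(np.uint8)
    alleles[:, 0] = target
    alleles[:, 1] = target  # a homozygous reference pair matching the study
    sites = [VariantSite(f"s{j}", int(positions[j]), "A", "G")
             for j in range(S)]
    reference = HaplotypePanel(sites=sites, alleles=alleles)
    typed = np.arange(0, S, 2)
    untyped = np.arange(1, S, 2)
    study = GenotypeMatrix(
        sites=[sites[j] for j in typed],
        genotypes=(2 * target[typed])[:, None].astype(np.int8))
    return reference, study, target, typed, untyped


class TestRunMcmc:
    def test_perfect_reference_match_concentrates(self):
        reference, study, target, typed, untyped = _perfect_match_setup()
        # low recombination keeps the copying posterior pinned on the
        # matching reference pair across untyped columns
        gmap = GeneticMap.constant_rate(1, 20_000, 0.05)
        params = ModelParams(k=4, k_hap=10, iterations=6, burnin=2,
                             lambda_mismatch=1e-3)
        chunk = Chunk(1, 20_001, 1, 20_001)
        res = run_mcmc(study, reference, gmap, params, chunk,
                       np.random.default_rng(3))
        true_g = 2 * target[untyped]
        picked = res.triples[np.arange(len(untyped)), 0, true_g]
        assert picked.min() > 0.99

    def test_no_shared_typed_sites_skips_chunk(self, caplog):
        reference, study, *_ = _perfect_match_setup()
        far = GenotypeMatrix(
            sites=[VariantSite("x", 900_000, "A", "G")],
            genotypes=np.array([[1]], dtype=np.int8))
        gmap = GeneticMap.constant_rate(1, 1_000_000, 1.0)
        chunk = Chunk(1, 1_000_000, 1, 1_000_000)
        with caplog.at_level("WARNING"):
            out = run_mcmc(far, reference, gmap,
                           ModelParams(iterations=2, burnin=1), chunk,
                           np.random.default_rng(0))
        assert out is None
        assert "skipped" in caplog.text

    def test_khap_above_panel_clamps_to_identical_run(self):
        reference, study, *_ = _perfect_match_setup()
        gmap = GeneticMap.constant_rate(1, 20_000, 1.0)
        chunk = Chunk(1, 20_001, 1, 20_001)
        kwargs = dict(k=4, iterations=4, burnin=2, lambda_mismatch=1e-3)
        a = run_mcmc(study, reference, gmap,
                     ModelParams(k_hap=10, **kwargs), chunk,
                     np.random.default_rng(8))
        b = run_mcmc(study, reference, gmap,
                     ModelParams(k_hap=999, **kwargs), chunk,
                     np.random.default_rng(8))
        np.testing.assert_array_equal(a.triples, b.triples)

    def test_missing_typed_genotypes_reported_separately(self):
        reference, study, target, typed, _ = _perfect_match_setup()
        g = study.genotypes.copy()
        g[3, 0] = MISSING
        study2 = GenotypeMatrix(sites=study.sites, genotypes=g)
        gmap = GeneticMap.constant_rate(1, 20_000, 1.0)
        params = ModelParams(k=4, k_hap=10, iterations=4, burnin=2,
                             lambda_mismatch=1e-3)
        res = run_mcmc(study2, reference, gmap, params,
                       Chunk(1, 20_001, 1, 20_001), np.random.default_rng(3))
        tm = res.typed_missing_triples
        assert np.isfinite(tm[3, 0]).all()
        other = np.delete(tm, 3, axis=0)
        assert np.isnan(other).all()
        assert tm[3, 0].sum() == pytest.approx(1.0, abs=1e-9)


class TestImputerFit:
    def test_equal_seed_runs_are_identical(self):
        ds = simulate_dataset(SimConfig(snps_per_kb=0.3,
                                        haplotypes_per_population=60),
                              n_study=5, seed=21)
        params = ModelParams(k=20, k_hap=60, iterations=4, burnin=2)
        model = Imputer(ds.study, ds.reference, genetic_map=ds.gmap,
                        params=params)
        a = model.fit(seed=5)
        b = model.fit(seed=5)
        np.testing.assert_array_equal(a.triples, b.triples)
        np.testing.assert_array_equal(a.typed_haplotypes, b.typed_haplotypes)

    def test_accuracy_beats_frequency_baseline_and_grows_with_reference(self):
        cfg = SimConfig(snps_per_kb=0.5)
        ds = simulate_dataset(cfg, n_study=10, seed=13)
        truth = ds.truth_genotypes(ds.untyped_index)
        maf = truth.mean(axis=1) / 2
        poly = np.minimum(maf, 1 - maf) > 0
        labels = np.array(ds.reference_labels)
        pop0 = np.flatnonzero(labels == "pop0")
        means = []
        for size in (40, len(pop0)):
            ref = ds.reference.subset_haplotypes(pop0[:size])
            params = ModelParams(k=40, k_hap=size, iterations=12, burnin=4)
            res = Imputer(ds.study, ref, genetic_map=ds.gmap,
                          params=params).fit(seed=2)
            r2 = np.array([snp_r2(truth[j], res.dosages[j])
                           for j in range(truth.shape[0])])
            means.append(r2[poly].mean())
        # frequency-only imputation has constant dosages, hence R^2 = 0
        assert means[0] > 0.2
        assert means[1] > means[0] + 0.02

    def test_summary_and_info_table(self):
        ds = simulate_dataset(SimConfig(snps_per_kb=0.3,
                                        haplotypes_per_population=60),
                              n_study=4, seed=9)
        params = ModelParams(k=10, k_hap=30, iterations=3, burnin=1)
        res = Imputer(ds.study, ds.reference, genetic_map=ds.gmap,
                      params=params).fit(seed=1)
        info = res.info_table()
        assert len(info) == len(res.untyped_sites)
        assert ((info["maf"] >= 0) & (info["maf"] <= 0.5)).all()
        assert ((info["certainty"] > 0) & (info["certainty"] <= 1)).all()
        text = res.summary()
        assert "imputed SNPs" in text and "k_hap=30" in text
        # triples sum to 1 and dosages stay in [0,2]
        np.testing.assert_allclose(res.triples.sum(axis=2), 1.0, atol=1e-6)
        assert res.dosages.min() >= 0 and res.dosages.max() <= 2
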