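import numpy as np
import pytest

from conftest import make_families, make_marker_map

from famassoc.genedrop import (
    ClusterModel,
    EstimationError,
    FounderModel,
    LDClusterConfig,
    cluster_markers_by_ld,
    estimate_founder_model,
    gene_drop,
    gene_drop_stream,
)
from famassoc.pedio import (
    GenotypeMatrix,
    Individual,
    Pedigree,
    PedigreeSet,
    StructureError,
    mendel_check_indices,
)


def _founder_set(dosage_rows):
    """Unrelated 'founder-only' pedigree set with given per-SNP dosages."""
    fams = [
        [(f"1", None, None, "unknown", row)] for row in dosage_rows
    ]
    pedset, genotypes, _ = make_families(fams)
    return pedset, genotypes


class TestClustering:
    def test_threshold_splits_by_adjacent_r2(self):
        # SNP0/SNP1 identical (r²=1); SNP2 independent noise
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 120)
        c = rng.integers(0, 3, 120)
        pedset, genotypes = _founder_set(np.stack([a, a, c], axis=1).tolist())
        clusters = cluster_markers_by_ld(genotypes, make_marker_map(3), pedset)
        assert clusters == [[0, 1], [2]]

    def test_independent_snps_all_singletons(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 3, (200, 4)).tolist()
        pedset, genotypes = _founder_set(rows)
        clusters = cluster_markers_by_ld(genotypes, make_marker_map(4), pedset)
        assert clusters == [[0], [1], [2], [3]]

    def test_zero_threshold_merges_chromosome_block(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 3, (50, 3)).tolist()
        pedset, genotypes = _founder_set(rows)
        clusters = cluster_markers_by_ld(
            genotypes, make_marker_map(3), pedset, LDClusterConfig(r2_threshold=0.0)
        )
        assert clusters == [[0, 1, 2]]

    def test_monomorphic_snp_is_singleton(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 80)
        rows = np.stack([a, np.zeros(80, int), a], axis=1).tolist()
        pedset, genotypes = _founder_set(rows)
        clusters = cluster_markers_by_ld(genotypes, make_marker_map(3), pedset)
        assert [1] in clusters


class TestFounderModel:
    def test_fixed_allele_frequency(self):
        pedset, genotypes = _founder_set([[0], [0], [0]])
        model = estimate_founder_model(pedset, genotypes, [[0]])
        np.testing.assert_allclose(model.clusters[0].frequencies, [1.0, 0.0])

    def test_singleton_frequency_within_sampling_error(self):
        rng = np.random.default_rng(4)
        n = 100
        dos = rng.binomial(2, 0.3, n)
        pedset, genotypes = _founder_set([[int(d)] for d in dos])
        model = estimate_founder_model(pedset, genotypes, [[0]])
        q = model.clusters[0].frequencies[1]
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert abs(q - 0.3) < 3 * se

    def test_em_fixed_point_on_unambiguous_phase(self):
        # founders carry only AB and ab haplotypes in equal measure:
        # genotypes AABB, aabb and AaBb in HWE proportions resolve to 50/50
        pedset, genotypes = _founder_set([[0, 0], [2, 2], [1, 1], [1, 1]])
        model = estimate_founder_model(pedset, genotypes, [[0, 1]])
        cm = model.clusters[0]
        freq = {tuple(h): f for h, f in zip(cm.haplotypes.tolist(), cm.frequencies)}
        assert freq[(0, 0)] == pytest.approx(0.5, abs=1e-6)
        assert freq[(1, 1)] == pytest.approx(0.5, abs=1e-6)
        assert freq.get((0, 1), 0.0) < 1e-9

    def test_bits_cap_excludes_complex_pedigrees(self):
        # one huge family above the cap, none eligible → estimation error
        members = [Individual(id="f1", father_id=None, mother_id=None, sex=0),
                   Individual(id="f2", father_id=None, mother_id=None, sex=0)]
        members += [
            Individual(id=f"c{i}", father_id="f1", mother_id="f2", sex=0)
            for i in range(40)
        ]
        pedset = PedigreeSet([Pedigree("F", members)])
        genotypes = GenotypeMatrix(np.zeros((42, 1, 2), dtype=np.int8))
        with pytest.raises(EstimationError):
            estimate_founder_model(pedset, genotypes, [[0]], LDClusterConfig(bits_cap=70))


def _trio_pedset():
    fams = [
        [("1", None, None, "unknown", [0]), ("2", None, None, "unknown", [0]),
         ("3", "1", "2", "aff", [0])]
        for _ in range(5)
    ]
    pedset, genotypes, _ = make_families(fams)
    return pedset, genotypes


class TestGeneDrop:
    def test_zero_frequency_gives_monomorphic_output(self):
        pedset, genotypes = _trio_pedset()
        model = FounderModel(
            clusters=[ClusterModel([0], np.array([[0], [1]]), np.array([1.0, 0.0]))],
            n_snps=1,
        )
        rep = gene_drop(pedset, model, np.zeros((15, 1), bool), seed=1)
        assert (rep.codes == 0).all()

    def test_seed_determinism_and_substreams(self, small_sim):
        ds = small_sim
        clusters = cluster_markers_by_ld(ds.genotypes, ds.marker_map, ds.pedset)
        model = estimate_founder_model(ds.pedset, ds.genotypes, clusters)
        a = gene_drop(ds.pedset, model, ds.genotypes.missing_mask, seed=9, replicate=3)
        b = gene_drop(ds.pedset, model, ds.genotypes.missing_mask, seed=9, replicate=3)
        assert a == b
        # stream replicate 3 identical to isolated request
        stream = gene_drop_stream(ds.pedset, model, ds.genotypes.missing_mask, seed=9)
        for _ in range(3):
            next(stream)
        assert next(stream) == a
        c = gene_drop(ds.pedset, model, ds.genotypes.missing_mask, seed=10, replicate=3)
        assert c != a

    def test_single_known_parent_rejected(self):
        # bypass Pedigree validation to hit the drop-time structure check
        pedset, _ = _trio_pedset()
        fa, mo = pedset.parent_rows()
        import famassoc.genedrop as gd

        class Broken:
            n_individuals = pedset.n_individuals

            @staticmethod
            def parent_rows():
                mo2 = mo.copy()
                mo2[2] = -1
                return fa, mo2

        model = FounderModel(
            clusters=[ClusterModel([0], np.array([[0], [1]]), np.array([0.5, 0.5]))],
            n_snps=1,
        )
        with pytest.raises(StructureError):
            gd._DropEngine(Broken, model)

    def test_replicates_mendelian_and_missingness_exact(self, small_sim):
        ds = small_sim
        clusters = cluster_markers_by_ld(ds.genotypes, ds.marker_map, ds.pedset)
        model = estimate_founder_model(ds.pedset, ds.genotypes, clusters)
        for i, rep in enumerate(
            gene_drop_stream(ds.pedset, model, ds.genotypes.missing_mask, seed=21,
                             n_replicates=5)
        ):
            assert mendel_check_indices(ds.pedset, rep) == []
            assert np.array_equal(rep.missing_mask, ds.genotypes.missing_mask)

    def test_founder_maf_unbiased_over_replicates(self):
        pedset, _ = _trio_pedset()
        model = FounderModel(
            clusters=[ClusterModel([0], np.array([[0], [1]]), np.array([0.8, 0.2]))],
            n_snps=1,
        )
        n_rep = 2000
        mafs = []
        founders = pedset.founder_rows()
        for i in range(n_rep):
            rep = gene_drop(pedset, model, np.zeros((15, 1), bool), seed=33, replicate=i)
            mafs.append(rep.codes[founders, 0, :].mean())
        n_gametes = 2 * len(founders) * n_rep
        se = np.sqrt(0.2 * 0.8 / n_gametes)
        assert abs(np.mean(mafs) - 0.2) < 3 * se

    def test_cluster_ld_preserved_across_replicates(self):
        # 2-SNP cluster dropped as a unit: replicate-averaged founder dosage
        # r² matches the model-implied haplotype r² within Monte Carlo error
        fams = [
            [("1", None, None, "unknown", [0, 0]), ("2", None, None, "unknown", [0, 0]),
             ("3", "1", "2", "aff", [0, 0])]
            for _ in range(60)
        ]
        pedset, _, _ = make_families(fams)
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        freqs = np.array([0.5, 0.1, 0.1, 0.3])
        cm = ClusterModel([0, 1], haps, freqs)
        model = FounderModel(clusters=[cm], n_snps=2)
        target = cm.implied_r2()[0, 1]
        mask = np.zeros((pedset.n_individuals, 2), bool)
        founders = pedset.founder_rows()
        pooled = []
        for i in range(1000):
            rep = gene_drop(pedset, model, mask, seed=55, replicate=i)
            pooled.append(rep.dosage()[founders])
        dos = np.concatenate(pooled)  # founder draws are iid across replicates
        r = np.corrcoef(dos, rowvar=False)[0, 1]
        rho = np.sqrt(target)
        se_r2 = 2 * rho * (1 - target) / np.sqrt(len(dos))
        assert abs(r**2 - target) < 3 * se_r2
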