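import numpy as np
import pytest

from conftest import make_families, write_ped_map_files

from famassoc.pedio import (
    DataError,
    DomainError,
    GenotypeMatrix,
    Individual,
    ParseError,
    Pedigree,
    StructureError,
    completion_rate,
    mendel_check_indices,
    pedigree_bits,
    read_ped_map,
    scrub_mendel_errors,
    write_ped_map,
)


class TestReadPedMap:
    def test_minimal_trio(self, trio_data):
        pedset, genotypes, marker_map = trio_data
        assert pedset.n_families == 1
        assert pedset.n_individuals == 3
        assert genotypes.codes.shape == (3, 2, 2)
        assert marker_map.snp_ids == ["rs1", "rs2"]
        # rs1: A is the frequent allele → major; child AA has dosage 0
        assert marker_map.alleles("rs1") == ("A", "G")
        assert genotypes.dosage()[2, 0] == 0

    def test_missing_code_zero(self, tmp_path):
        ped = [
            "F1 1 0 0 1 0 A A",
            "F1 2 0 0 2 0 0 0",
            "F1 3 1 2 1 2 A G",
        ]
        pedset, genotypes, _ = read_ped_map(
            *write_ped_map_files(tmp_path, ped, ["20 rs1 0 1000"])
        )
        assert genotypes.missing_mask[1, 0]
        assert not genotypes.missing_mask[0, 0]

    def test_third_allele_rejected(self, tmp_path):
        ped = [
            "F1 1 0 0 1 0 A A",
            "F1 2 0 0 2 0 A G",
            "F1 3 1 2 1 2 C A",
        ]
        with pytest.raises(DataError, match="two alleles"):
            read_ped_map(*write_ped_map_files(tmp_path, ped, ["20 rs1 0 1000"]))

    def test_malformed_line_reports_number(self, tmp_path):
        ped = ["F1 1 0 0 1 0 A A", "F1 2 0 0 2 0 A"]
        with pytest.raises(ParseError, match=":2"):
            read_ped_map(*write_ped_map_files(tmp_path, ped, ["20 rs1 0 1000"]))

    def test_single_parent_is_structure_error(self, tmp_path):
        ped = ["F1 1 0 0 1 0 A A", "F1 3 1 0 1 2 A A"]
        with pytest.raises(StructureError, match="one parent"):
            read_ped_map(*write_ped_map_files(tmp_path, ped, ["20 rs1 0 1000"]))

    def test_unresolved_parent_is_structure_error(self, tmp_path):
        ped = ["F1 3 1 2 1 2 A G", "F1 4 1 2 2 2 A A"]
        with pytest.raises(StructureError, match="unresolved"):
            read_ped_map(*write_ped_map_files(tmp_path, ped, ["20 rs1 0 1000"]))

    def test_round_trip_bit_exact(self, small_sim, tmp_path):
        # allele-letter content and missingness survive a write/read/write
        # cycle exactly (internal major/minor codes may relabel at MAF ≈ 0.5)
        ds = small_sim
        write_ped_map(
            ds.pedset, ds.genotypes, ds.marker_map, tmp_path / "o.ped", tmp_path / "o.map"
        )
        pedset2, geno2, map2 = read_ped_map(tmp_path / "o.ped", tmp_path / "o.map")
        assert pedset2.keys == ds.pedset.keys
        assert np.array_equal(geno2.missing_mask, ds.genotypes.missing_mask)
        assert map2.table["pos_bp"].tolist() == ds.marker_map.table["pos_bp"].tolist()
        write_ped_map(pedset2, geno2, map2, tmp_path / "o2.ped", tmp_path / "o2.map")
        assert (tmp_path / "o2.ped").read_text() == (tmp_path / "o.ped").read_text()


class TestMendel:
    def test_forced_incompatibility(self):
        pedset, genotypes, _ = make_families(
            [[("1", None, None, "unaff", [0]), ("2", None, None, "unaff", [0]),
              ("3", "1", "2", "aff", [1])]]
        )
        viols = mendel_check_indices(pedset, genotypes)
        assert viols == [("F0", 0, "3")]

    @pytest.mark.parametrize("child_dosage", [0, 1, 2])
    def test_het_parents_allow_everything(self, child_dosage):
        pedset, genotypes, _ = make_families(
            [[("1", None, None, "unaff", [1]), ("2", None, None, "unaff", [1]),
              ("3", "1", "2", "aff", [child_dosage])]]
        )
        assert mendel_check_indices(pedset, genotypes) == []

    def test_planted_violations_all_found(self, small_sim):
        ds = small_sim
        rng = np.random.default_rng(3)
        codes = ds.genotypes.codes.copy()
        fa, mo = ds.pedset.parent_rows()
        children = np.nonzero(fa >= 0)[0]
        planted = set()
        k = 7
        while len(planted) < k:
            r = int(rng.choice(children))
            j = int(rng.integers(ds.marker_map.n_snps))
            # force parents hom-major, child hom-minor: always incompatible
            codes[fa[r], j] = (0, 0)
            codes[mo[r], j] = (0, 0)
            codes[r, j] = (1, 1)
            planted.add((r, j))
        # planting may collaterally break *other* trios sharing these parents;
        # restrict the check to cells we control: every planted cell is found
        viols = mendel_check_indices(ds.pedset, GenotypeMatrix(codes))
        found = {
            (ds.pedset.row_index[(fam, iid)], j) for fam, j, iid in viols
        }
        assert planted <= found

    def test_scrub_family_policy_and_idempotence(self):
        pedset, genotypes, _ = make_families(
            [[("1", None, None, "unaff", [0, 1]), ("2", None, None, "unaff", [0, 1]),
              ("3", "1", "2", "aff", [1, 1]), ("4", "1", "2", "unaff", [0, 0])]]
        )
        viols = mendel_check_indices(pedset, genotypes)
        assert viols == [("F0", 0, "3")]
        cleaned = scrub_mendel_errors(pedset, genotypes, viols)
        # whole family blanked at SNP 0, SNP 1 untouched
        assert cleaned.missing_mask[:, 0].all()
        assert not cleaned.missing_mask[:, 1].any()
        assert mendel_check_indices(pedset, cleaned) == []

    def test_scrub_empty_is_identity(self, small_sim):
        ds = small_sim
        out = scrub_mendel_errors(ds.pedset, ds.genotypes, [])
        assert out == ds.genotypes


class TestPedigreeBits:
    def _family(self, n_founders, n_children):
        members = [
            Individual(id=f"f{i}", father_id=None, mother_id=None, sex=0)
            for i in range(n_founders)
        ]
        members += [
            Individual(id=f"c{i}", father_id="f0", mother_id="f1", sex=0)
            for i in range(n_children)
        ]
        return Pedigree(family_id="F", members=members)

    def test_trio_is_zero_bits(self):
        assert pedigree_bits(self._family(2, 1)) == 0

    def test_nuclear_family_formula(self):
        assert pedigree_bits(self._family(2, 4)) == 6

    def test_three_generation_formula(self):
        # 6 founders, 10 non-founders → 2·10 − 6 = 14
        members = [
            Individual(id=f"g{i}", father_id=None, mother_id=None, sex=0)
            for i in range(6)
        ]
        members += [
            Individual(id="p1", father_id="g0", mother_id="g1", sex=1),
            Individual(id="p2", father_id="g2", mother_id="g3", sex=2),
            Individual(id="p3", father_id="g4", mother_id="g5", sex=1),
        ]
        members += [
            Individual(id=f"c{i}", father_id="p1", mother_id="p2", sex=0)
            for i in range(7)
        ]
        ped = Pedigree(family_id="F", members=members)
        assert pedigree_bits(ped) == 14

    def test_order_invariance(self):
        ped = self._family(2, 3)
        shuffled = Pedigree(family_id="F", members=list(reversed(ped.members)))
        assert pedigree_bits(ped) == pedigree_bits(shuffled)


class TestCompletionRate:
    def test_bounds_and_paper_style_rate(self):
        codes = np.zeros((100, 100, 2), dtype=np.int8)
        gm = GenotypeMatrix(codes)
        assert completion_rate(gm) == 1.0
        codes2 = codes.copy()
        codes2[0, 0] = codes2[0, 1] = codes2[0, 2] = -1
        assert completion_rate(GenotypeMatrix(codes2)) == pytest.approx(0.9997)
        assert completion_rate(GenotypeMatrix(np.full_like(codes, -1))) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(DomainError):
            completion_rate(GenotypeMatrix(np.zeros((0, 0, 2), dtype=np.int8)))


class TestPhenotypes:
    def test_tier_nesting(self, small_sim):
        ds = small_sim
        narrow = ds.phenotypes.affected_mask(ds.pedset, "narrow")
        broad = ds.phenotypes.affected_mask(ds.pedset, "broad")
        very = ds.phenotypes.affected_mask(ds.pedset, "very_broad")
        assert (narrow <= broad).all() and (broad <= very).all()
        assert not (ds.phenotypes.unaffected_mask(ds.pedset) & very).any()
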