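import numpy as np
import pytest

from conftest import make_families
from _oracles import brute_pdt

from famassoc.pedio import GenotypeMatrix
from famassoc.single_marker import (
    build_pdt_index,
    chisq_from_z,
    extract_informative_units,
    p_from_chisq,
    pdt_scores_bulk,
    pdt_statistic,
    qpdt_statistic,
    z_from_scores,
)


def _to_oracle(pedset, genotypes, affected, unaffected, snp=0):
    families = []
    for p in pedset.pedigrees:
        members = {}
        for m in p.members:
            r = pedset.row_index[(p.family_id, m.id)]
            pair = genotypes.codes[r, snp]
            geno = None if pair[0] < 0 else tuple("G" if a else "A" for a in pair)
            status = "aff" if affected[r] else ("unaff" if unaffected[r] else "unknown")
            members[m.id] = {
                "father": m.father_id,
                "mother": m.mother_id,
                "genotype": geno,
                "status": status,
            }
        families.append({"members": members})
    return families


class TestChainArithmetic:
    @pytest.mark.parametrize(
        "chi_sq,expected,tol",
        [
            (10.82, 1.00e-3, 5e-6),
            (3.841, 0.0500, 5e-5),
            (0.0, 1.0, 0),
        ],
    )
    def test_p_from_chisq(self, chi_sq, expected, tol):
        assert p_from_chisq(chi_sq) == pytest.approx(expected, abs=tol)

    def test_p_from_chisq_rejects_negative(self):
        with pytest.raises(Exception):
            p_from_chisq(-1.0)

    def test_chisq_from_z_table_values(self):
        assert 16.97 <= chisq_from_z(4.120) <= 16.98
        assert chisq_from_z(-3.289) == pytest.approx(10.82, abs=0.005)
        assert chisq_from_z(0.0) == 0.0


class TestInformativeUnits:
    def test_unit_extraction(self):
        # family: AA×AA (uninformative), AG×AA (1 triad), sibship 2 aff + 1 unaff
        pedset, genotypes, phenotypes = make_families(
            [
                [("1", None, None, "unaff", [0]), ("2", None, None, "unaff", [0]),
                 ("3", "1", "2", "aff", [0])],
                [("1", None, None, "unaff", [1]), ("2", None, None, "unaff", [0]),
                 ("3", "1", "2", "aff", [1]),
                 ("4", "1", "2", "aff", [0]),
                 ("5", "1", "2", "unaff", [0])],
            ]
        )
        t0, d0 = extract_informative_units(
            pedset.pedigrees[0], pedset, genotypes, phenotypes, 0, "narrow"
        )
        assert t0 == [] and d0 == []
        t1, d1 = extract_informative_units(
            pedset.pedigrees[1], pedset, genotypes, phenotypes, 0, "narrow"
        )
        assert len(t1) == 2  # both affected children, het father
        assert sorted(d1) == [("3", "5"), ("4", "5")]


class TestPdt:
    def test_hand_example_single_triad(self):
        # AG×AG parents, affected AA child: minor-allele D = 2·0−1−1 = −2,
        # |Z| = 1, χ² = 1, p ≈ 0.3173
        pedset, genotypes, phenotypes = make_families(
            [[("1", None, None, "unaff", [1]), ("2", None, None, "unaff", [1]),
              ("3", "1", "2", "aff", [0])]]
        )
        res = pdt_statistic(pedset, genotypes, phenotypes, 0, "narrow", min_families=1)
        assert res.estimable
        d = res.family_scores[0].d_value
        assert abs(d) == 2
        assert abs(res.z_score) == pytest.approx(1.0)
        assert res.chi_sq == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.3173, abs=2e-4)
        assert res.associated_allele == "major"  # A over-transmitted

    def test_mirrored_families_cancel(self):
        fam_plus = [("1", None, None, "unaff", [1]), ("2", None, None, "unaff", [1]),
                    ("3", "1", "2", "aff", [2])]
        fam_minus = [("1", None, None, "unaff", [1]), ("2", None, None, "unaff", [1]),
                     ("3", "1", "2", "aff", [0])]
        pedset, genotypes, phenotypes = make_families([fam_plus, fam_minus])
        res = pdt_statistic(pedset, genotypes, phenotypes, 0, "narrow")
        assert res.estimable
        assert res.z_score == 0.0
        assert res.p_value == 1.0

    def test_not_estimable_without_informative_families(self):
        pedset, genotypes, phenotypes = make_families(
            [[("1", None, None, "unaff", [0]), ("2", None, None, "unaff", [0]),
              ("3", "1", "2", "aff", [0])]]
        )
        res = pdt_statistic(pedset, genotypes, phenotypes, 0, "narrow")
        assert not res.estimable
        assert res.p_value == 1.0

    def test_matches_bruteforce_on_random_small_families(self, small_sim):
        ds = small_sim
        affected = ds.phenotypes.affected_mask(ds.pedset, "broad")
        unaffected = ds.phenotypes.unaffected_mask(ds.pedset)
        for snp in range(ds.marker_map.n_snps):
            res = pdt_statistic(ds.pedset, ds.genotypes, ds.phenotypes, snp, "broad")
            z_oracle, d_oracle = brute_pdt(
                _to_oracle(ds.pedset, ds.genotypes, affected, unaffected, snp),
                target="G",
            )
            if res.estimable:
                assert res.z_score == pytest.approx(z_oracle, abs=1e-12)
            else:
                assert len(d_oracle) < 2 or all(d == 0 for d in d_oracle)

    def test_allele_label_swap_flips_z(self, small_sim):
        ds = small_sim
        swapped = GenotypeMatrix(np.where(ds.genotypes.codes >= 0,
                                          1 - ds.genotypes.codes,
                                          ds.genotypes.codes))
        for snp in [0, 3, 7]:
            a = pdt_statistic(ds.pedset, ds.genotypes, ds.phenotypes, snp, "broad")
            b = pdt_statistic(ds.pedset, swapped, ds.phenotypes, snp, "broad")
            assert a.z_score == pytest.approx(-b.z_score)
            assert a.chi_sq == pytest.approx(b.chi_sq)
            assert a.p_value == pytest.approx(b.p_value)

    def test_dsp_only_information(self):
        # ungenotyped parents: only the discordant sib pair contributes
        pedset, genotypes, phenotypes = make_families(
            [[("1", None, None, "unknown", [None]), ("2", None, None, "unknown", [None]),
              ("3", "1", "2", "aff", [2]), ("4", "1", "2", "unaff", [0])]] * 1
        )
        res = pdt_statistic(pedset, genotypes, phenotypes, 0, "narrow", min_families=1)
        assert res.estimable
        assert res.family_scores[0].d_value == 2.0


class TestQpdt:
    def _triad(self, traits, doses, parents=(1, 0)):
        fams = []
        for t, d in zip(traits, doses):
            fams.append(
                [("1", None, None, "unknown", [parents[0]]),
                 ("2", None, None, "unknown", [parents[1]]),
                 ("3", "1", "2", "aff", [d])]
            )
        pedset, genotypes, phenotypes = make_families(fams)
        trait = np.full(pedset.n_individuals, np.nan)
        for i, t in enumerate(traits):
            trait[3 * i + 2] = t
        return pedset, genotypes, trait

    def test_hand_example_expectation_deviation(self):
        # AG×AA triad, child AG: E[minor|parents] = 0.5, child deviation +0.5;
        # with trait +1 against a grand mean of 0 the family score is +0.5
        # and Z = 0.5/sqrt(0.25) = 1.  A second, genotypically uninformative
        # family (AA×AA) anchors the grand mean without contributing.
        fams = [
            [("1", None, None, "unknown", [1]), ("2", None, None, "unknown", [0]),
             ("3", "1", "2", "aff", [1])],
            [("1", None, None, "unknown", [0]), ("2", None, None, "unknown", [0]),
             ("3", "1", "2", "aff", [0])],
        ]
        pedset, genotypes, _ = make_families(fams)
        trait = np.full(pedset.n_individuals, np.nan)
        trait[2] = 1.0
        trait[5] = -1.0
        res = qpdt_statistic(pedset, genotypes, trait, 0, min_families=1)
        assert res.estimable
        assert [s.d_value for s in res.family_scores] == pytest.approx([0.5])
        assert res.z_score == pytest.approx(1.0)

    def test_constant_trait_not_estimable(self):
        pedset, genotypes, trait = self._triad([2.0, 2.0], [1, 0])
        res = qpdt_statistic(pedset, genotypes, trait, 0)
        assert not res.estimable
        assert res.p_value == 1.0

    def test_affine_trait_invariance(self, small_sim):
        ds = small_sim
        trait = ds.phenotypes.factor_values(ds.pedset, "dep")
        a = qpdt_statistic(ds.pedset, ds.genotypes, trait, 2, ds.marker_map)
        b = qpdt_statistic(ds.pedset, ds.genotypes, 3.7 * trait + 11.0, 2, ds.marker_map)
        assert a.estimable
        assert a.z_score == pytest.approx(b.z_score)

    def test_gamete_fraction_reproduces_frq_assoc(self, small_sim):
        ds = small_sim
        trait = ds.phenotypes.factor_values(ds.pedset, "dep")
        for snp in range(0, ds.marker_map.n_snps, 3):
            res = qpdt_statistic(ds.pedset, ds.genotypes, trait, snp, ds.marker_map)
            maj, mino = res.gamete_counts
            if maj + mino == 0 or not res.estimable:
                continue
            frac_minor = mino / (maj + mino)
            expected = frac_minor if res.associated_allele == "G" else 1 - frac_minor
            assert res.frq_assoc == pytest.approx(expected, abs=5e-4)


class TestBulkEngineConsistency:
    def test_bulk_matches_single_snp_path(self, small_sim):
        ds = small_sim
        affected = ds.phenotypes.affected_mask(ds.pedset, "broad")
        unaffected = ds.phenotypes.unaffected_mask(ds.pedset)
        index = build_pdt_index(ds.pedset, affected, unaffected)
        D, units = pdt_scores_bulk(index, ds.genotypes.dosage())
        z, _, ok = z_from_scores(D, units)
        for snp in range(ds.marker_map.n_snps):
            res = pdt_statistic(ds.pedset, ds.genotypes, ds.phenotypes, snp, "broad")
            assert res.estimable == bool(ok[snp])
            if res.estimable:
                assert res.z_score == pytest.approx(float(z[snp]))
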