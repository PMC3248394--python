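"""Per-SNP family-based association statistics: PDT and quantitative PDT.

The pedigree disequilibrium test (PDT) extends the TDT to general pedigrees
and remains a valid test of association in the presence of linkage.  Each
family contributes a signed score

    D_i = Σ_triads (#A transmitted − #A untransmitted)
        + Σ_DSPs  (#A in affected sib − #A in unaffected sib)

for target allele A, and the test statistic is Z = Σ D_i / sqrt(Σ D_i²),
with Z² ~ χ²(1) under the null.  The default is the unweighted sum-PDT; an
averaged variant (per-family mean over informative units) is available via
``variant="avg"``.

The quantitative PDT correlates trait deviations with transmission
deviations: per family

    S_i = Σ_offspring (t_j − t̄) · (x_j − E[x_j | parents])
        + Σ_DSPs (t_aff − t_unaff) · (x_aff − x_unaff)

where x is the minor-allele count and E[x|parents] its Mendelian expectation
(half the parents' summed dosage); Z = Σ S_i / sqrt(Σ S_i²).

Triads require both parents genotyped; no haplotype/EM reconstruction of
ungenotyped parents is attempted — such offspring contribute only through
discordant-sib-pair (DSP) terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pedio import (
    ConfigError,
    DomainError,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PedigreeSet,
    PhenotypeTable,
)

__all__ = [
    "AssocResult",
    "FamilyScore",
    "PdtIndex",
    "build_pdt_index",
    "extract_informative_units",
    "pdt_statistic",
    "qpdt_statistic",
    "pdt_scores_bulk",
    "qpdt_scores_bulk",
    "z_to_p_matrix",
    "p_from_chisq",
    "chisq_from_z",
]


def chisq_from_z(z: float) -> float:
    """χ² statistic paired with a Z score: simply z² (sign-invariant)."""
    if not np.isfinite(z):
        raise DomainError("z must be finite")
    return float(z) ** 2


def p_from_chisq(chi_sq: float, df: int = 1) -> float:
    """Upper-tail probability of a central χ² — the two-sided p for Z."""
    if chi_sq < 0:
        raise DomainError("chi-square statistic must be non-negative")
    return float(stats.chi2.sf(chi_sq, df))


@dataclass
class FamilyScore:
    family_id: str
    d_value: float


@dataclass
class AssocResult:
    """Single-SNP association summary (one table row).

    ``z_score`` is signed with respect to the *minor* allele; swapping the
    allele labels flips its sign and leaves ``chi_sq``/``p_value`` unchanged.
    ``associated_allele`` names the positively associated allele (for the
    quantitative test, the allele whose carriers have the higher trait mean),
    and reports print |Z| alongside it.
    """

    snp_id: str
    trait_label: str
    estimable: bool
    z_score: float
    chi_sq: float
    p_value: float
    associated_allele: str | None = None
    frq_assoc: float = float("nan")
    trio_counts: tuple[int, int] = (0, 0)  # (transmitted, untransmitted) of assoc
    dsp_counts: tuple[int, int] = (0, 0)  # assoc-allele counts (affected, unaffected)
    gamete_counts: tuple[int, int] = (0, 0)  # (major, minor) analyzed gametes
    n_informative_families: int = 0
    family_scores: list[FamilyScore] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Informative-unit indexing
# ---------------------------------------------------------------------------

@dataclass
class PdtIndex:
    """Row indices of candidate triads and DSPs for one phenotype dichotomy.

    Built once per (pedigree set, affection tier); genotype availability and
    heterozygous-parent requirements are applied per SNP at compute time.
    """

    triad_child: np.ndarray
    triad_fa: np.ndarray
    triad_mo: np.ndarray
    triad_fam: np.ndarray
    dsp_aff: np.ndarray
    dsp_unaff: np.ndarray
    dsp_fam: np.ndarray
    n_families: int


def build_pdt_index(
    pedset: PedigreeSet, affected: np.ndarray, unaffected: np.ndarray
) -> PdtIndex:
    fa, mo = pedset.parent_rows()
    fam_of = pedset.family_of_rows()

    child = np.nonzero((fa >= 0) & affected)[0]
    tri = (child, fa[child], mo[child], fam_of[child])

    # discordant sib pairs: same two parents, one affected / one unaffected
    sib_groups: dict[tuple[int, int], list[int]] = {}
    for r in np.nonzero(fa >= 0)[0]:
        sib_groups.setdefault((fa[r], mo[r]), []).append(r)
    d_aff, d_un, d_fam = [], [], []
    for sibs in sib_groups.values():
        affs = [r for r in sibs if affected[r]]
        uns = [r for r in sibs if unaffected[r]]
        for a in affs:
            for u in uns:
                d_aff.append(a)
                d_un.append(u)
                d_fam.append(fam_of[a])
    return PdtIndex(
        triad_child=tri[0],
        triad_fa=tri[1],
        triad_mo=tri[2],
        triad_fam=tri[3],
        dsp_aff=np.array(d_aff, dtype=np.int64),
        dsp_unaff=np.array(d_un, dtype=np.int64),
        dsp_fam=np.array(d_fam, dtype=np.int64),
        n_families=pedset.n_families,
    )


def extract_informative_units(
    pedigree: Pedigree,
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    snp_index: int,
    tier: str,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """Informative units of one family at one SNP.

    Returns ``(triads, dsps)`` as id tuples: triads (father, mother, child)
    with all three genotyped and at least one heterozygous parent; DSPs as
    (affected, unaffected) sib pairs, both genotyped.
    """
    affected = phenotypes.affected_mask(pedset, tier)
    unaffected = phenotypes.unaffected_mask(pedset)
    fam = pedigree.family_id
    codes = genotypes.codes[:, snp_index, :]
    genotyped = codes[:, 0] >= 0
    het = genotyped & (codes[:, 0] != codes[:, 1])

    triads = []
    by_id = {m.id: m for m in pedigree.members}
    for m in pedigree.members:
        if m.is_founder:
            continue
        r = pedset.row_index[(fam, m.id)]
        rf = pedset.row_index[(fam, m.father_id)]
        rm = pedset.row_index[(fam, m.mother_id)]
        if affected[r] and genotyped[[r, rf, rm]].all() and (het[rf] or het[rm]):
            triads.append((m.father_id, m.mother_id, m.id))

    dsps = []
    sib_groups: dict[tuple[str, str], list[str]] = {}
    for m in pedigree.members:
        if not m.is_founder:
            sib_groups.setdefault((m.father_id, m.mother_id), []).append(m.id)
    for sibs in sib_groups.values():
        rows = {s: pedset.row_index[(fam, s)] for s in sibs}
        for a in sibs:
            for u in sibs:
                if a == u:
                    continue
                if (
                    affected[rows[a]]
                    and unaffected[rows[u]]
                    and genotyped[rows[a]]
                    and genotyped[rows[u]]
                ):
                    dsps.append((a, u))
    return triads, dsps


# ---------------------------------------------------------------------------
# Bulk (vectorised over SNPs) engines — also used by the permutation null
# ---------------------------------------------------------------------------

def pdt_scores_bulk(
    index: PdtIndex, dosage: np.ndarray, variant: str = "sum"
) -> tuple[np.ndarray, np.ndarray]:
    """Family score matrix D (n_families × n_snps) and informative-unit counts.

    ``dosage`` is minor-allele counts with NaN at missing cells.  Triads with
    any ungenotyped member, or with no heterozygous parent, contribute
    nothing; likewise DSPs with a missing sib.  With ``variant="avg"`` each
    family's score is its mean (not sum) over informative units.
    """
    if variant not in ("sum", "avg"):
        raise ConfigError(f"unknown PDT variant {variant!r}")
    n_fam = index.n_families
    m = dosage.shape[1]
    D = np.zeros((n_fam, m))
    units = np.zeros((n_fam, m), dtype=np.int64)

    if len(index.triad_child):
        c = dosage[index.triad_child]
        f = dosage[index.triad_fa]
        mo = dosage[index.triad_mo]
        het = (f == 1) | (mo == 1)
        valid = het & ~np.isnan(c + f + mo)
        contrib = np.where(valid, 2 * c - f - mo, 0.0)
        np.add.at(D, index.triad_fam, np.nan_to_num(contrib))
        np.add.at(units, index.triad_fam, valid.astype(np.int64))

    if len(index.dsp_aff):
        a = dosage[index.dsp_aff]
        u = dosage[index.dsp_unaff]
        valid = ~np.isnan(a + u)
        contrib = np.where(valid, a - u, 0.0)
        np.add.at(D, index.dsp_fam, np.nan_to_num(contrib))
        np.add.at(units, index.dsp_fam, valid.astype(np.int64))

    if variant == "avg":
        with np.errstate(invalid="ignore"):
            D = np.where(units > 0, D / np.maximum(units, 1), 0.0)
    return D, units


def qpdt_scores_bulk(
    index: PdtIndex,
    dosage: np.ndarray,
    trait: np.ndarray,
    centering: str = "grand",
    include_dsp: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Family score matrix S for the quantitative PDT, plus unit counts.

    ``trait`` is one value per individual row (NaN = unscored; such
    individuals are excluded).  Offspring terms use the deviation from the
    grand mean over scored offspring (``centering="family"`` centres within
    family instead); DSP terms require both sibs scored.
    """
    if centering not in ("grand", "family"):
        raise ConfigError(f"unknown trait centering {centering!r}")
    n_fam = index.n_families
    m = dosage.shape[1]
    S = np.zeros((n_fam, m))
    units = np.zeros((n_fam, m), dtype=np.int64)

    c_rows = index.triad_child
    scored = ~np.isnan(trait[c_rows]) if len(c_rows) else np.zeros(0, bool)
    if scored.any():
        rows = c_rows[scored]
        fam = index.triad_fam[scored]
        t = trait[rows]
        if centering == "grand":
            t_dev = t - t.mean()
        else:
            fam_sum = np.zeros(n_fam)
            fam_n = np.zeros(n_fam)
            np.add.at(fam_sum, fam, t)
            np.add.at(fam_n, fam, 1.0)
            t_dev = t - fam_sum[fam] / fam_n[fam]
        x = dosage[rows]
        f = dosage[index.triad_fa[scored]]
        mo = dosage[index.triad_mo[scored]]
        valid = ~np.isnan(x + f + mo)
        dev = np.where(valid, x - (f + mo) / 2.0, 0.0)
        np.add.at(S, fam, np.nan_to_num(t_dev[:, None] * dev))
        np.add.at(units, fam, (valid & (dev != 0)).astype(np.int64))

    if include_dsp and len(index.dsp_aff):
        ta = trait[index.dsp_aff]
        tu = trait[index.dsp_unaff]
        pair_scored = ~np.isnan(ta + tu)
        if pair_scored.any():
            a = dosage[index.dsp_aff[pair_scored]]
            u = dosage[index.dsp_unaff[pair_scored]]
            fam = index.dsp_fam[pair_scored]
            valid = ~np.isnan(a + u)
            contrib = np.where(valid, (ta - tu)[pair_scored, None] * (a - u), 0.0)
            np.add.at(S, fam, np.nan_to_num(contrib))
            np.add.at(units, fam, valid.astype(np.int64))
    return S, units


def z_from_scores(D: np.ndarray, units: np.ndarray, min_families: int = 2):
    """Z = Σ D_i / sqrt(Σ D_i²) per SNP; NaN where not estimable.

    A SNP is estimable when at least ``min_families`` families carry an
    informative unit and the denominator is positive.
    """
    num = D.sum(axis=0)
    den2 = (D**2).sum(axis=0)
    n_inf = (units > 0).sum(axis=0)
    ok = (n_inf >= min_families) & (den2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(ok, num / np.sqrt(np.where(den2 > 0, den2, 1.0)), np.nan)
    return z, n_inf, ok


def z_to_p_matrix(z: np.ndarray) -> np.ndarray:
    """Two-sided p per Z; non-estimable (NaN) entries map to p = 1."""
    p = stats.chi2.sf(np.nan_to_num(z) ** 2, 1)
    p[~np.isfinite(z)] = 1.0
    return p


# ---------------------------------------------------------------------------
# Single-SNP public API
# ---------------------------------------------------------------------------

def _triad_transmission_counts(
    index: PdtIndex, dosage: np.ndarray, j: int
) -> tuple[int, int]:
    """(minor transmitted, minor untransmitted) over heterozygous parents."""
    tr = ntr = 0
    for k in range(len(index.triad_child)):
        c = dosage[index.triad_child[k], j]
        f = dosage[index.triad_fa[k], j]
        m = dosage[index.triad_mo[k], j]
        if np.isnan(c + f + m):
            continue
        n_het = (f == 1) + (m == 1)
        if n_het == 0:
            continue
        forced_minor = (f == 2) + (m == 2)
        t_min = c - forced_minor
        if t_min < 0 or t_min > n_het:  # Mendelian inconsistency; skip unit
            continue
        tr += int(t_min)
        ntr += int(n_het - t_min)
    return tr, ntr


def pdt_statistic(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    snp: int | str,
    tier: str,
    marker_map: MarkerMap | None = None,
    variant: str = "sum",
    min_families: int = 2,
) -> AssocResult:
    """Pedigree disequilibrium test at one SNP for one diagnostic tier.

    ``min_families`` controls the estimability rule: fewer informative
    families (or a zero denominator) yields a flagged, not-estimable result.
    """
    j = marker_map.index_of(snp) if isinstance(snp, str) else int(snp)
    snp_id = marker_map.snp_ids[j] if marker_map is not None else f"snp{j}"
    affected = phenotypes.affected_mask(pedset, tier)
    unaffected = phenotypes.unaffected_mask(pedset)
    index = build_pdt_index(pedset, affected, unaffected)
    dosage = genotypes.dosage()[:, [j]]
    D, units = pdt_scores_bulk(index, dosage, variant=variant)
    z, n_inf, ok = z_from_scores(D, units, min_families=min_families)

    alleles = marker_map.alleles(snp_id) if marker_map is not None else ("major", "minor")
    result = AssocResult(
        snp_id=snp_id,
        trait_label=f"dx:{tier}",
        estimable=bool(ok[0]),
        z_score=float(z[0]) if ok[0] else 0.0,
        chi_sq=float(z[0]) ** 2 if ok[0] else 0.0,
        p_value=p_from_chisq(float(z[0]) ** 2) if ok[0] else 1.0,
        n_informative_families=int(n_inf[0]),
        family_scores=[
            FamilyScore(pedset.pedigrees[i].family_id, float(D[i, 0]))
            for i in range(pedset.n_families)
            if units[i, 0] > 0
        ],
    )

    # Count reporting with respect to the associated (positively scoring)
    # allele: minor if Z ≥ 0 else major.
    z_minor = float(z[0]) if ok[0] else 0.0
    assoc_is_minor = z_minor >= 0
    result.associated_allele = alleles[1] if assoc_is_minor else alleles[0]

    full_dos = genotypes.dosage()
    tr_min, ntr_min = _triad_transmission_counts(index, full_dos, j)
    aff_min = unaff_min = 0
    dsp_gametes = 0
    for k in range(len(index.dsp_aff)):
        a = full_dos[index.dsp_aff[k], j]
        u = full_dos[index.dsp_unaff[k], j]
        if np.isnan(a + u):
            continue
        aff_min += int(a)
        unaff_min += int(u)
        dsp_gametes += 4
    if assoc_is_minor:
        result.trio_counts = (tr_min, ntr_min)
        result.dsp_counts = (aff_min, unaff_min)
    else:
        result.trio_counts = (ntr_min, tr_min)
        # each counted sib carries 2 alleles, so per-sib gametes = dsp_gametes/2
        result.dsp_counts = (
            dsp_gametes // 2 - aff_min,
            dsp_gametes // 2 - unaff_min,
        )
    # analyzed gametes: both alleles of each counted unit member (parents of
    # informative triads, sibs of informative DSPs)
    gam_minor = 0
    gam_total = 0
    for k in range(len(index.triad_child)):
        c = full_dos[index.triad_child[k], j]
        f = full_dos[index.triad_fa[k], j]
        m_ = full_dos[index.triad_mo[k], j]
        if np.isnan(c + f + m_) or not ((f == 1) or (m_ == 1)):
            continue
        gam_minor += int(f + m_)
        gam_total += 4
    gam_minor += aff_min + unaff_min
    gam_total += dsp_gametes
    result.gamete_counts = (gam_total - gam_minor, gam_minor)
    if gam_total:
        frq_minor = gam_minor / gam_total
        result.frq_assoc = frq_minor if assoc_is_minor else 1.0 - frq_minor
    return result


def qpdt_statistic(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    snp: int | str,
    marker_map: MarkerMap | None = None,
    affected: np.ndarray | None = None,
    unaffected: np.ndarray | None = None,
    trait_label: str = "trait",
    centering: str = "grand",
    include_dsp: bool = True,
    min_families: int = 2,
) -> AssocResult:
    """Quantitative PDT at one SNP.

    ``trait`` is a per-row score vector (NaN = unscored).  ``affected`` and
    ``unaffected`` masks define the DSP pairing; by default every scored
    offspring is a potential triad member and DSP terms use phenotypically
    discordant pairs where both sibs carry a score.
    """
    j = marker_map.index_of(snp) if isinstance(snp, str) else int(snp)
    snp_id = marker_map.snp_ids[j] if marker_map is not None else f"snp{j}"
    if affected is None:
        affected = np.ones(pedset.n_individuals, dtype=bool)
    if unaffected is None:
        unaffected = np.zeros(pedset.n_individuals, dtype=bool)
    scored = ~np.isnan(trait)
    if scored.sum() >= 2 and np.nanstd(trait) == 0:
        return AssocResult(
            snp_id=snp_id, trait_label=trait_label, estimable=False,
            z_score=0.0, chi_sq=0.0, p_value=1.0,
        )
    index = build_pdt_index(pedset, affected & scored, unaffected)
    dosage = genotypes.dosage()[:, [j]]
    S, units = qpdt_scores_bulk(
        index, dosage, trait, centering=centering, include_dsp=include_dsp
    )
    z, n_inf, ok = z_from_scores(S, units, min_families=min_families)
    alleles = marker_map.alleles(snp_id) if marker_map is not None else ("major", "minor")

    result = AssocResult(
        snp_id=snp_id,
        trait_label=trait_label,
        estimable=bool(ok[0]),
        z_score=float(z[0]) if ok[0] else 0.0,
        chi_sq=float(z[0]) ** 2 if ok[0] else 0.0,
        p_value=p_from_chisq(float(z[0]) ** 2) if ok[0] else 1.0,
        n_informative_families=int(n_inf[0]),
        family_scores=[
            FamilyScore(pedset.pedigrees[i].family_id, float(S[i, 0]))
            for i in range(pedset.n_families)
            if units[i, 0] > 0
        ],
    )

    # gametes: the two alleles of each scored triad offspring, plus alleles
    # unshared within scored discordant sib pairs
    full_dos = genotypes.dosage()
    gam_minor = gam_total = 0
    for k in range(len(index.triad_child)):
        r = index.triad_child[k]
        if np.isnan(trait[r]):
            continue
        c = full_dos[r, j]
        f = full_dos[index.triad_fa[k], j]
        m_ = full_dos[index.triad_mo[k], j]
        if np.isnan(c + f + m_):
            continue
        gam_minor += int(c)
        gam_total += 2
    if include_dsp:
        for k in range(len(index.dsp_aff)):
            ra, ru = index.dsp_aff[k], index.dsp_unaff[k]
            if np.isnan(trait[ra] + trait[ru]):
                continue
            a = full_dos[ra, j]
            u = full_dos[ru, j]
            if np.isnan(a + u):
                continue
            unshared = int(abs(a - u))
            gam_minor += unshared if a > u else 0
            gam_minor += unshared if u > a else 0
            gam_total += 2 * unshared
    result.gamete_counts = (gam_total - gam_minor, gam_minor)

    # direction: allele whose carriers have the higher trait mean
    dos_scored = full_dos[scored, j]
    t_scored = trait[scored]
    carrier = dos_scored >= 1
    noncarrier = dos_scored == 0
    if carrier.any() and noncarrier.any():
        assoc_is_minor = t_scored[carrier].mean() > t_scored[noncarrier].mean()
    else:
        assoc_is_minor = result.z_score >= 0
    result.associated_allele = alleles[1] if assoc_is_minor else alleles[0]
    if gam_total:
        frq_minor = gam_minor / gam_total
        result.frq_assoc = frq_minor if assoc_is_minor else 1.0 - frq_minor
    return result
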