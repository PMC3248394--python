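"""Synthetic high-density-family data with the structure the analysis assumes.

The generator emulates a family study ascertained for multiplex psychotic
illness: families are retained only if at least two first-degree relatives
are affected at the ascertainment tier (rejection sampling), diagnoses come
from a liability-threshold model with nested concentric tiers, founder
genotypes carry block-structured LD with a minimum tag-SNP MAF, and affected
individuals receive five correlated symptom-factor scores built as integer
item sums over a latent Gaussian factor layer.  An optional "modifier" SNP
adds a dose effect to one factor score among affected individuals while
leaving disease liability untouched — the signature of a modifier locus,
which shapes clinical presentation without altering risk.

Liability model: L = A + E with additive polygenic A (founders N(0, h²),
offspring mid-parent mean plus segregation noise of variance h²/2) and
E ~ N(0, 1−h²); tier thresholds are normal quantiles of nested population
prevalences, so narrow ⊆ intermediate ⊆ broad ⊆ very_broad.

Block LD: within a block every SNP shares one MAF m and haplotypes come from
a two-component mixture — with probability θ a "perfect LD" haplotype
(all-minor with probability m, else all-major), with probability 1−θ an
independent-per-SNP haplotype.  Haplotype-level correlation between any two
block SNPs is then θ, so θ = sqrt(target r²); targets of exactly 1 are
infeasible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from scipy import stats

from .genedrop import ClusterModel, FounderModel, _DropEngine
from .pedio import (
    DataError,
    DomainError,
    FACTORS,
    GeneAnnotation,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    PedigreeSet,
    PhenotypeTable,
    write_gene_annotations,
    write_ped_map,
    write_phenotype_table,
)

import pandas as pd

__all__ = [
    "BlockSpec",
    "ModifierEffect",
    "SimConfig",
    "SimulatedDataset",
    "block_ld_spec_to_haplotypes",
    "simulate_dataset",
]


@dataclass
class BlockSpec:
    """One haplotype block: SNP count, within-block r² target, common MAF."""

    n_snps: int
    r2_target: float
    maf: float


@dataclass
class ModifierEffect:
    """Planted dose effect of one SNP on one factor score (not on liability).

    ``beta`` is expressed on the observed trait scale: the per-minor-allele
    shift of the emitted item-sum factor score, in units of that score's
    population standard deviation.  The generator converts it to a latent-layer
    coefficient through the item-sum attenuation (see
    :func:`_item_sum_calibration`), so the planted condition holds for the
    score the analysis actually sees.
    """

    gene_index: int
    snp_in_gene: int
    beta: float  # score-SD units per minor allele
    factor: str = "dep"


@dataclass
class SimConfig:
    n_families: int = 200
    mean_extra_children: float = 1.5  # sibship = 2 + Poisson(this), capped
    max_children: int = 6
    three_gen_prob: float = 0.25
    ascertainment_min_affected: int = 2
    ascertainment_tier: str = "narrow"
    n_genes: int = 10
    snps_per_gene: int | tuple[int, int] = 9
    block_len: int = 3
    block_r2: float = 0.4
    maf_min: float = 0.1
    liability_h2: float = 0.8
    # nested population prevalences for narrow/intermediate/broad/very_broad
    tier_prevalences: tuple[float, float, float, float] = (0.01, 0.017, 0.025, 0.10)
    factor_corr: float = 0.3
    n_items: int = 10
    item_noise_sd: float = 0.5
    modifier: ModifierEffect | None = None
    missing_rate: float = 0.0003
    seed: int = 0
    max_attempts_per_family: int = 200_000

    def __post_init__(self) -> None:
        if not 0 < self.maf_min <= 0.5:
            raise DomainError("maf_min must be in (0, 0.5]")
        if not 0 < self.liability_h2 < 1:
            raise DomainError("liability_h2 must be in (0, 1)")
        if list(self.tier_prevalences) != sorted(self.tier_prevalences):
            raise DomainError("tier prevalences must be nondecreasing (nested tiers)")
        if self.modifier is not None and self.modifier.factor not in FACTORS:
            raise DomainError(f"modifier factor must be one of {FACTORS}")


@dataclass
class SimulatedDataset:
    pedset: PedigreeSet
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: PhenotypeTable
    genes: list[GeneAnnotation]
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ped": out / "data.ped",
            "map": out / "data.map",
            "phenotypes": out / "phenotypes.tsv",
            "genes": out / "genes.tsv",
            "truth": out / "truth.json",
        }
        write_ped_map(
            self.pedset, self.genotypes, self.marker_map, paths["ped"], paths["map"]
        )
        write_phenotype_table(self.phenotypes, paths["phenotypes"])
        write_gene_annotations(self.genes, paths["genes"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2))
        return paths


def block_ld_spec_to_haplotypes(spec: BlockSpec) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype pool whose implied pairwise haplotype r² equals the target.

    Mixture of a perfect-LD component (weight θ = sqrt(target)) and an
    independent component (weight 1−θ); see the module docstring.  Enumerates
    all 2^k haplotypes, so blocks are capped at 12 SNPs.
    """
    k, t, m = spec.n_snps, spec.r2_target, spec.maf
    if not 0 <= t < 1:
        raise DomainError(f"within-block r² target must be in [0, 1); got {t}")
    if not 0 < m <= 0.5:
        raise DomainError(f"block MAF must be in (0, 0.5]; got {m}")
    if k > 12:
        raise DomainError("block length capped at 12 SNPs (haplotype enumeration)")
    theta = float(np.sqrt(t))
    haps = np.array(list(product((0, 1), repeat=k)), dtype=np.int8)
    indep = np.prod(np.where(haps == 1, m, 1 - m), axis=1)
    freqs = (1 - theta) * indep
    freqs[np.all(haps == 1, axis=1)] += theta * m
    freqs[np.all(haps == 0, axis=1)] += theta * (1 - m)
    return haps, freqs / freqs.sum()


def _item_sum_calibration(cfg: SimConfig) -> tuple[float, float]:
    """Slope and residual SD of the item-sum score against the latent factor.

    The score is Σ_i 1{L + σ·ε_i > c_i} with L ~ N(0,1) and independent item
    noise; both moments are obtained by numeric integration over L.  Used to
    convert a planted effect stated in population score-SD units into the
    equivalent latent-layer coefficient: λ = β · sd(score) / slope.
    """
    c = stats.norm.ppf(np.linspace(0.12, 0.88, cfg.n_items))
    sigma = cfg.item_noise_sd
    grid = np.linspace(-6, 6, 2001)
    w = stats.norm.pdf(grid)
    w /= w.sum()
    p = stats.norm.cdf((grid[:, None] - c[None, :]) / sigma)  # P(item|L)
    mean_l = p.sum(axis=1)
    var_l = (p * (1 - p)).sum(axis=1)  # items independent given L
    mu = float(w @ mean_l)
    ex2 = float(w @ (var_l + mean_l**2))
    var = ex2 - mu**2
    slope = float(w @ (stats.norm.pdf((grid[:, None] - c[None, :]) / sigma) / sigma).sum(axis=1))
    return slope, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Family structure and liabilities
# ---------------------------------------------------------------------------

def _draw_structure(rng: np.random.Generator, cfg: SimConfig):
    """One family skeleton: member ids, parent indices, sexes.

    Nuclear: 1=father, 2=mother, children 3…  With probability
    ``three_gen_prob`` paternal grandparents are prepended and the father
    becomes a non-founder (a 3-generation pedigree).
    """
    n_children = 2 + min(
        int(rng.poisson(cfg.mean_extra_children)), cfg.max_children - 2
    )
    three_gen = rng.random() < cfg.three_gen_prob
    ids: list[str] = []
    fa_idx: list[int] = []
    mo_idx: list[int] = []
    sex: list[int] = []

    def add(iid, f, m_, s):
        ids.append(iid)
        fa_idx.append(f)
        mo_idx.append(m_)
        sex.append(s)
        return len(ids) - 1

    if three_gen:
        gf = add("101", -1, -1, 1)
        gm = add("102", -1, -1, 2)
        father = add("1", gf, gm, 1)
    else:
        father = add("1", -1, -1, 1)
    mother = add("2", -1, -1, 2)
    for c in range(n_children):
        add(str(3 + c), father, mother, int(rng.integers(1, 3)))
    return ids, np.array(fa_idx), np.array(mo_idx), sex


def _simulate_liabilities(
    rng: np.random.Generator,
    fa: np.ndarray,
    mo: np.ndarray,
    h2: float,
    n_attempts: int,
) -> np.ndarray:
    """Liability matrix (n_attempts × n_members) under the additive model."""
    n = len(fa)
    A = np.zeros((n_attempts, n))
    order = np.argsort([0 if f < 0 else 1 for f in fa])  # founders first
    for i in order:
        if fa[i] < 0:
            A[:, i] = rng.normal(0.0, np.sqrt(h2), n_attempts)
        else:
            seg = rng.normal(0.0, np.sqrt(h2 / 2), n_attempts)
            A[:, i] = 0.5 * (A[:, fa[i]] + A[:, mo[i]]) + seg
    E = rng.normal(0.0, np.sqrt(1 - h2), (n_attempts, n))
    return A + E


def _tiers_from_liability(liab: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Tier index per individual: 0..3 = narrow..very_broad, 4 = unaffected.

    Thresholds decrease from narrow to very_broad, so assigning in that
    order labels each individual with the narrowest tier they exceed.
    """
    tier = np.full(liab.shape, 4, dtype=np.int8)
    for t, thr in enumerate(thresholds):
        tier[(tier == 4) & (liab > thr)] = t
    return tier


def _first_degree_pairs(fa: np.ndarray, mo: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    n = len(fa)
    for i in range(n):
        if fa[i] >= 0:
            pairs.append((fa[i], i))
            pairs.append((mo[i], i))
        for j in range(i + 1, n):
            if fa[i] >= 0 and fa[i] == fa[j] and mo[i] == mo[j]:
                pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _build_marker_layout(rng: np.random.Generator, cfg: SimConfig):
    """Gene/block layout, marker map table and true founder haplotype model."""
    map_rows = []
    genes: list[GeneAnnotation] = []
    cluster_models: list[ClusterModel] = []
    blocks_truth = []
    snp_counter = 0
    for g in range(cfg.n_genes):
        if isinstance(cfg.snps_per_gene, tuple):
            lo, hi = cfg.snps_per_gene
            n_snps = int(rng.integers(lo, hi + 1))
        else:
            n_snps = int(cfg.snps_per_gene)
        gene_snps = []
        base = 1_000_000 + g * 500_000
        offset = 0
        while offset < n_snps:
            blen = min(cfg.block_len, n_snps - offset)
            maf = float(rng.uniform(cfg.maf_min, 0.5))
            spec = BlockSpec(n_snps=blen, r2_target=cfg.block_r2 if blen > 1 else 0.0, maf=maf)
            haps, freqs = block_ld_spec_to_haplotypes(spec)
            idx = list(range(snp_counter + offset, snp_counter + offset + blen))
            cluster_models.append(
                ClusterModel(snp_indices=idx, haplotypes=haps, frequencies=freqs)
            )
            blocks_truth.append(
                {"gene": f"GENE{g}", "snps": idx, "maf": maf, "r2_target": spec.r2_target}
            )
            offset += blen
        for s in range(n_snps):
            sid = f"rs{g:02d}{s:03d}"
            gene_snps.append(sid)
            map_rows.append(
                {
                    "chrom": "20",
                    "snp_id": sid,
                    "pos_bp": base + s * 3000,
                    "allele_major": "A",
                    "allele_minor": "G",
                }
            )
        genes.append(GeneAnnotation(f"GENE{g}", gene_snps))
        snp_counter += n_snps
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    return marker_map, genes, cluster_models, blocks_truth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one ascertained multiplex-family dataset plus truth record."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0xFA)))
    thresholds = stats.norm.isf(np.asarray(cfg.tier_prevalences))

    marker_map, genes, cluster_models, blocks_truth = _build_marker_layout(rng, cfg)
    n_snps = marker_map.n_snps

    pedigrees: list[Pedigree] = []
    tier_codes: list[int] = []
    batch = 256
    for fam_i in range(cfg.n_families):
        accepted = None
        attempts = 0
        while accepted is None:
            ids, fa, mo, sex = _draw_structure(rng, cfg)
            pairs = _first_degree_pairs(fa, mo)
            liab = _simulate_liabilities(rng, fa, mo, cfg.liability_h2, batch)
            tiers = _tiers_from_liability(liab, thresholds)
            asc_cut = ("narrow", "intermediate", "broad", "very_broad").index(
                cfg.ascertainment_tier
            )
            aff = tiers <= asc_cut
            # need an affected first-degree pair and the minimum affected count
            pair_ok = np.zeros(batch, dtype=bool)
            for a, b in pairs:
                pair_ok |= aff[:, a] & aff[:, b]
            ok = pair_ok & (aff.sum(axis=1) >= cfg.ascertainment_min_affected)
            if cfg.ascertainment_min_affected < 2:
                ok = aff.sum(axis=1) >= cfg.ascertainment_min_affected
            hits = np.nonzero(ok)[0]
            attempts += batch
            if len(hits):
                accepted = (ids, fa, mo, sex, tiers[hits[0]])
            elif attempts >= cfg.max_attempts_per_family:
                raise DomainError(
                    f"family {fam_i}: ascertainment unreachable after "
                    f"{attempts} attempts (thresholds too strict?)"
                )
        ids, fa, mo, sex, tiers1 = accepted
        fam_id = f"F{fam_i:04d}"
        members = [
            Individual(
                id=ids[i],
                father_id=None if fa[i] < 0 else ids[fa[i]],
                mother_id=None if mo[i] < 0 else ids[mo[i]],
                sex=sex[i],
            )
            for i in range(len(ids))
        ]
        pedigrees.append(Pedigree(family_id=fam_id, members=members))
        tier_codes.extend(int(t) for t in tiers1)

    pedset = PedigreeSet(pedigrees)
    tier_arr = np.asarray(tier_codes)

    # genotypes: Mendelian drop from the true block haplotype model
    model = FounderModel(clusters=cluster_models, n_snps=n_snps)
    engine = _DropEngine(pedset, model)
    codes = np.sort(engine.drop(rng), axis=2)

    # factor scores for individuals with psychosis history (affected, broad)
    scored_rows = np.nonzero(tier_arr <= 2)[0]
    corr = np.full((5, 5), cfg.factor_corr)
    np.fill_diagonal(corr, 1.0)
    latent = rng.multivariate_normal(
        np.zeros(5), corr, size=len(scored_rows), method="cholesky"
    )
    truth_mod = None
    if cfg.modifier is not None:
        mod = cfg.modifier
        gene = genes[mod.gene_index]
        snp_id = gene.snp_ids[mod.snp_in_gene]
        j = marker_map.index_of(snp_id)
        dose = codes[scored_rows, j, :].sum(axis=1)
        slope, score_sd = _item_sum_calibration(cfg)
        beta_latent = mod.beta * score_sd / slope
        latent[:, FACTORS.index(mod.factor)] += beta_latent * dose
        truth_mod = {
            "gene": gene.gene_id,
            "snp_id": snp_id,
            "snp_index": int(j),
            "beta": mod.beta,
            "beta_latent": float(beta_latent),
            "factor": mod.factor,
        }

    # item sums: n_items graded thresholds over the latent factor
    item_thresholds = stats.norm.ppf(np.linspace(0.12, 0.88, cfg.n_items))
    scores = np.zeros((len(scored_rows), 5), dtype=np.int64)
    for f in range(5):
        noise = rng.normal(0.0, cfg.item_noise_sd, (len(scored_rows), cfg.n_items))
        items = (latent[:, [f]] + noise) > item_thresholds[None, :]
        scores[:, f] = items.sum(axis=1)

    # missingness
    miss = rng.random((pedset.n_individuals, n_snps)) < cfg.missing_rate
    codes[miss] = -1
    genotypes = GenotypeMatrix(codes)

    tier_names = ("narrow", "intermediate", "broad", "very_broad", "unaffected")
    score_of = {int(r): scores[i] for i, r in enumerate(scored_rows)}
    rows = []
    for i, (fam, iid) in enumerate(pedset.keys):
        rec = {
            "individual_id": iid,
            "family_id": fam,
            "dx_tier": tier_names[tier_arr[i]],
        }
        sc = score_of.get(i)
        for f_i, f in enumerate(FACTORS):
            rec[f] = float(sc[f_i]) if sc is not None else np.nan
        rows.append(rec)
    phenotypes = PhenotypeTable(pd.DataFrame(rows))

    truth = {
        "seed": int(cfg.seed),
        "n_families": cfg.n_families,
        "thresholds": thresholds.tolist(),
        "modifier": truth_mod,
        "blocks": blocks_truth,
    }
    return SimulatedDataset(
        pedset=pedset,
        genotypes=genotypes,
        marker_map=marker_map,
        phenotypes=phenotypes,
        genes=genes,
        truth=truth,
    )
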