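"""Gene-dropping permutation null for family data.

Simulated genotypes preserve allele/haplotype frequency, marker order and the
observed pattern of missing data, while pedigree structure and phenotypes are
untouched.  Markers in linkage disequilibrium (r² at or above a configurable
threshold, default 0.1) are grouped into clusters; founder haplotypes are
drawn from EM-estimated cluster haplotype frequencies and transmitted as
units (no recombination within a cluster, free recombination between
clusters).  Within-family transmissions are randomised, so association
statistics on replicates are null-distributed even at truly associated SNPs,
while between-marker LD is conserved.

Pedigrees whose complexity exceeds a bit cap (default 70 bits) are excluded
from frequency estimation but still receive simulated genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np

from .pedio import (
    ConfigError,
    DataError,
    GenotypeMatrix,
    MarkerMap,
    PedigreeSet,
    StructureError,
    pedigree_bits,
    logger,
)

__all__ = [
    "LDClusterConfig",
    "ClusterModel",
    "FounderModel",
    "founder_dosage_r2",
    "cluster_markers_by_ld",
    "estimate_founder_model",
    "gene_drop",
    "gene_drop_stream",
]


class EstimationError(Exception):
    pass


@dataclass
class LDClusterConfig:
    """Clustering and complexity-cap settings for the permutation null."""

    r2_threshold: float = 0.1
    bits_cap: int = 70
    linkage: str = "adjacent"  # "adjacent" chaining or "complete" linkage
    em_max_iter: int = 100
    em_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ConfigError("r2_threshold must be in [0, 1]")
        if self.bits_cap < 0:
            raise ConfigError("bits_cap must be non-negative")
        if self.linkage not in ("adjacent", "complete"):
            raise ConfigError(f"unknown cluster linkage {self.linkage!r}")


@dataclass
class ClusterModel:
    """Haplotype pool over a run of member SNPs (singletons have one SNP)."""

    snp_indices: list[int]
    haplotypes: np.ndarray  # (H, k) minor-allele indicators
    frequencies: np.ndarray  # (H,), sums to 1

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        s = self.frequencies.sum()
        if not np.isclose(s, 1.0):
            raise DataError(f"cluster frequencies sum to {s}, not 1")

    @property
    def k(self) -> int:
        return len(self.snp_indices)

    def allele_frequencies(self) -> np.ndarray:
        """Implied per-SNP minor-allele frequencies."""
        return self.frequencies @ self.haplotypes

    def implied_r2(self) -> np.ndarray:
        """Pairwise haplotype-level r² implied by the pool (k × k)."""
        p = self.allele_frequencies()
        ex = (self.frequencies[:, None] * self.haplotypes).T @ self.haplotypes
        cov = ex - np.outer(p, p)
        sd = np.sqrt(p * (1 - p))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.outer(sd, sd)
        return np.nan_to_num(r) ** 2


@dataclass
class FounderModel:
    """Per-cluster founder haplotype frequencies covering every SNP once."""

    clusters: list[ClusterModel]
    n_snps: int

    def __post_init__(self) -> None:
        seen: list[int] = []
        for c in self.clusters:
            seen.extend(c.snp_indices)
        if sorted(seen) != list(range(self.n_snps)):
            raise DataError("clusters must cover every SNP exactly once")


def founder_dosage_r2(
    genotypes: GenotypeMatrix, pedset: PedigreeSet
) -> np.ndarray:
    """Pairwise squared Pearson correlation of founder dosages (composite LD).

    Computed on 0/1/2 minor-allele counts among founders with pairwise
    complete observations; no phasing required.  Monomorphic columns yield
    NaN rows/columns.
    """
    dos = genotypes.dosage()[pedset.founder_rows()]
    m = dos.shape[1]
    r2 = np.full((m, m), np.nan)
    df = np.ma.masked_invalid(dos)
    corr = np.ma.corrcoef(df, rowvar=False)
    r2 = np.asarray(corr.filled(np.nan)) ** 2
    return r2


def cluster_markers_by_ld(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    pedset: PedigreeSet,
    config: LDClusterConfig | None = None,
) -> list[list[int]]:
    """Contiguous marker clusters by founder-dosage LD.

    Default rule chains consecutive markers: an adjacent SNP joins the open
    cluster iff its r² with the previous SNP meets the threshold
    (single-linkage on consecutive pairs).  ``linkage="complete"`` instead
    requires r² ≥ threshold against *every* member of the open cluster.
    Monomorphic SNPs have undefined r² and become singletons.  Clusters never
    span chromosomes.
    """
    config = config or LDClusterConfig()
    r2 = founder_dosage_r2(genotypes, pedset)
    chrom = marker_map.table["chrom"].to_numpy()
    clusters: list[list[int]] = []
    current: list[int] = [0]
    for j in range(1, marker_map.n_snps):
        if chrom[j] != chrom[j - 1]:
            clusters.append(current)
            current = [j]
            continue
        if config.linkage == "adjacent":
            link = r2[j, j - 1]
            joined = np.isfinite(link) and link >= config.r2_threshold
        else:
            vals = r2[j, current]
            joined = np.all(np.isfinite(vals)) and np.all(vals >= config.r2_threshold)
        if joined:
            current.append(j)
        else:
            if not np.isfinite(r2[j, j - 1]):
                logger.warning(
                    "SNP %s: r² undefined (monomorphic); treated as singleton",
                    marker_map.snp_ids[j],
                )
            clusters.append(current)
            current = [j]
    clusters.append(current)
    return clusters


# ---------------------------------------------------------------------------
# Founder-model estimation
# ---------------------------------------------------------------------------

def _em_haplotype_frequencies(
    codes: np.ndarray, k: int, max_iter: int, tol: float, max_expansions: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """EM over unphased founder genotypes in one cluster.

    ``codes``: (n_founders, k, 2) minor-allele indicators with -1 missing.
    Returns (haplotypes, frequencies) restricted to haplotypes with positive
    estimated frequency.  Founders whose ambiguity expansion exceeds
    ``max_expansions`` ordered pairs are skipped.
    """
    H = 1 << k
    haps = np.array(list(product((0, 1), repeat=k)), dtype=np.int8)
    hap_id = {tuple(h): i for i, h in enumerate(haps)}

    pair_lists: list[list[tuple[int, int]]] = []
    for g in codes:
        per_snp: list[list[tuple[int, int]]] = []
        n_amb = 1
        for j in range(k):
            a, b = int(g[j, 0]), int(g[j, 1])
            if a < 0:
                opts = [(0, 0), (0, 1), (1, 0), (1, 1)]
            elif a != b:
                opts = [(0, 1), (1, 0)]
            else:
                opts = [(a, a)]
            n_amb *= len(opts)
            per_snp.append(opts)
        if n_amb > max_expansions:
            continue
        pairs = set()
        for combo in product(*per_snp):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            pairs.add((hap_id[h1], hap_id[h2]))
        pair_lists.append(sorted(pairs))
    if not pair_lists:
        raise EstimationError("no usable founders in cluster")

    freqs = np.full(H, 1.0 / H)
    for _ in range(max_iter):
        new = np.zeros(H)
        for pairs in pair_lists:
            i1 = np.array([p[0] for p in pairs])
            i2 = np.array([p[1] for p in pairs])
            w = freqs[i1] * freqs[i2]
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
            w /= tot
            np.add.at(new, i1, w / 2)
            np.add.at(new, i2, w / 2)
        new /= new.sum()
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            break
    keep = freqs > 1e-12
    freqs = freqs[keep]
    return haps[keep], freqs / freqs.sum()


def estimate_founder_model(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    clusters: list[list[int]],
    config: LDClusterConfig | None = None,
) -> FounderModel:
    """Allele / haplotype frequencies from founders of low-complexity pedigrees.

    Singleton clusters use direct founder allele counts; multi-SNP clusters
    use EM over unphased founder genotypes.  Pedigrees above ``bits_cap``
    are omitted from estimation (they are still simulated at drop time).
    """
    config = config or LDClusterConfig()
    eligible = [p for p in pedset.pedigrees if pedigree_bits(p) <= config.bits_cap]
    if not eligible:
        raise EstimationError(
            f"all pedigrees exceed the {config.bits_cap}-bit complexity cap"
        )
    rows = np.array(
        [
            pedset.row_index[(p.family_id, m.id)]
            for p in eligible
            for m in p.founders()
        ],
        dtype=np.int64,
    )
    codes = genotypes.codes[rows]

    models: list[ClusterModel] = []
    for cl in clusters:
        sub = codes[:, cl, :]
        if len(cl) == 1:
            obs = sub[sub[:, 0, 0] >= 0]
            n = obs.size
            q = float((obs == 1).sum()) / n if n else 0.0
            models.append(
                ClusterModel(
                    snp_indices=list(cl),
                    haplotypes=np.array([[0], [1]], dtype=np.int8),
                    frequencies=np.array([1.0 - q, q]),
                )
            )
        else:
            haps, freqs = _em_haplotype_frequencies(
                sub, len(cl), config.em_max_iter, config.em_tol
            )
            models.append(
                ClusterModel(snp_indices=list(cl), haplotypes=haps, frequencies=freqs)
            )
    return FounderModel(clusters=models, n_snps=genotypes.n_snps)


# ---------------------------------------------------------------------------
# Dropping
# ---------------------------------------------------------------------------

def _generation_levels(pedset: PedigreeSet) -> list[np.ndarray]:
    """Rows grouped so every level's parents lie in earlier levels."""
    fa, mo = pedset.parent_rows()
    depth = np.full(pedset.n_individuals, -1, dtype=np.int64)

    def d(r: int) -> int:
        if depth[r] >= 0:
            return depth[r]
        if fa[r] < 0:
            depth[r] = 0
        else:
            depth[r] = 1 + max(d(fa[r]), d(mo[r]))
        return depth[r]

    for r in range(pedset.n_individuals):
        d(r)
    return [np.nonzero(depth == lvl)[0] for lvl in range(depth.max() + 1)]


class _DropEngine:
    """Precomputed structures for repeated drops over one pedigree set."""

    def __init__(self, pedset: PedigreeSet, model: FounderModel):
        fa, mo = pedset.parent_rows()
        if ((fa >= 0) != (mo >= 0)).any():
            raise StructureError("individual with exactly one known parent")
        self.fa, self.mo = fa, mo
        self.levels = _generation_levels(pedset)
        self.founder_rows = np.nonzero(fa < 0)[0]
        self.model = model
        self.n = pedset.n_individuals
        self.n_clusters = len(model.clusters)
        self.cum_freqs = [np.cumsum(c.frequencies) for c in model.clusters]

    def drop(self, rng: np.random.Generator) -> np.ndarray:
        """One replicate; returns allele codes (n, m, 2)."""
        n, C = self.n, self.n_clusters
        # haplotype index per individual × chromosome copy × cluster
        hap = np.zeros((n, 2, C), dtype=np.int32)
        for ci, cum in enumerate(self.cum_freqs):
            u = rng.random((len(self.founder_rows), 2))
            hap[self.founder_rows, :, ci] = np.searchsorted(cum, u)
        for level in self.levels[1:]:
            # per child, per parent, per cluster: which parental copy
            pick = rng.integers(0, 2, size=(len(level), 2, C))
            fa_h = hap[self.fa[level]]  # (L, 2, C)
            mo_h = hap[self.mo[level]]
            idx = np.arange(len(level))[:, None]
            crange = np.arange(C)[None, :]
            hap[level, 0, :] = fa_h[idx, pick[:, 0, :], crange]
            hap[level, 1, :] = mo_h[idx, pick[:, 1, :], crange]
        codes = np.empty((n, self.model.n_snps, 2), dtype=np.int8)
        for ci, cm in enumerate(self.model.clusters):
            cols = cm.snp_indices
            codes[:, cols, 0] = cm.haplotypes[hap[:, 0, ci]]
            codes[:, cols, 1] = cm.haplotypes[hap[:, 1, ci]]
        return codes


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # replicate index mixed into the seed so any replicate reproduces alone
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(replicate))))


def gene_drop(
    pedset: PedigreeSet,
    founder_model: FounderModel,
    missing_mask: np.ndarray,
    seed: int,
    replicate: int = 0,
) -> GenotypeMatrix:
    """Simulate one replicate genotype matrix through the pedigrees.

    Founders draw cluster haplotypes i.i.d. from the founder model;
    non-founders inherit one haplotype per cluster from each parent uniformly
    at random.  The result is masked to be MISSING exactly where
    ``missing_mask`` is true.
    """
    engine = _DropEngine(pedset, founder_model)
    codes = engine.drop(_replicate_rng(seed, replicate))
    codes = np.sort(codes, axis=2)
    codes[missing_mask] = -1
    return GenotypeMatrix(codes)


def gene_drop_stream(
    pedset: PedigreeSet,
    founder_model: FounderModel,
    missing_mask: np.ndarray,
    seed: int,
    n_replicates: int | None = None,
    start: int = 0,
    as_dosage: bool = False,
) -> Iterator:
    """Replicate stream; with ``as_dosage`` yields dosage arrays directly.

    The stream is deterministic per (seed, replicate index): replicate ``i``
    is identical whether reached by iteration or requested in isolation.
    """
    engine = _DropEngine(pedset, founder_model)
    i = start
    while n_replicates is None or i < start + n_replicates:
        codes = engine.drop(_replicate_rng(seed, i))
        if as_dosage:
            dos = codes.sum(axis=2).astype(float)
            dos[missing_mask] = np.nan
            yield dos
        else:
            codes = np.sort(codes, axis=2)
            codes[missing_mask] = -1
            yield GenotypeMatrix(codes)
        i += 1
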