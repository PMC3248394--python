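"""Pedigree, genotype and phenotype I/O plus Mendelian-consistency QC.

File dialects
-------------
* PED: whitespace-delimited pre-makeped LINKAGE / PLINK layout —
  ``fam id father mother sex phenotype a1 b1 a2 b2 ...`` with ``0`` as the
  missing code for parents, sex, and alleles.  The PED phenotype column is
  ignored: tiered diagnoses live in a separate phenotype table.
* MAP: ``chrom snp_id genetic_dist position_bp`` (genetic distance ignored).
* Phenotype table: TSV with header
  ``individual_id family_id dx_tier del dep hal manic neg`` where ``dx_tier``
  is one of the concentric diagnostic definitions (narrow ⊆ intermediate ⊆
  broad ⊆ very_broad), ``unaffected`` or ``unknown``, and the five factor
  columns are symptom-factor scores (empty = missing).
* Gene annotation: TSV with header ``gene_id chrom snps`` (comma-separated
  SNP ids) or ``gene_id chrom start_snp end_snp`` (inclusive boundary SNPs
  in map order).

Genotypes are stored allele-coded per SNP: 0 = major allele, 1 = minor
allele, -1 = missing; each cell is an unordered pair stored sorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("famassoc")

MISSING = -1
MISSING_ALLELE = "0"

# Concentric diagnostic tiers, narrowest first.  An individual recorded at a
# tier is affected at that tier and every broader one (narrow ⊆ intermediate
# ⊆ broad ⊆ very_broad).
AFFECTED_TIERS = ("narrow", "intermediate", "broad", "very_broad")
DX_VALUES = AFFECTED_TIERS + ("unaffected", "unknown")
TIER_ORDER = {t: i for i, t in enumerate(AFFECTED_TIERS)}

# Symptom-factor score columns: delusions, depressive, hallucinations,
# manic and negative symptom dimensions.
FACTORS = ("del", "dep", "hal", "manic", "neg")


class FamassocError(Exception):
    """Base class for package errors."""


class ParseError(FamassocError):
    pass


class DataError(FamassocError):
    pass


class StructureError(FamassocError):
    pass


class ConfigError(FamassocError):
    pass


class DomainError(FamassocError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: members with resolved parent links, validated acyclic."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if len(ids) != len(self.members):
            raise StructureError(f"family {self.family_id}: duplicate individual ids")
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise StructureError(
                    f"family {self.family_id}, individual {m.id}: "
                    "exactly one parent recorded (must be 0 or 2)"
                )
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise StructureError(
                        f"family {self.family_id}, individual {m.id}: "
                        f"unresolved parent id {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.id: m for m in self.members}
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise StructureError(
                    f"family {self.family_id}: pedigree cycle through {iid}"
                )
            state[iid] = 0
            m = by_id[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for m in self.members:
            visit(m.id, [])

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]


def pedigree_bits(pedigree: Pedigree) -> int:
    """Pedigree complexity in bits: 2·(non-founders) − (founders).

    Governs the feasibility of exact likelihood computations; pedigrees above
    a bit cap are excluded from founder-frequency estimation.
    """
    n_nf = len(pedigree.nonfounders())
    n_f = len(pedigree.founders())
    return 2 * n_nf - n_f


class PedigreeSet:
    """A collection of pedigrees with a stable global row order.

    Row order is the order individuals appear across families; it indexes the
    rows of the companion :class:`GenotypeMatrix` and phenotype arrays.
    """

    def __init__(self, pedigrees: Sequence[Pedigree]):
        self.pedigrees = list(pedigrees)
        self.keys: list[tuple[str, str]] = [
            (p.family_id, m.id) for p in self.pedigrees for m in p.members
        ]
        if len(set(self.keys)) != len(self.keys):
            raise StructureError("duplicate (family, individual) keys")
        self.row_index: dict[tuple[str, str], int] = {
            k: i for i, k in enumerate(self.keys)
        }
        self.family_index: dict[str, int] = {
            p.family_id: i for i, p in enumerate(self.pedigrees)
        }

    @property
    def n_individuals(self) -> int:
        return len(self.keys)

    @property
    def n_families(self) -> int:
        return len(self.pedigrees)

    def rows_of_family(self, family_id: str) -> list[int]:
        p = self.pedigrees[self.family_index[family_id]]
        return [self.row_index[(family_id, m.id)] for m in p.members]

    def parent_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Father/mother row per individual row (-1 for founders)."""
        fa = np.full(self.n_individuals, -1, dtype=np.int64)
        mo = np.full(self.n_individuals, -1, dtype=np.int64)
        for p in self.pedigrees:
            for m in p.members:
                r = self.row_index[(p.family_id, m.id)]
                if not m.is_founder:
                    fa[r] = self.row_index[(p.family_id, m.father_id)]
                    mo[r] = self.row_index[(p.family_id, m.mother_id)]
        return fa, mo

    def founder_rows(self) -> np.ndarray:
        return np.array(
            [
                self.row_index[(p.family_id, m.id)]
                for p in self.pedigrees
                for m in p.founders()
            ],
            dtype=np.int64,
        )

    def family_of_rows(self) -> np.ndarray:
        """Family index (position in ``pedigrees``) per row."""
        out = np.empty(self.n_individuals, dtype=np.int64)
        for p in self.pedigrees:
            fi = self.family_index[p.family_id]
            for m in p.members:
                out[self.row_index[(p.family_id, m.id)]] = fi
        return out


@dataclass
class MarkerMap:
    """Per-SNP metadata; positions strictly increasing within chromosome."""

    table: pd.DataFrame  # snp_id, chrom, pos_bp, allele_major, allele_minor

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp", "allele_major", "allele_minor"}
        if not required.issubset(self.table.columns):
            raise DataError(f"marker map missing columns {required - set(self.table.columns)}")
        if self.table["snp_id"].duplicated().any():
            raise DataError("duplicate SNP ids in marker map")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise DataError(f"positions not strictly increasing on chromosome {chrom}")
        self._index = {s: i for i, s in enumerate(self.table["snp_id"])}

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise DataError(f"unknown SNP id {snp_id!r}") from None

    def alleles(self, snp_id: str) -> tuple[str, str]:
        row = self.table.iloc[self.index_of(snp_id)]
        return row["allele_major"], row["allele_minor"]


class GenotypeMatrix:
    """individuals × SNPs unordered biallelic allele pairs with missingness.

    ``codes`` has shape (n, m, 2) with values 0 (major), 1 (minor) and -1
    (missing); pairs are stored sorted so heterozygotes are always (0, 1).
    A cell is missing as a whole: both slots are -1 or neither.
    """

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 3 or codes.shape[2] != 2:
            raise DataError("genotype codes must have shape (n, m, 2)")
        half_missing = (codes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise DataError("half-missing genotype cell")
        self.codes = np.sort(codes, axis=2)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes[:, :, 0] == MISSING

    def dosage(self) -> np.ndarray:
        """Minor-allele count per cell as float, NaN where missing."""
        d = self.codes.sum(axis=2).astype(float)
        d[self.missing_mask] = np.nan
        return d

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and np.array_equal(
            self.codes, other.codes
        )


@dataclass
class PhenotypeTable:
    """Tiered affection status and five symptom-factor scores per individual."""

    table: pd.DataFrame  # individual_id, family_id, dx_tier, del..neg

    def __post_init__(self) -> None:
        bad = set(self.table["dx_tier"]) - set(DX_VALUES)
        if bad:
            raise DataError(f"unknown diagnosis tier values: {sorted(bad)}")
        self._by_key = {
            (str(r.family_id), str(r.individual_id)): i
            for i, r in enumerate(self.table.itertuples())
        }

    def dx_tier(self, family_id: str, individual_id: str) -> str:
        i = self._by_key.get((family_id, individual_id))
        return "unknown" if i is None else self.table["dx_tier"].iloc[i]

    def affected_mask(self, pedset: PedigreeSet, tier: str) -> np.ndarray:
        """True where the individual is affected at ``tier`` (nested tiers)."""
        if tier not in TIER_ORDER:
            raise ConfigError(f"unknown diagnosis tier {tier!r}")
        cut = TIER_ORDER[tier]
        out = np.zeros(pedset.n_individuals, dtype=bool)
        for i, (fam, iid) in enumerate(pedset.keys):
            dx = self.dx_tier(fam, iid)
            out[i] = dx in TIER_ORDER and TIER_ORDER[dx] <= cut
        return out

    def unaffected_mask(self, pedset: PedigreeSet) -> np.ndarray:
        out = np.zeros(pedset.n_individuals, dtype=bool)
        for i, (fam, iid) in enumerate(pedset.keys):
            out[i] = self.dx_tier(fam, iid) == "unaffected"
        return out

    def factor_values(self, pedset: PedigreeSet, factor: str) -> np.ndarray:
        """Factor score per row, NaN where missing/unscored."""
        if factor not in FACTORS:
            raise ConfigError(f"unknown factor {factor!r}; expected one of {FACTORS}")
        out = np.full(pedset.n_individuals, np.nan)
        col = self.table[factor].to_numpy(dtype=float)
        for i, (fam, iid) in enumerate(pedset.keys):
            j = self._by_key.get((fam, iid))
            if j is not None:
                out[i] = col[j]
        return out


@dataclass
class GeneAnnotation:
    gene_id: str
    snp_ids: list[str]

    def validate(self, marker_map: MarkerMap) -> None:
        if not self.snp_ids:
            raise DataError(f"gene {self.gene_id}: empty SNP list")
        for s in self.snp_ids:
            marker_map.index_of(s)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_path}:{ln}: expected ≥4 MAP columns, got {len(parts)}")
        try:
            pos = int(parts[3])
        except ValueError:
            raise ParseError(f"{map_path}:{ln}: bad bp position {parts[3]!r}") from None
        rows.append({"chrom": parts[0], "snp_id": parts[1], "pos_bp": pos})
    if not rows:
        raise ParseError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows)


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[PedigreeSet, GenotypeMatrix, MarkerMap]:
    """Parse companion PED/MAP files into validated in-memory structures.

    Allele coding is normalised from observed frequencies: at each SNP the
    more frequent allele becomes the major allele (ties broken
    lexicographically).  More than two observed alleles at a SNP is a data
    error; a malformed line reports its line number.
    """
    map_df = _read_map(map_path)
    m = len(map_df)

    fam_members: dict[str, list[tuple[str, str, str, int]]] = {}
    fam_order: list[str] = []
    raw_rows: list[list[str]] = []
    row_keys: list[tuple[str, str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields "
                f"(6 + 2×{m} alleles), got {len(parts)}"
            )
        fam, iid, fid, mid, sex_s = parts[:5]
        try:
            sex = int(sex_s)
        except ValueError:
            raise ParseError(f"{ped_path}:{ln}: bad sex code {sex_s!r}") from None
        if fam not in fam_members:
            fam_members[fam] = []
            fam_order.append(fam)
        fam_members[fam].append((iid, fid, mid, sex))
        raw_rows.append(parts[6:])
        row_keys.append((fam, iid))

    pedigrees = []
    for fam in fam_order:
        members = [
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=sex,
            )
            for iid, fid, mid, sex in fam_members[fam]
        ]
        pedigrees.append(Pedigree(family_id=fam, members=members))
    pedset = PedigreeSet(pedigrees)
    # PED row order must match pedigree-set row order (it does: both follow
    # file order), but guard against surprises.
    assert row_keys == pedset.keys

    n = len(raw_rows)
    alleles = np.array(raw_rows, dtype=object).reshape(n, m, 2)

    codes = np.full((n, m, 2), MISSING, dtype=np.int8)
    major = []
    minor = []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != MISSING_ALLELE]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise DataError(
                f"SNP {map_df['snp_id'].iloc[j]}: more than two alleles observed "
                f"({sorted(uniq)})"
            )
        if len(uniq) == 0:
            a_major, a_minor = "A", "B"  # fully missing column; placeholder labels
        elif len(uniq) == 1:
            a_major, a_minor = uniq[0], "?"
        else:
            order = np.lexsort((uniq, -counts))  # by count desc, then name
            a_major, a_minor = uniq[order[0]], uniq[order[1]]
        major.append(a_major)
        minor.append(a_minor)
        half = (col == MISSING_ALLELE).sum(axis=1) == 1
        if half.any():
            raise DataError(
                f"SNP {map_df['snp_id'].iloc[j]}: half-missing genotype"
            )
        present = col[:, 0] != MISSING_ALLELE
        codes[present, j, 0] = (col[present, 0] == a_minor).astype(np.int8)
        codes[present, j, 1] = (col[present, 1] == a_minor).astype(np.int8)

    map_df = map_df.assign(allele_major=major, allele_minor=minor)
    return pedset, GenotypeMatrix(codes), MarkerMap(map_df)


def write_ped_map(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Emit PED/MAP in the dialect :func:`read_ped_map` accepts (round-trips)."""
    t = marker_map.table
    with open(map_path, "w") as fh:
        for _, r in t.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos_bp']}\n")
    allele_lookup = np.stack(
        [t["allele_major"].to_numpy(object), t["allele_minor"].to_numpy(object)],
        axis=1,
    )  # (m, 2)
    with open(ped_path, "w") as fh:
        for p in pedset.pedigrees:
            for mbr in p.members:
                r = pedset.row_index[(p.family_id, mbr.id)]
                fields = [
                    p.family_id,
                    mbr.id,
                    mbr.father_id or "0",
                    mbr.mother_id or "0",
                    str(mbr.sex),
                    "0",
                ]
                row = genotypes.codes[r]
                for j in range(marker_map.n_snps):
                    a, b = row[j]
                    if a == MISSING:
                        fields += [MISSING_ALLELE, MISSING_ALLELE]
                    else:
                        # canonical letter order so output is label-invariant
                        fields += sorted((allele_lookup[j, a], allele_lookup[j, b]))
                fh.write(" ".join(fields) + "\n")


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "family_id": str})
    required = ["individual_id", "family_id", "dx_tier", *FACTORS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: phenotype table missing columns {missing}")
    return PhenotypeTable(df)


def write_phenotype_table(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def read_gene_annotations(
    path: str | Path, marker_map: MarkerMap
) -> list[GeneAnnotation]:
    """Gene → SNP membership, either explicit lists or boundary-SNP ranges."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes: list[GeneAnnotation] = []
    if "snps" in df.columns:
        for _, r in df.iterrows():
            genes.append(GeneAnnotation(r["gene_id"], r["snps"].split(",")))
    elif {"start_snp", "end_snp"}.issubset(df.columns):
        for _, r in df.iterrows():
            i0 = marker_map.index_of(r["start_snp"])
            i1 = marker_map.index_of(r["end_snp"])
            if i1 < i0:
                raise DataError(f"gene {r['gene_id']}: boundary SNPs out of order")
            genes.append(GeneAnnotation(r["gene_id"], marker_map.snp_ids[i0 : i1 + 1]))
    else:
        raise ParseError(f"{path}: need 'snps' or 'start_snp'/'end_snp' columns")
    for g in genes:
        g.validate(marker_map)
    return genes


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tsnps\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t.\t{','.join(g.snp_ids)}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def mendel_check(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
) -> list[tuple[str, str, str]]:
    """Flag single-SNP Mendelian incompatibilities in child/parent trios.

    Returns (family_id, snp_id, child_id) triples; cells with any missing
    member are skipped.  Without a marker map SNPs are named positionally
    (``snp<j>``); :func:`mendel_check_indices` returns raw indices.
    """
    viols_idx = mendel_check_indices(pedset, genotypes)
    name = (
        (lambda j: marker_map.snp_ids[j]) if marker_map is not None
        else (lambda j: f"snp{j}")
    )
    return [(fam, name(j), iid) for fam, j, iid in viols_idx]


def mendel_check_indices(
    pedset: PedigreeSet, genotypes: GenotypeMatrix
) -> list[tuple[str, int, str]]:
    """As :func:`mendel_check` but with integer SNP indices."""
    fa, mo = pedset.parent_rows()
    child_rows = np.nonzero(fa >= 0)[0]
    codes = genotypes.codes
    out: list[tuple[str, int, str]] = []
    fam_of = pedset.family_of_rows()
    for r in child_rows:
        c = codes[r]  # (m, 2)
        f = codes[fa[r]]
        mth = codes[mo[r]]
        ok_any = (c[:, 0] == MISSING) | (f[:, 0] == MISSING) | (mth[:, 0] == MISSING)
        c1, c2 = c[:, 0], c[:, 1]
        from_f_c1 = (c1 == f[:, 0]) | (c1 == f[:, 1])
        from_f_c2 = (c2 == f[:, 0]) | (c2 == f[:, 1])
        from_m_c1 = (c1 == mth[:, 0]) | (c1 == mth[:, 1])
        from_m_c2 = (c2 == mth[:, 0]) | (c2 == mth[:, 1])
        consistent = (from_f_c1 & from_m_c2) | (from_f_c2 & from_m_c1)
        bad = ~(consistent | ok_any)
        if bad.any():
            ped = pedset.pedigrees[fam_of[r]]
            fam_id, iid = pedset.keys[r]
            for j in np.nonzero(bad)[0]:
                out.append((fam_id, int(j), iid))
    return out


def scrub_mendel_errors(
    pedset: PedigreeSet,
    genotypes: GenotypeMatrix,
    violations: list[tuple[str, int, str]],
    policy: str = "family",
) -> GenotypeMatrix:
    """Blank flagged genotypes; default removes the SNP for the whole family.

    ``violations`` uses integer SNP indices (from
    :func:`mendel_check_indices`).  Policy ``"individual"`` blanks only the
    offending child's cell.
    """
    if policy not in ("family", "individual"):
        raise ConfigError(f"unknown Mendelian scrub policy {policy!r}")
    out = genotypes.codes.copy()
    for fam_id, j, iid in violations:
        if policy == "family":
            rows = pedset.rows_of_family(fam_id)
            out[rows, j, :] = MISSING
        else:
            out[pedset.row_index[(fam_id, iid)], j, :] = MISSING
    return GenotypeMatrix(out)


def completion_rate(genotypes: GenotypeMatrix) -> float:
    """Fraction of non-missing genotype cells; the study-style QC summary."""
    total = genotypes.n_individuals * genotypes.n_snps
    if total == 0:
        raise DomainError("completion rate undefined for an empty matrix")
    return 1.0 - genotypes.missing_mask.sum() / total
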