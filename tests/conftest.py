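from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famassoc.pedio import (
    FACTORS,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    PedigreeSet,
    PhenotypeTable,
    read_ped_map,
)


def write_ped_map_files(tmp_path, ped_lines, map_lines, stem="data"):
    ped = tmp_path / f"{stem}.ped"
    mp = tmp_path / f"{stem}.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


def make_marker_map(n_snps, chrom="20"):
    return MarkerMap(
        pd.DataFrame(
            {
                "chrom": chrom,
                "snp_id": [f"rs{j}" for j in range(n_snps)],
                "pos_bp": [1000 * (j + 1) for j in range(n_snps)],
                "allele_major": "A",
                "allele_minor": "G",
            }
        )
    )


def make_families(spec):
    """Build (PedigreeSet, GenotypeMatrix, PhenotypeTable) from a dict spec.

    spec: list of families; each family is a list of member tuples
    (id, father, mother, status, genotypes) where genotypes is a list of
    minor-allele dosages (0/1/2) or None for missing, and status is
    "aff"/"unaff"/"unknown" or a dx tier name.
    """
    peds = []
    geno_rows = []
    pheno_rows = []
    n_snps = None
    for fi, fam in enumerate(spec):
        fam_id = f"F{fi}"
        members = []
        for iid, fa, mo, status, genos in fam:
            members.append(Individual(id=iid, father_id=fa, mother_id=mo, sex=0))
            if n_snps is None:
                n_snps = len(genos)
            row = []
            for g in genos:
                if g is None:
                    row.append((-1, -1))
                else:
                    row.append((0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1)))
            geno_rows.append(row)
            dx = {"aff": "narrow", "unaff": "unaffected", "unknown": "unknown"}.get(
                status, status
            )
            pheno_rows.append(
                {"individual_id": iid, "family_id": fam_id, "dx_tier": dx}
                | {f: np.nan for f in FACTORS}
            )
        peds.append(Pedigree(family_id=fam_id, members=members))
    pedset = PedigreeSet(peds)
    genotypes = GenotypeMatrix(np.array(geno_rows, dtype=np.int8))
    phenotypes = PhenotypeTable(pd.DataFrame(pheno_rows))
    return pedset, genotypes, phenotypes


@pytest.fixture
def trio_files(tmp_path):
    """Minimal well-formed 1-trio, 2-SNP PED/MAP pair."""
    ped_lines = [
        "F1 1 0 0 1 0 A A A G",
        "F1 2 0 0 2 0 A G G G",
        "F1 3 1 2 1 2 A A G G",
    ]
    map_lines = ["20 rs1 0 1000", "20 rs2 0 2000"]
    return write_ped_map_files(tmp_path, ped_lines, map_lines)


@pytest.fixture
def trio_data(trio_files):
    return read_ped_map(*trio_files)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset shared by read-only tests."""
    from famassoc.synthdata import SimConfig, simulate_dataset

    return simulate_dataset(
        SimConfig(n_families=40, n_genes=4, snps_per_gene=6, seed=11, missing_rate=0.01)
    )
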