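"""Independent reference implementations used only as test oracles.

Deliberately written with explicit allele multisets and python loops, not
the package's vectorised dosage arithmetic, so the two paths share nothing
but the definitions.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_pdt(families: list[dict], target: str) -> tuple[float, list[float]]:
    """Sum-PDT by exhaustive enumeration of triads and discordant sib pairs.

    ``families`` is a list of dicts with keys:
      members: {id: {"father": id|None, "mother": id|None,
                     "genotype": (a, b) allele letters or None,
                     "status": "aff"|"unaff"|"unknown"}}
    ``target`` is the allele letter whose transmissions are counted.
    Returns (Z, per-family D values for families with informative units).
    """
    d_values = []
    for fam in families:
        members = fam["members"]
        d = 0.0
        informative = 0
        # triads
        for iid, m in members.items():
            if m["father"] is None or m["status"] != "aff" or m["genotype"] is None:
                continue
            gf = members[m["father"]]["genotype"]
            gm = members[m["mother"]]["genotype"]
            if gf is None or gm is None:
                continue
            het_f = gf[0] != gf[1]
            het_m = gm[0] != gm[1]
            if not (het_f or het_m):
                continue
            child = Counter(m["genotype"])
            parents = Counter(gf) + Counter(gm)
            untransmitted = parents - child
            if sum(untransmitted.values()) != 2:  # Mendelian-inconsistent triad
                continue
            d += child[target] - untransmitted[target]
            informative += 1
        # discordant sib pairs
        ids = list(members)
        for a in ids:
            for u in ids:
                ma, mu = members[a], members[u]
                if a == u or ma["father"] is None or mu["father"] is None:
                    continue
                if (ma["father"], ma["mother"]) != (mu["father"], mu["mother"]):
                    continue
                if ma["status"] != "aff" or mu["status"] != "unaff":
                    continue
                if ma["genotype"] is None or mu["genotype"] is None:
                    continue
                d += Counter(ma["genotype"])[target] - Counter(mu["genotype"])[target]
                informative += 1
        if informative:
            d_values.append(d)
    denom = math.sqrt(sum(x * x for x in d_values))
    z = sum(d_values) / denom if denom > 0 else float("nan")
    return z, d_values


def nyholt_meff_direct(corr_rows: list[list[float]]) -> float:
    """Effective tests from a symbolic eigen-decomposition (sympy)."""
    import sympy

    M = len(corr_rows)
    mat = sympy.Matrix(corr_rows)
    lam = []
    for val, mult in mat.eigenvals().items():
        lam.extend([complex(sympy.N(val, 30)).real] * mult)
    mean = sum(lam) / M
    var = sum((x - mean) ** 2 for x in lam) / (M - 1)
    return 1 + (M - 1) * (1 - var / M)
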