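"""Gene-based statistics and adaptive Monte Carlo significance.

Two gene-level statistics summarise a gene's single-SNP p-values:

* **min-P** — the smallest p-value among the gene's SNPs;
* **threshold-truncated product** — the product of only those p-values at or
  below a truncation threshold (default 0.01), kept on the log scale to
  avoid underflow.  An empty selection gives a product of 1 (log 0), the
  least significant possible value.

Both are calibrated by gene-dropping permutation.  Significance is staged
adaptively: empirical p-values are evaluated after 100, 1,000, 10,000 and
100,000 replicates, and a gene is carried to the next stage only while fewer
than ten simulated statistics are at least as significant as the observed
one.  The empirical p is (r_obs + 1) / (n_perm + 1), so p ≥ 1/(n+1) always.

Replicates from earlier stages are retained and counted toward later stages
(the replicate stream is cumulative).

For independent uniform p-values the truncated product has a closed-form
tail probability (Zaykin's formula), provided here as an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .pedio import ConfigError, DomainError

__all__ = [
    "GeneTestConfig",
    "StageRecord",
    "GeneTestResult",
    "min_p",
    "truncated_product",
    "zaykin_analytic_p",
    "adaptive_permutation",
    "adaptive_gene_scan",
]

METHODS = ("min_p", "trunc_prod")


@dataclass
class GeneTestConfig:
    """Truncation threshold, permutation stages and the carry-forward rule."""

    alpha_trunc: float = 0.01
    stages: tuple[int, ...] = (100, 1_000, 10_000, 100_000)
    carry_forward_max_exceedances: int = 10  # carried forward iff r < this
    count_ties: bool = True  # replicate stat equal to observed counts as exceedance

    def __post_init__(self) -> None:
        if not 0 < self.alpha_trunc <= 1:
            raise ConfigError("alpha_trunc must be in (0, 1]")
        if list(self.stages) != sorted(set(self.stages)) or any(
            s <= 0 for s in self.stages
        ):
            raise ConfigError("stages must be strictly increasing positive counts")


@dataclass
class StageRecord:
    n_perm: int
    exceedances: int
    carried_forward: bool


@dataclass
class GeneTestResult:
    gene_id: str
    method: str
    observed_stat: float
    n_perm: int
    r_obs: int
    p_emp: float
    stage_trace: list[StageRecord] = field(default_factory=list)


def min_p(p_values: Iterable[float]) -> float:
    """Smallest single-SNP p-value in the gene."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise DomainError("min_p of an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    return float(p.min())


def truncated_product(p_values: Iterable[float], alpha_trunc: float = 0.01) -> float:
    """Log truncated product: Σ log p over p ≤ alpha_trunc (inclusive).

    Returns 0.0 when no p-value qualifies (empty product = 1).
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    sel = p[p <= alpha_trunc]
    if sel.size == 0:
        return 0.0
    return float(np.log(sel).sum())


def zaykin_analytic_p(
    trunc_prod_stat: float, k_snps: int, alpha_trunc: float = 0.01
) -> float:
    """Tail probability of the truncated product under independence.

    For k independent Uniform(0,1) p-values and threshold τ, the probability
    that the truncated product W is at most w = exp(stat) is

        P(W ≤ w) = Σ_{r=1..k} C(k,r) (1−τ)^{k−r} ×
                   { τ^r                                   if w > τ^r
                     w · Σ_{s=0}^{r−1} (r ln τ − ln w)^s / s!   otherwise }

    with W = 1 when no p-value falls below τ, so stat = 0 gives p = 1.
    Serves as an independence-case oracle for the permutation calibration.
    """
    if k_snps <= 0:
        raise DomainError("k_snps must be positive")
    if trunc_prod_stat > 0:
        raise DomainError("truncated-product statistic is a log product, must be ≤ 0")
    if trunc_prod_stat == 0.0:
        return 1.0
    log_w = trunc_prod_stat
    log_tau = math.log(alpha_trunc)
    log_terms = []
    for r in range(1, k_snps + 1):
        log_c = (
            gammaln(k_snps + 1) - gammaln(r + 1) - gammaln(k_snps - r + 1)
        )
        if k_snps - r == 0:
            log_pref = log_c
        elif alpha_trunc == 1.0:
            continue  # (1−τ)^(k−r) vanishes
        else:
            log_pref = log_c + (k_snps - r) * math.log1p(-alpha_trunc)
        if log_w > r * log_tau:
            log_body = r * log_tau
        else:
            x = r * log_tau - log_w  # ≥ 0
            s = np.arange(r)
            with np.errstate(divide="ignore"):
                log_series = np.where(
                    (s == 0), 0.0, s * np.log(x if x > 0 else 1.0) - gammaln(s + 1)
                )
            if x == 0:
                log_sum = 0.0
            else:
                log_sum = logsumexp(log_series)
            log_body = log_w + log_sum
        log_terms.append(log_pref + log_body)
    return float(min(1.0, math.exp(logsumexp(np.array(log_terms)))))


# ---------------------------------------------------------------------------
# Adaptive permutation
# ---------------------------------------------------------------------------

def _count(r_stats: np.ndarray, observed: float, count_ties: bool) -> int:
    # smaller is more significant for both gene statistics
    return int((r_stats <= observed).sum() if count_ties else (r_stats < observed).sum())


def adaptive_permutation(
    gene_id: str,
    method: str,
    observed_stat: float,
    replicate_stat_stream: Iterator[float],
    config: GeneTestConfig | None = None,
) -> GeneTestResult:
    """Staged empirical significance for one gene and one method.

    The stream yields the gene statistic on successive null replicates
    (smaller = more significant).  At each stage the cumulative exceedance
    count r is checked: with r at or above the carry-forward cap the
    procedure stops and reports p_emp = (r+1)/(n+1) at that stage; otherwise
    the gene is carried to the next stage.  Exhausting the stream before a
    stage count is an engine error.
    """
    config = config or GeneTestConfig()
    if method not in METHODS:
        raise ConfigError(f"unknown gene test method {method!r}")
    r = 0
    n_done = 0
    trace: list[StageRecord] = []
    for stage_n in config.stages:
        while n_done < stage_n:
            try:
                stat = next(replicate_stat_stream)
            except StopIteration:
                raise DomainError(
                    f"replicate stream exhausted at {n_done} < stage {stage_n}"
                ) from None
            n_done += 1
            if (stat <= observed_stat) if config.count_ties else (stat < observed_stat):
                r += 1
        carried = r < config.carry_forward_max_exceedances
        trace.append(StageRecord(stage_n, r, carried))
        if not carried:
            break
    trace[-1].carried_forward = False
    return GeneTestResult(
        gene_id=gene_id,
        method=method,
        observed_stat=observed_stat,
        n_perm=n_done,
        r_obs=r,
        p_emp=(r + 1) / (n_done + 1),
        stage_trace=trace,
    )


def adaptive_gene_scan(
    observed: dict[str, dict[str, float]],
    replicate_stats: Callable[[int], dict[str, dict[str, float]]],
    config: GeneTestConfig | None = None,
) -> list[GeneTestResult]:
    """Joint staged scan over many genes sharing one replicate stream.

    ``observed[gene][method]`` holds observed statistics;
    ``replicate_stats(i)`` returns the same structure for replicate ``i``.
    One replicate serves every gene at a given index (whole-dataset drops),
    and replicate generation stops as soon as no (gene, method) pair needs
    more — the computational point of adaptive staging.
    """
    config = config or GeneTestConfig()
    active = {(g, m) for g in observed for m in observed[g]}
    counts = {key: 0 for key in active}
    traces: dict[tuple[str, str], list[StageRecord]] = {key: [] for key in active}
    finished: dict[tuple[str, str], tuple[int, int]] = {}
    n_done = 0
    for stage_n in config.stages:
        if not active:
            break
        while n_done < stage_n:
            stats = replicate_stats(n_done)
            n_done += 1
            for g, m in active:
                stat = stats[g][m]
                obs = observed[g][m]
                if (stat <= obs) if config.count_ties else (stat < obs):
                    counts[(g, m)] += 1
        stopped = set()
        for key in active:
            r = counts[key]
            carried = r < config.carry_forward_max_exceedances
            last_stage = stage_n == config.stages[-1]
            traces[key].append(StageRecord(stage_n, r, carried and not last_stage))
            if not carried or last_stage:
                finished[key] = (r, stage_n)
                stopped.add(key)
        active -= stopped
    results = []
    for (g, m), (r, n) in finished.items():
        results.append(
            GeneTestResult(
                gene_id=g,
                method=m,
                observed_stat=observed[g][m],
                n_perm=n,
                r_obs=r,
                p_emp=(r + 1) / (n + 1),
                stage_trace=traces[(g, m)],
            )
        )
    return results
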