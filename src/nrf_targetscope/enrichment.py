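"""Gene-set enrichment: running-sum GSEA with a permutation null, and
hypergeometric over-representation analysis (ORA).

The enrichment score walks a ranked gene list; genes in the set ("hits")
increment the running sum by |metric|**weight_exponent normalized by the sum
over hits, genes outside it decrement by 1/(N - N_hit), and the ES is the
signed maximum deviation. Nominal p-values come from a gene-label permutation
null (random same-size sets), sign-stratified, with additive smoothing so p is
never exactly 0; NES divides the ES by the mean |null ES| of the same sign.

ORA is the standard one-sided hypergeometric upper tail with
Benjamini-Hochberg correction across the supplied term list; the DAVID-style
EASE variant (k - 1) is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential_expression import DifferentialResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class RankedList:
    """Genes ordered best-to-worst with their (signed, finite) metric values."""

    gene_ids: list[str]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.gene_ids) != self.metrics.size:
            raise ValueError("gene_ids and metrics must be aligned")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if not np.isfinite(self.metrics).all():
            raise ValueError("metric values must be finite")
        if np.any(np.diff(self.metrics) > 0):
            raise ValueError("metrics must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_nominal: float
    n_permutations: int
    leading_edge: list[str]
    running_sum: np.ndarray | None = None


@dataclass
class ORAResult:
    term: str
    k: int       # overlap
    K: int       # term size (within background)
    n: int       # query size
    N: int       # background size
    p_value: float
    q_value: float = float("nan")


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def rank_genes(
    results: Sequence[DifferentialResult], metric: str = "t_stat"
) -> RankedList:
    """Rank DE results by ``t_stat`` or ``signed_logp`` (sign(log2FC)*-log10 p).

    Descending metric order; exact ties break lexicographically on gene id so
    the ranking is deterministic.
    """
    if not results:
        raise ValueError("no results to rank")
    if metric == "t_stat":
        values = np.array([r.t_stat for r in results])
    elif metric == "signed_logp":
        p = np.array([r.p_value for r in results])
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        values = np.sign([r.log2fc for r in results]) * (-np.log10(p))
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    if not np.isfinite(values).all():
        raise ValueError("non-finite ranking metric")
    genes = [r.gene_id for r in results]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in DE results")
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    return RankedList([genes[i] for i in order], values[order])


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def _hit_mask(ranked: RankedList, members: Iterable[str]) -> np.ndarray:
    members = set(members)
    return np.array([g in members for g in ranked.gene_ids], dtype=bool)


def _running_sum(
    metrics: np.ndarray, hit: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Running sum over one ranking (1-D) or a stack of hit masks (2-D)."""
    hit = np.atleast_2d(hit)
    n = hit.shape[1]
    n_hit = hit.sum(axis=1)
    w = np.abs(metrics) ** weight_exponent if weight_exponent != 0 else np.ones(n)
    hw = np.where(hit, w[None, :], 0.0)
    sums = hw.sum(axis=1)
    # All-zero hit weights (e.g. every hit metric is 0 at weight>0) fall back
    # to equal weighting so the score stays defined.
    zero = sums == 0
    if zero.any():
        hw[zero] = hit[zero].astype(float)
        sums[zero] = n_hit[zero]
    step = hw / sums[:, None] - (~hit) / (n - n_hit)[:, None]
    return np.cumsum(step, axis=1)


#: Tolerance for ties between the positive and negative running-sum extrema.
#: Exact ties are structural (after the final hit the sum equals
#: 1 - n_remaining_misses/(N - N_hit) independent of the weights), so the
#: tie-break must be robust to accumulation order; ties resolve positive.
_ES_TIE_TOL = 1e-9


def _es_from_running(running: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = running.max(axis=1)
    neg = running.min(axis=1)
    use_pos = pos >= -neg - _ES_TIE_TOL
    es = np.where(use_pos, pos, neg)
    idx = np.where(use_pos, np.argmax(running, axis=1), np.argmin(running, axis=1))
    return es, idx


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum and leading edge for one gene set.

    The leading edge contains the hit genes at or before the running-sum
    extremum for positive ES, and at or after it for negative ES.
    """
    hit = _hit_mask(ranked, gene_set.members)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError(f"gene set {gene_set.name!r} is disjoint from the ranked universe")
    if n_hit == len(ranked):
        raise ValueError(f"gene set {gene_set.name!r} covers the whole ranked universe")
    running = _running_sum(ranked.metrics, hit, weight_exponent)[0]
    es_arr, idx_arr = _es_from_running(running[None, :])
    es, idx = float(es_arr[0]), int(idx_arr[0])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit[i] and i >= idx]
    return es, running, leading


def gsea_permutation(
    ranked: RankedList,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """GSEA with a gene-label permutation null.

    Null ES values come from random same-size gene sets; the nominal p is the
    sign-stratified, additively smoothed tail fraction
    (1 + #{null same-signed, |null| >= |obs|}) / (1 + #{null same-signed}),
    and NES = ES / mean(|null ES| of the same sign).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    es, running, leading = enrichment_score(ranked, gene_set, weight_exponent)

    n = len(ranked)
    m = int(_hit_mask(ranked, gene_set.members).sum())
    rng = np.random.default_rng(seed)
    # Random m-subsets via partial argsort of uniform keys, vectorized.
    keys = rng.random((n_permutations, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null_hits = np.zeros((n_permutations, n), dtype=bool)
    null_hits[np.arange(n_permutations)[:, None], idx] = True
    null_run = _running_sum(ranked.metrics, null_hits, weight_exponent)
    null_es, _ = _es_from_running(null_run)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    n_extreme = int((same_sign & (np.abs(null_es) >= abs(es))).sum())
    if n_same == 0:
        logger.warning(
            "gene set %r: no same-signed null ES draws; p reported as guard value",
            gene_set.name,
        )
        nes = float("nan")
    else:
        nes = float(es / np.mean(np.abs(null_es[same_sign])))
    p = (1 + n_extreme) / (1 + n_same)
    return EnrichmentResult(
        name=gene_set.name,
        es=es,
        nes=nes,
        p_nominal=float(p),
        n_permutations=n_permutations,
        leading_edge=leading,
        running_sum=running,
    )


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


def ora_test(
    query: Iterable[str],
    terms: Sequence[GeneSet],
    background: Iterable[str],
    ease: bool = False,
) -> list[ORAResult]:
    """One-sided hypergeometric over-representation of ``query`` in each term.

    Every term is intersected with the background before testing; terms
    disjoint from the background are skipped (logged). ``ease=True`` applies
    the DAVID/EASE conservative variant (overlap reduced by one). q-values are
    Benjamini-Hochberg across the tested terms.
    """
    background = set(background)
    query = set(query)
    if not background or not query:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")

    N, n = len(background), len(query)
    out: list[ORAResult] = []
    for term in terms:
        members = term.members & background
        if not members:
            logger.info("term %r skipped (reason=disjoint_from_background)", term.name)
            continue
        K = len(members)
        k = len(members & query)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        out.append(ORAResult(term=term.name, k=k, K=K, n=n, N=N, p_value=min(p, 1.0)))
    if out:
        q = multipletests([r.p_value for r in out], method="fdr_bh")[1]
        for r, qv in zip(out, q):
            r.q_value = float(qv)
    return out
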