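"""Gene-set enrichment statistics.

Three flavours used in screen follow-up:

* one-sided Fisher's exact test of a hit list against a target set within a
  universe, with the fold enrichment ``(a/n) / (K/N)``;
* the same test against a background *proportion* only (binomial tail),
  for targets such as a cancer-gene census where only the genome-wide
  percentage (e.g. 3.3%) is quoted;
* batch right-sided hypergeometric tests over a GMT collection with
  Bonferroni or BH correction;
* the EASE score: a conservative jackknifed Fisher p computed after
  removing one gene from the overlap cell (a=1 gives p=1 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DropscreenError
from .screen_model import GeneSet
from .diff_repr import bh_adjust


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment outcome: overlap a of n hits vs K of N universe genes."""

    set_name: str
    a: int                # hits ∩ set
    n: int                # hits
    K: int                # set ∩ universe (or -1 in proportion mode)
    N: int                # universe (or -1 in proportion mode)
    fold: float
    p: float
    p_adjusted: float = float("nan")
    method: str = "fisher"
    background: float = float("nan")  # proportion-mode background

    def __post_init__(self) -> None:
        if self.K >= 0 and not 0 <= self.a <= min(self.n, self.K):
            raise DropscreenError("overlap a must satisfy 0 <= a <= min(n, K)")
        if not (np.isnan(self.p) or 0 <= self.p <= 1):
            raise DropscreenError("p must lie in [0, 1]")


def _hypergeom_sf(a, N: int, K: int, n: int):
    """Right tail P(X >= a) for X ~ Hypergeom(N, K, n); ``a`` may be an array."""
    out = stats.hypergeom.sf(np.asarray(a) - 1, N, K, n)
    return float(out) if np.ndim(a) == 0 else out


def fisher_enrichment(
    hits: GeneSet | Iterable[str],
    universe: GeneSet | Iterable[str],
    target: GeneSet,
    background_proportion: float | None = None,
) -> EnrichmentResult:
    """One-sided (greater) enrichment of ``hits`` in ``target``.

    With a full universe the p-value is the hypergeometric tail
    P(X >= a | N, K, n) and fold = (a/n)/(K/N).  If
    ``background_proportion`` is given instead, the target's universe size
    is unknown: fold = (a/n)/prop and the tail is binomial — an
    approximation, tagged ``method="binomial"`` in the result.
    """
    hit_set = set(hits.genes if isinstance(hits, GeneSet) else map(str.upper, hits))
    uni_set = set(
        universe.genes if isinstance(universe, GeneSet) else map(str.upper, universe)
    )
    if not hit_set or not uni_set:
        raise DropscreenError("hits and universe must be non-empty")
    stray = hit_set - uni_set
    if stray:
        raise DropscreenError(f"hits not contained in universe: {sorted(stray)[:5]}")
    target_in_universe = target.genes & uni_set
    a = len(hit_set & target_in_universe)
    n = len(hit_set)
    if background_proportion is not None:
        if not 0 < background_proportion < 1:
            raise DropscreenError("background proportion must be in (0, 1)")
        fold = (a / n) / background_proportion
        p = float(stats.binom.sf(a - 1, n, background_proportion))
        return EnrichmentResult(
            target.name, a, n, -1, -1, fold, p,
            method="binomial", background=background_proportion,
        )
    K = len(target_in_universe)
    N = len(uni_set)
    fold = (a / n) / (K / N) if K else float("nan")
    p = _hypergeom_sf(a, N, K, n) if K else 1.0
    return EnrichmentResult(target.name, a, n, K, N, fold, p, method="fisher")


def hypergeom_rightsided_batch(
    hits: GeneSet | Iterable[str],
    universe: GeneSet | Iterable[str],
    collection: Sequence[GeneSet],
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Right-sided hypergeometric test per set with multiplicity correction.

    Sets with zero overlap with the universe are tested with K=0 (p = 1).
    Bonferroni: ``p_adj = min(1, m p)`` with m the number of sets tested;
    ``"bh"`` applies the step-up adjustment instead.
    """
    if not collection:
        raise DropscreenError("empty gene-set collection")
    if correction not in {"bonferroni", "bh"}:
        raise DropscreenError(f"unknown correction {correction!r}")
    results = [fisher_enrichment(hits, universe, gs) for gs in collection]
    ps = np.array([r.p for r in results])
    if correction == "bonferroni":
        adj = np.minimum(ps * len(results), 1.0)
    else:
        adj = bh_adjust(ps)
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.method += f"+{correction}"
    return results


def ease_score(a: int, n: int, K: int, N: int) -> float:
    """Jackknifed Fisher p: the hypergeometric tail with ``a`` replaced by ``a-1``.

    Penalises single-gene overlaps: a=1 returns 1 by convention; a=0 is an
    error (there is no enrichment to penalise).
    """
    if a < 1:
        raise DropscreenError("EASE score requires at least one overlapping gene")
    if not a <= min(n, K) or K > N or n > N:
        raise DropscreenError("inconsistent 2x2 margins for EASE score")
    if a == 1:
        return 1.0
    return _hypergeom_sf(a - 1, N, K, n)
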