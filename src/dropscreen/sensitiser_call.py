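"""Gene-level hit calling and cross-screen set logic.

A gene is *depleted* under a treatment if enough of its hairpins drop out
independently: at least 50% of its (post-filter) hairpins OR a minimum of 3
hairpins significant (FDR <= 0.05) with negative log2FC, and the median
log2FC of those significant hairpins below zero.  A *sensitiser* must
additionally have median log2FC <= -1.  Both branches of the "50% or 3"
rule suffice on their own; the 50% branch uses a ceiling on the hairpin
count.  Ligand-specific sets subtract genes depleted under vehicle (DMSO),
and cross-screen comparison produces Venn counts, per-ligand intersections
and the "key genes" present for both ligands in every screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DropscreenError
from .screen_model import ShRNALibrary

CLASSES = ("untested", "not_called", "depleted", "sensitiser")


@dataclass
class GeneCall:
    """Aggregated verdict for one gene under one contrast."""

    gene: str
    contrast: str
    n_hairpins: int
    n_sig_depleted: int
    median_log2fc: float
    classification: str

    def __post_init__(self) -> None:
        if self.n_sig_depleted > self.n_hairpins:
            raise DropscreenError("n_sig_depleted cannot exceed n_hairpins")
        if self.classification not in CLASSES:
            raise DropscreenError(f"unknown classification {self.classification!r}")


def call_gene(
    hairpin_rows: pd.DataFrame,
    alpha: float = 0.05,
    frac: float = 0.5,
    min_n: int = 3,
    fc_cut: float = -1.0,
    median_over: str = "significant",
) -> GeneCall:
    """Apply the "50% or 3 hairpins" rule to one gene's hairpin statistics.

    ``hairpin_rows`` is a slice of the differential table (columns ``fdr``
    and ``log2fc``; optionally ``gene``/``contrast`` for labelling).
    ``median_over`` selects the hairpins the median log2FC summarises:
    ``"significant"`` (the significantly depleted ones, the default) or
    ``"all"``.
    """
    if len(hairpin_rows) == 0:
        raise DropscreenError("empty hairpin slice for gene call")
    if median_over not in {"significant", "all"}:
        raise DropscreenError(f"unknown median_over mode {median_over!r}")
    gene = str(hairpin_rows["gene"].iloc[0]) if "gene" in hairpin_rows else ""
    contrast = (
        str(hairpin_rows["contrast"].iloc[0]) if "contrast" in hairpin_rows else ""
    )
    fdr = hairpin_rows["fdr"].to_numpy(dtype=float)
    lfc = hairpin_rows["log2fc"].to_numpy(dtype=float)
    sig = (fdr <= alpha) & (lfc < 0)
    n, n_sig = len(hairpin_rows), int(sig.sum())
    pool = lfc[sig] if median_over == "significant" else lfc
    median = float(np.median(pool)) if pool.size else float("nan")
    passes = (n_sig >= math.ceil(frac * n)) or (n_sig >= min_n)
    classification = "not_called"
    if n_sig > 0 and passes and median < 0:
        classification = "sensitiser" if median <= fc_cut else "depleted"
    return GeneCall(gene, contrast, n, n_sig, median, classification)


def classify_screen(
    dr: pd.DataFrame,
    lib: ShRNALibrary | None = None,
    alpha: float = 0.05,
    frac: float = 0.5,
    min_n: int = 3,
    fc_cut: float = -1.0,
    median_over: str = "significant",
) -> pd.DataFrame:
    """Gene calls for every gene x contrast in a differential table.

    Genes present in ``lib`` but absent from ``dr`` (all hairpins filtered)
    are reported as ``untested``.
    """
    if "gene" not in dr.columns:
        raise DropscreenError("differential table must carry a 'gene' column")
    rows = []
    for (contrast, gene), sub in dr.groupby(["contrast", "gene"], sort=True):
        call = call_gene(
            sub, alpha=alpha, frac=frac, min_n=min_n, fc_cut=fc_cut,
            median_over=median_over,
        )
        rows.append(
            {
                "gene": gene,
                "contrast": contrast,
                "n_hairpins": call.n_hairpins,
                "n_sig_depleted": call.n_sig_depleted,
                "median_log2fc": call.median_log2fc,
                "class": call.classification,
            }
        )
    calls = pd.DataFrame(rows)
    if lib is not None and len(calls):
        tested = set(calls["gene"])
        untested = [g for g in lib.genes if g not in tested]
        extra = [
            {
                "gene": g,
                "contrast": c,
                "n_hairpins": 0,
                "n_sig_depleted": 0,
                "median_log2fc": float("nan"),
                "class": "untested",
            }
            for c in calls["contrast"].unique()
            for g in untested
        ]
        if extra:
            calls = pd.concat([calls, pd.DataFrame(extra)], ignore_index=True)
    return calls


def genes_with_class(
    calls: pd.DataFrame, contrast: str, classes: Sequence[str] = ("sensitiser",)
) -> set[str]:
    """Genes carrying any of ``classes`` for a contrast (union across pools)."""
    mask = (calls["contrast"] == contrast) & calls["class"].isin(classes)
    return set(calls.loc[mask, "gene"])


def ligand_specific(
    ligand_sets: Mapping[str, set[str]], dmso_depleted: set[str]
) -> dict[str, set[str]]:
    """Subtract vehicle-depleted genes from each ligand's set (idempotent)."""
    return {name: set(s) - set(dmso_depleted) for name, s in ligand_sets.items()}


def venn_counts(named_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive region sizes of an n-set Venn diagram; they sum to |union|."""
    names = list(named_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(named_sets[n]) for n in names if n not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def overlap_percent(query: set, reference: set) -> float:
    """100 * |query ∩ reference| / |reference|."""
    if not reference:
        raise DropscreenError("reference set is empty")
    return 100.0 * len(set(query) & set(reference)) / len(reference)


def combine_and_intersect(
    screens: Mapping[str, Mapping[str, set[str]]],
    ligands: Sequence[str] = ("PDS", "PhenDC3"),
) -> dict:
    """Cross-screen summary: Venn counts, intersections, and key genes.

    ``screens`` maps screen name -> ligand -> sensitiser gene set.  The
    summary reports, per ligand, per-screen sets and their Venn regions;
    per screen, genes common to both ligands; and ``key_genes`` -- genes
    present for *both* ligands in *all* screens.
    """
    if not screens:
        raise DropscreenError("at least one screen is required")
    for name, per_ligand in screens.items():
        unknown = set(per_ligand) - set(ligands)
        if unknown:
            raise DropscreenError(f"screen {name!r}: unknown ligand(s) {sorted(unknown)}")
    summary: dict = {"ligands": {}, "per_screen_common": {}, "key_genes": set()}
    for lig in ligands:
        per_screen = {name: set(s.get(lig, set())) for name, s in screens.items()}
        union = set.union(*per_screen.values())
        inter = set.intersection(*per_screen.values())
        summary["ligands"][lig] = {
            "per_screen": per_screen,
            "union": union,
            "intersection": inter,
            "venn": venn_counts(per_screen),
        }
    for name, per_ligand in screens.items():
        summary["per_screen_common"][name] = set.intersection(
            *(set(per_ligand.get(lig, set())) for lig in ligands)
        )
    summary["key_genes"] = set.intersection(
        *(
            set(screens[name].get(lig, set()))
            for name in screens
            for lig in ligands
        )
    )
    return summary
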