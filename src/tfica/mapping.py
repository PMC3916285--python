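"""Map TF binding sites to putative target genes.

Each ChIP-Seq peak is assigned to the single nearest gene on its
chromosome, provided the gap between peak and gene does not exceed a
window (100 kb by default). Distance is the gap between the two
intervals -- zero when they overlap or abut -- measured boundary to
boundary with strand ignored. Ties are broken by smaller gap, then
lexicographic gene id, so the assignment is deterministic.

Per-TF target sets aggregate the assigned genes together with the best
(maximum) peak score seen for each gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WINDOW",
    "TargetSet",
    "assign_site_to_gene",
    "assign_sites",
    "build_target_sets",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class TargetSet:
    """Genes putatively regulated by one TF."""

    tf: str
    genes: frozenset[str]
    best_score_per_gene: dict[str, float]

    def __post_init__(self) -> None:
        if self.genes != frozenset(self.best_score_per_gene):
            raise ValueError("genes must equal the keys of best_score_per_gene")


def _validate_interval(start: int, end: int) -> None:
    if start < 0 or end <= start:
        raise ValueError(f"malformed interval [{start}, {end})")


def _gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Gap in bp between two 0-based half-open intervals; 0 on overlap/abutment."""
    return max(0, start2 - end1, start1 - end2)


def assign_site_to_gene(site, genes: pd.DataFrame,
                        window: int = DEFAULT_WINDOW,
                        use_tss: bool = False):
    """Assign one binding site to its nearest gene within ``window``.

    Parameters
    ----------
    site : mapping with keys chrom, start, end (0-based half-open).
    genes : gene-model table (chrom, start, end, strand, gene_id).
    use_tss : measure distance to the transcription start site instead
        of the gene boundaries (strand-aware point position).

    Returns (gene_id, distance) or None when no gene on the site's
    chromosome lies within the window.
    """
    chrom, start, end = site["chrom"], int(site["start"]), int(site["end"])
    _validate_interval(start, end)
    cand = genes[genes["chrom"] == chrom]
    if cand.empty:
        return None
    gs = cand["start"].to_numpy()
    ge = cand["end"].to_numpy()
    if use_tss:
        tss = np.where(cand["strand"].to_numpy() == "+", gs, ge - 1)
        gs, ge = tss, tss + 1
    gaps = np.maximum(0, np.maximum(gs - end, start - ge))
    best = gaps.min()
    if best > window:
        return None
    ids = cand["gene_id"].to_numpy()[gaps == best]
    return str(np.sort(ids)[0]), int(best)


def assign_sites(sites: pd.DataFrame, genes: pd.DataFrame,
                 window: int = DEFAULT_WINDOW,
                 use_tss: bool = False) -> tuple[pd.DataFrame, int]:
    """Vectorised nearest-gene assignment for a whole peak table.

    Returns (assignments, n_skipped). Assignments has one row per site
    that found a gene: tf, gene_id, chrom, site_start, site_end,
    distance, score. Sites on chromosomes absent from the gene table
    are skipped with a warning; their count is returned.
    """
    if (sites["start"] >= sites["end"]).any() or (sites["start"] < 0).any():
        bad = sites[(sites["start"] >= sites["end"]) | (sites["start"] < 0)]
        raise ValueError(f"{len(bad)} malformed site intervals (end <= start or start < 0)")
    known = set(genes["chrom"])
    skipped = int((~sites["chrom"].isin(known)).sum())
    if skipped:
        logger.warning("skipping %d sites on chromosomes absent from the gene table",
                       skipped)
    out = []
    for chrom, chunk in sites[sites["chrom"].isin(known)].groupby("chrom", sort=True):
        cand = genes[genes["chrom"] == chrom].sort_values(["start", "gene_id"])
        gs = cand["start"].to_numpy()
        ge = cand["end"].to_numpy()
        if use_tss:
            tss = np.where(cand["strand"].to_numpy() == "+", gs, ge - 1)
            gs, ge = tss, tss + 1
        ids = cand["gene_id"].to_numpy()
        # order genes by id within equal gaps via lexicographic argsort later
        ss = chunk["start"].to_numpy()[:, None]
        se = chunk["end"].to_numpy()[:, None]
        gaps = np.maximum(0, np.maximum(gs[None, :] - se, ss - ge[None, :]))
        best = gaps.min(axis=1)
        ok = best <= window
        # deterministic tie-break: among minimal gaps pick smallest gene_id
        order = np.argsort(ids, kind="mergesort")
        gaps_sorted = gaps[:, order]
        ids_sorted = ids[order]
        pick = np.argmax(gaps_sorted == best[:, None], axis=1)
        chosen = ids_sorted[pick]
        sub = chunk.loc[ok, ["tf", "chrom", "start", "end", "score"]].copy()
        sub["gene_id"] = chosen[ok]
        sub["distance"] = best[ok]
        out.append(sub)
    if not out:
        assignments = pd.DataFrame(
            columns=["tf", "gene_id", "chrom", "site_start", "site_end",
                     "distance", "score"])
        return assignments, skipped
    res = pd.concat(out, ignore_index=True)
    res = res.rename(columns={"start": "site_start", "end": "site_end"})
    res = res[["tf", "gene_id", "chrom", "site_start", "site_end", "distance", "score"]]
    return (res.sort_values(["tf", "chrom", "site_start", "site_end", "gene_id"],
                            kind="mergesort").reset_index(drop=True), skipped)


def build_target_sets(sites: pd.DataFrame, genes: pd.DataFrame,
                      window: int = DEFAULT_WINDOW,
                      use_tss: bool = False) -> dict[str, TargetSet]:
    """Per-TF target sets from a peak table.

    The target set of a TF is the union of genes its sites map to; each
    gene carries the maximum peak score over the TF's sites assigned to
    it. TFs present in the peak table but with no mappable site yield
    an empty TargetSet.
    """
    tfs = sorted(sites["tf"].unique()) if len(sites) else []
    if sites.empty:
        return {}
    assignments, _ = assign_sites(sites, genes, window=window, use_tss=use_tss)
    result: dict[str, TargetSet] = {}
    best = assignments.groupby(["tf", "gene_id"])["score"].max()
    for tf in tfs:
        if tf in best.index.get_level_values(0):
            scores = best.loc[tf].to_dict()
        else:
            scores = {}
        result[tf] = TargetSet(tf=tf, genes=frozenset(scores),
                               best_score_per_gene=scores)
    return result
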