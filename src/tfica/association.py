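"""TF-module association by gene-set enrichment.

Every TF target set is tested against every module's member set with a
two-sided Fisher exact test on the 2x2 overlap table; p-values are
Benjamini-Hochberg adjusted across the full TF x module family and
associations with adjusted p below alpha (default 0.01) and odds ratio
above 1 are retained. Retained associations are tiered by how many TFs
share the module: high confidence when the module is associated with a
single TF, medium when with at most three, low otherwise.

Also provides the greedy module-explanation count (how many top TFs
account for a stated fraction of a module's TF-targetable genes) and
the shared-functional-annotation evaluation of TF-target pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .mapping import TargetSet

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "IcaModule",
    "modules_from_loadings",
    "fisher_enrichment",
    "bh_adjust",
    "associate_tf_modules",
    "assign_confidence",
    "greedy_module_explanation",
    "shared_annotation_evaluation",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table: in-both, set1-only, set2-only, neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None


@dataclass(frozen=True)
class IcaModule:
    """A data-driven expression module: member genes with real loadings."""

    module_id: str
    loadings: dict[str, float]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(g for g, w in self.loadings.items() if w != 0)


def modules_from_loadings(loadings: pd.DataFrame) -> dict[str, IcaModule]:
    """Build IcaModule objects from a gene x module loading matrix."""
    out = {}
    for mod in loadings.columns:
        col = loadings[mod]
        nz = col[col != 0]
        out[mod] = IcaModule(module_id=str(mod), loadings=nz.to_dict())
    return out


def fisher_enrichment(set1, set2, universe) -> EnrichmentResult:
    """Two-sided Fisher exact test of the overlap of two gene sets.

    The odds ratio is the sample cross-product ratio ad/bc, computed on
    Haldane-corrected cells (0.5 added to every cell) only when some
    cell is zero; the 95% CI comes from the normal approximation to the
    log odds ratio.
    """
    set1, set2, universe = set(set1), set(set2), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set1 <= universe or not set2 <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set1 & set2)
    b = len(set1 - set2)
    c = len(set2 - set1)
    d = len(universe) - a - b - c
    return fisher_from_table(ContingencyTable(a, b, c, d))


def fisher_from_table(table: ContingencyTable) -> EnrichmentResult:
    """Fisher test and odds-ratio CI from an explicit 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    # Haldane correction only where the sample OR ad/bc is undefined
    # (zero denominator); a zero numerator is a legitimate OR of 0.
    if b * c == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    or_ci = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo = float(np.exp(np.log(or_ci) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(or_ci) + 1.959963984540054 * se))
    return EnrichmentResult(table=table, odds_ratio=float(orr),
                            ci_low=lo, ci_high=hi, p=float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_tf_modules(target_sets: dict[str, TargetSet],
                         modules: dict[str, IcaModule],
                         universe,
                         alpha: float = 0.01,
                         family: str = "global",
                         keep_all: bool = False) -> pd.DataFrame:
    """Test every TF x module pair for target-set / membership overlap.

    Parameters
    ----------
    family : "global" adjusts across the full TF x module family (the
        default); "per_tf" adjusts within each TF's tests separately.
    keep_all : return all tested pairs with a ``retained`` flag instead
        of only the associations passing ``p_adj < alpha and OR > 1``.

    Returns a tidy frame (tf, module_id, n_overlap, n_targets,
    module_size, odds_ratio, ci_low, ci_high, p, p_adj[, retained])
    with confidence tiers attached by :func:`assign_confidence`.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not target_sets or not modules:
        raise ValueError("need at least one target set and one module")
    rows = []
    for tf in sorted(target_sets):
        tset = target_sets[tf].genes & universe
        for mod in sorted(modules):
            mset = modules[mod].members & universe
            res = fisher_enrichment(tset, mset, universe)
            rows.append({
                "tf": tf, "module_id": mod,
                "n_overlap": res.table.a, "n_targets": len(tset),
                "module_size": len(mset),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p,
            })
    df = pd.DataFrame(rows)
    if family == "global":
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    elif family == "per_tf":
        df["p_adj"] = df.groupby("tf")["p"].transform(
            lambda s: pd.Series(bh_adjust(s.to_numpy()), index=s.index))
    else:
        raise ValueError(f"unknown family {family!r}")
    df["retained"] = (df["p_adj"] < alpha) & (df["odds_ratio"] > 1)
    if not keep_all:
        df = df[df["retained"]].drop(columns="retained").reset_index(drop=True)
    df = assign_confidence(df)
    return df


def assign_confidence(associations: pd.DataFrame) -> pd.DataFrame:
    """Attach confidence tiers from per-module TF counts.

    A module associated with exactly one TF gives its association high
    confidence; with at most three, medium; otherwise low. When the
    frame carries a ``retained`` column, only retained rows count and
    non-retained rows get no tier.
    """
    df = associations.copy()
    if df.empty:
        df["confidence"] = pd.Series(dtype=object)
        return df
    mask = df["retained"] if "retained" in df else pd.Series(True, index=df.index)
    counts = df.loc[mask, "module_id"].value_counts()
    k = df["module_id"].map(counts).fillna(0)
    tier = np.where(k == 1, "high", np.where(k <= 3, "medium", "low"))
    df["confidence"] = np.where(mask, tier, None)
    return df


NOT_EXPLAINABLE = "not_explainable"


def greedy_module_explanation(module: IcaModule,
                              associated_tfs,
                              target_sets: dict[str, TargetSet],
                              threshold: float = 0.9):
    """How many top TFs account for a module's TF-targetable genes.

    The "possible" genes are the module members targeted by at least
    one associated TF. TFs are ranked once by the size of their overlap
    with the module (ties by TF id) and accumulated in that order until
    the union covers at least ``threshold`` of the possible genes.
    Returns the number of TFs added, or ``NOT_EXPLAINABLE`` when no
    associated TF targets any member.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    tfs = sorted(associated_tfs)
    if not tfs:
        return NOT_EXPLAINABLE
    members = module.members
    overlaps = {tf: members & target_sets[tf].genes for tf in tfs if tf in target_sets}
    possible = set().union(*overlaps.values()) if overlaps else set()
    if not possible:
        return NOT_EXPLAINABLE
    need = threshold * len(possible)
    ranked = sorted(overlaps, key=lambda tf: (-len(overlaps[tf]), tf))
    covered: set[str] = set()
    for i, tf in enumerate(ranked, start=1):
        covered |= overlaps[tf]
        if len(covered) >= need:
            return i
    return len(ranked)


def shared_annotation_evaluation(pairs: pd.DataFrame,
                                 annotation_map: dict[str, set],
                                 score_bins,
                                 subset_cols) -> tuple[pd.DataFrame, int]:
    """Fraction of TF-target pairs sharing >= 1 functional annotation.

    Sharing an annotation term is used as a proxy for a high-quality
    TF-target link; subsets of pairs (e.g. all targets vs module-derived
    vs high-confidence) are compared per peak-score bin with a
    two-proportion z-test against the first subset column.

    Parameters
    ----------
    pairs : frame with columns tf, gene_id, score plus one boolean
        column per subset named in ``subset_cols``.
    annotation_map : gene/TF -> set of annotation terms.
    score_bins : bin edges for ``score`` (passed to ``pd.cut``).

    Returns (per-bin results, number of pairs skipped because the TF
    has no annotation entry).
    """
    df = pairs.copy()
    known_tf = df["tf"].isin(annotation_map)
    skipped = int((~known_tf).sum())
    df = df[known_tf]
    shared = [
        bool(annotation_map.get(tf, set()) & annotation_map.get(g, set()))
        for tf, g in zip(df["tf"], df["gene_id"])
    ]
    df = df.assign(shared=shared, score_bin=pd.cut(df["score"], bins=score_bins))
    ref = subset_cols[0]
    rows = []
    for b, chunk in df.groupby("score_bin", observed=True):
        ref_chunk = chunk[chunk[ref]]
        for col in subset_cols:
            sub = chunk[chunk[col]]
            n = len(sub)
            prop = sub["shared"].mean() if n else np.nan
            if col != ref and n and len(ref_chunk):
                count = np.array([sub["shared"].sum(), ref_chunk["shared"].sum()])
                nobs = np.array([n, len(ref_chunk)])
                if (count == 0).all() or (count == nobs).all():
                    pz = 1.0
                else:
                    _, pz = proportions_ztest(count, nobs)
            else:
                pz = np.nan
            rows.append({"score_bin": str(b), "subset": col, "n_pairs": n,
                         "shared_fraction": prop, "p_vs_" + ref: pz})
    return pd.DataFrame(rows), skipped


def attach_adjusted(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Return copies of enrichment results with BH-adjusted p filled in."""
    adj = bh_adjust([r.p for r in results])
    return [replace(r, p_adj=float(q)) for r, q in zip(results, adj)]
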