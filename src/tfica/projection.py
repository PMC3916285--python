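"""Module expression projections and TF-module correlation validation.

A module's "expression" in a sample is the dot product of its member
genes' expression with their loadings. A TF-module association is
validated by the Spearman correlation between the TF gene's expression
and the module projection computed with the TF gene removed, so the TF
cannot correlate with itself.

Two naive baselines put the projection in context: the "best" module
(the TF's top-scoring bound genes) and the "matched" module (a random
sample of the TF's targets whose peak-score distribution matches that
of the module's bound genes). Naive gene sets are summarised by their
unweighted mean expression. An empirical null over all TF x module
correlations calibrates significance of the observed pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import IcaModule
from .mapping import TargetSet

__all__ = [
    "CorrelationResult",
    "project_module",
    "tf_module_correlation",
    "build_best_module",
    "build_matched_module",
    "compare_to_naive",
    "empirical_null_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def project_module(expr: pd.DataFrame, module: IcaModule,
                   exclude_gene: str | None = None) -> pd.Series:
    """Per-sample weighted sum of member-gene expression.

    ``exclude_gene`` removes one gene (typically the TF itself) from
    the sum before projecting.
    """
    genes = [g for g in sorted(module.members)
             if g != exclude_gene and g in expr.index]
    if not genes:
        raise ValueError(
            f"module {module.module_id}: no usable member genes in the matrix")
    w = np.array([module.loadings[g] for g in genes])
    vals = expr.loc[genes].to_numpy()
    return pd.Series(w @ vals, index=expr.columns, name=module.module_id)


def tf_module_correlation(expr: pd.DataFrame, tf_gene: str,
                          projection: pd.Series) -> CorrelationResult:
    """Spearman correlation between a TF gene's expression and a projection."""
    if tf_gene not in expr.index:
        raise KeyError(f"TF gene {tf_gene} not in expression matrix")
    x = expr.loc[tf_gene].to_numpy(dtype=float)
    y = projection.to_numpy(dtype=float)
    if len(x) != len(y):
        raise ValueError("projection length does not match sample count")
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(x))


def build_best_module(target_set: TargetSet, k: int) -> frozenset[str]:
    """The k targets with the highest best peak score (ties by gene id)."""
    if k > len(target_set.genes):
        raise ValueError(f"k={k} exceeds {len(target_set.genes)} available targets")
    ranked = sorted(target_set.best_score_per_gene.items(),
                    key=lambda kv: (-kv[1], kv[0]))
    return frozenset(g for g, _ in ranked[:k])


def build_matched_module(target_set: TargetSet, reference_scores,
                         seed: int | np.random.Generator = 0) -> list[str]:
    """Random targets matched to a reference peak-score distribution.

    The TF's full target-score distribution is cut into decile bins;
    for each reference score one gene is drawn without replacement from
    the bin containing it. An exhausted bin falls back to the nearest
    nonempty bin (logged). Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reference_scores = list(reference_scores)
    scores = target_set.best_score_per_gene
    if len(reference_scores) > len(scores):
        raise ValueError("more reference scores than available targets")
    all_scores = np.array(sorted(scores.values()))
    edges = np.quantile(all_scores, np.linspace(0, 1, 11))
    edges = np.unique(edges)  # degenerate score distributions collapse bins

    def bin_of(s: float) -> int:
        return int(np.clip(np.searchsorted(edges, s, side="right") - 1,
                           0, len(edges) - 2))

    bins: dict[int, list[str]] = {i: [] for i in range(len(edges) - 1)}
    for g in sorted(scores):
        bins[bin_of(scores[g])].append(g)
    chosen: list[str] = []
    for s in reference_scores:
        b = bin_of(s)
        if not bins[b]:
            nonempty = [i for i, gs in bins.items() if gs]
            b2 = min(nonempty, key=lambda i: (abs(i - b), i))
            logger.debug("matched-module: bin %d empty, falling back to bin %d", b, b2)
            b = b2
        idx = rng.integers(len(bins[b]))
        chosen.append(bins[b].pop(int(idx)))
    return chosen


def _abs_or_signed(r: float, absolute: bool) -> float:
    return abs(r) if absolute else r


def compare_to_naive(associations: pd.DataFrame,
                     expr: pd.DataFrame,
                     modules: dict[str, IcaModule],
                     target_sets: dict[str, TargetSet],
                     tf_genes: dict[str, str],
                     seed: int = 0,
                     naive: str = "matched",
                     tf_count_bins=(0, 1, 3, np.inf),
                     absolute: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Projection vs naive-module correlation, binned by TFs per module.

    For every retained (tf, module) pair: the projection correlation
    (TF gene excluded) is compared with the correlation of the TF gene
    against the mean expression of a naive gene set of the same size --
    "matched" (score-matched random targets) or "best" (top-scoring
    targets). A pair is a win when the projection's |rho| exceeds the
    naive |rho| (signed comparison with ``absolute=False``). Per bin of
    per-module TF counts: the win fraction with a binomial test against
    0.5 and a paired t-test on the r^2 values. Bins with fewer than 3
    pairs are flagged insufficient.

    Returns (per-pair frame, per-bin frame).
    """
    if naive not in ("matched", "best"):
        raise ValueError("naive must be 'matched' or 'best'")
    rng = np.random.default_rng(seed)
    counts = associations["module_id"].value_counts()
    pair_rows = []
    for _, row in associations.sort_values(["tf", "module_id"]).iterrows():
        tf, mod = row["tf"], row["module_id"]
        module = modules[mod]
        tf_gene = tf_genes[tf]
        tset = target_sets[tf]
        usable_members = [g for g in module.members if g in expr.index]
        k = min(len(usable_members), len(tset.genes))
        if k == 0:
            continue
        try:
            proj = project_module(expr, module, exclude_gene=tf_gene)
            r_t = tf_module_correlation(expr, tf_gene, proj).rho
        except ValueError:
            continue
        if naive == "best":
            naive_genes = sorted(build_best_module(tset, k))
        else:
            member_scores = [tset.best_score_per_gene[g] for g in usable_members
                             if g in tset.best_score_per_gene]
            ref = member_scores[:k] if member_scores else \
                list(tset.best_score_per_gene.values())[:k]
            naive_genes = build_matched_module(tset, ref, seed=rng)
        naive_genes = [g for g in naive_genes if g in expr.index and g != tf_gene]
        if not naive_genes:
            continue
        naive_proj = pd.Series(expr.loc[naive_genes].to_numpy().mean(axis=0),
                               index=expr.columns)
        try:
            r_n = tf_module_correlation(expr, tf_gene, naive_proj).rho
        except ValueError:
            continue
        pair_rows.append({
            "tf": tf, "module_id": mod, "n_tfs_in_module": int(counts[mod]),
            "rho_tfica": r_t, "rho_naive": r_n,
            "win": _abs_or_signed(r_t, absolute) > _abs_or_signed(r_n, absolute),
        })
    pairs = pd.DataFrame(pair_rows)
    bin_rows = []
    if not pairs.empty:
        pairs["bin"] = pd.cut(pairs["n_tfs_in_module"], bins=list(tf_count_bins))
        for b, chunk in pairs.groupby("bin", observed=True):
            n = len(chunk)
            if n < 3:
                bin_rows.append({"bin": str(b), "n_pairs": n, "win_fraction": np.nan,
                                 "binomial_p": np.nan, "paired_t_p": np.nan,
                                 "insufficient": True})
                continue
            wins = int(chunk["win"].sum())
            bp = stats.binomtest(wins, n, 0.5, alternative="greater").pvalue
            tt = stats.ttest_rel(chunk["rho_tfica"] ** 2, chunk["rho_naive"] ** 2)
            bin_rows.append({"bin": str(b), "n_pairs": n,
                             "win_fraction": wins / n, "binomial_p": float(bp),
                             "paired_t_p": float(tt.pvalue), "insufficient": False})
    return pairs, pd.DataFrame(bin_rows)


def empirical_null_correlations(expr: pd.DataFrame,
                                tf_genes: dict[str, str],
                                modules: dict[str, IcaModule],
                                observed_pairs,
                                alpha: float = 0.05) -> tuple[pd.DataFrame, int]:
    """z-transform observed TF-module correlations against the all-pairs null.

    The null distribution is the Spearman correlation of every TF gene
    against every module projection (TF gene excluded). Each observed
    (tf, module) pair's correlation is z-scored against the null mean
    and SD, with a two-sided normal p-value.

    Returns (per-pair frame with rho/z/p, count significant at alpha).
    """
    rhos = {}
    for tf in sorted(tf_genes):
        g = tf_genes[tf]
        for mod in sorted(modules):
            try:
                proj = project_module(expr, modules[mod], exclude_gene=g)
                rhos[(tf, mod)] = tf_module_correlation(expr, g, proj).rho
            except (ValueError, KeyError):
                continue
    if len(rhos) < 100:
        raise ValueError(f"only {len(rhos)} null correlations; need >= 100")
    null = np.array(list(rhos.values()))
    mu, sd = null.mean(), null.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("degenerate null variance")
    rows = []
    for tf, mod in observed_pairs:
        if (tf, mod) not in rhos:
            continue
        r = rhos[(tf, mod)]
        z = (r - mu) / sd
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"tf": tf, "module_id": mod, "rho": r, "z": float(z),
                     "p": float(p), "significant": bool(p < alpha)})
    df = pd.DataFrame(rows)
    n_sig = int(df["significant"].sum()) if not df.empty else 0
    return df, n_sig
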