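"""TF-TF cooperativity from shared associated modules.

Two TFs that regulate overlapping sets of expression modules are
candidate cooperating factors. Similarity between the module sets is
quantified by the Tanimoto (Jaccard) coefficient and by a
confidence-weighted variant that upweights modules associated with few
TFs: module i receives weight w_i = (N - N_TFi) / N, where N is the
total module count and N_TFi the number of TFs significantly
associated with module i (an alternative w_i = 1 / N_TFi is
selectable). Significance of the shared-module count is assessed by a
Fisher test against the N-module universe with BH correction over all
pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from .association import ContingencyTable, bh_adjust, fisher_from_table

__all__ = [
    "ModuleSetProfile",
    "tanimoto",
    "weighted_tanimoto",
    "profiles_from_associations",
    "module_tf_counts",
    "shared_module_enrichment",
    "build_tf_network",
    "evaluate_similarity_predictors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleSetProfile:
    """The modules significantly associated with one TF."""

    tf: str
    modules: frozenset[str]


def profiles_from_associations(associations: pd.DataFrame) -> dict[str, ModuleSetProfile]:
    """Per-TF module-set profiles from a retained-associations frame."""
    if "retained" in associations:
        associations = associations[associations["retained"]]
    out = {}
    for tf, chunk in associations.groupby("tf"):
        out[tf] = ModuleSetProfile(tf=tf, modules=frozenset(chunk["module_id"]))
    return out


def module_tf_counts(associations: pd.DataFrame, n_modules: int) -> dict[str, int]:
    """N_TFi: TFs significantly associated with each module."""
    if "retained" in associations:
        associations = associations[associations["retained"]]
    return associations["module_id"].value_counts().to_dict()


def tanimoto(a, b) -> float:
    """|A n B| / |A u B|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Tanimoto undefined for two empty sets")
    return len(a & b) / len(union)


def weighted_tanimoto(a, b, counts: dict[str, int], n_modules: int,
                      scheme: str = "complement") -> float:
    """Confidence-weighted Tanimoto over module sets.

    Weights decrease with the number of TFs associated with a module,
    so modules specific to few TFs dominate the similarity:

    - ``complement`` (default): w_i = (N - N_TFi) / N, replaced by 1/N
      when N_TFi = N so every weight stays positive;
    - ``inverse``: w_i = 1 / N_TFi.

    Reduces exactly to the simple Tanimoto when all N_TFi are equal.
    """
    a, b = set(a), set(b)
    union = sorted(a | b)
    if not union:
        raise ValueError("weighted Tanimoto undefined for two empty sets")
    missing = [m for m in union if m not in counts]
    if missing:
        raise ValueError(f"counts missing modules: {missing[:5]}")
    n = float(n_modules)
    if n < len(union):
        raise ValueError("n_modules smaller than the union of the sets")

    def weight(m: str) -> float:
        k = counts[m]
        if scheme == "complement":
            w = (n - k) / n
            return w if w > 0 else 1.0 / n
        if scheme == "inverse":
            if k <= 0:
                raise ValueError(f"module {m} has nonpositive TF count {k}")
            return 1.0 / k
        raise ValueError(f"unknown weighting scheme {scheme!r}")

    denom = sum(weight(m) for m in union)
    if denom <= 0:
        raise ValueError("zero weight denominator")
    num = sum(weight(m) for m in a & b)
    return num / denom


def shared_module_enrichment(profiles: dict[str, ModuleSetProfile],
                             n_modules: int,
                             alpha: float = 0.01,
                             scheme: str = "complement",
                             counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Score and test every unordered TF pair.

    Returns one row per pair with both similarities, the 2x2 overlap
    counts against the module universe, Fisher p and BH-adjusted p over
    all pairs, and a ``significant`` flag (p_adj < alpha and OR > 1).
    """
    tfs = sorted(profiles)
    if len(tfs) < 2:
        raise ValueError("need at least 2 TF profiles")
    if counts is None:
        counts = {}
        for prof in profiles.values():
            for m in prof.modules:
                counts[m] = counts.get(m, 0) + 1
    rows = []
    for tf1, tf2 in itertools.combinations(tfs, 2):
        s1, s2 = profiles[tf1].modules, profiles[tf2].modules
        if n_modules < len(s1 | s2):
            raise ValueError("n_modules smaller than a profile union")
        if not (s1 | s2):
            continue  # two empty profiles carry no evidence
        a = len(s1 & s2)
        b = len(s1 - s2)
        c = len(s2 - s1)
        d = n_modules - a - b - c
        res = fisher_from_table(ContingencyTable(a, b, c, d))
        rows.append({
            "tf1": tf1, "tf2": tf2,
            "tanimoto": tanimoto(s1, s2),
            "weighted_tanimoto": weighted_tanimoto(s1, s2, counts, n_modules,
                                                   scheme=scheme),
            "n_shared": a, "n_union": a + b + c,
            "odds_ratio": res.odds_ratio, "p": res.p,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no scorable TF pairs")
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p_adj"] < alpha) & (df["odds_ratio"] > 1)
    return df


def build_tf_network(edges: pd.DataFrame, mode: str = "threshold",
                     threshold: float = 0.2, k: int = 30) -> pd.DataFrame:
    """Select network edges by Tanimoto threshold or top-k ranking.

    Threshold mode keeps pairs with tanimoto > threshold (0.2 by
    default); top-k mode keeps the k highest-Tanimoto pairs, ties
    broken by weighted score then lexicographic pair.
    """
    if mode == "threshold":
        out = edges[edges["tanimoto"] > threshold]
        return out.sort_values(["tanimoto", "weighted_tanimoto", "tf1", "tf2"],
                               ascending=[False, False, True, True],
                               kind="mergesort").reset_index(drop=True)
    if mode == "topk":
        if k > len(edges):
            logger.warning("k=%d exceeds %d edges; returning all", k, len(edges))
            k = len(edges)
        ranked = edges.sort_values(
            ["tanimoto", "weighted_tanimoto", "tf1", "tf2"],
            ascending=[False, False, True, True], kind="mergesort")
        return ranked.head(k).reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_similarity_predictors(edge_table: pd.DataFrame,
                                   response: str,
                                   naive_cols: list[str],
                                   tfica_cols: list[str]) -> dict:
    """OLS of a validation response on naive and TFICA similarity scores.

    Fits ``response ~ naive_cols`` and ``response ~ naive_cols +
    tfica_cols`` and reports per-predictor coefficients with 95% CIs
    and p-values from the full model, plus the nested-model F-test for
    the added TFICA terms.
    """
    cols = list(naive_cols) + list(tfica_cols)
    x_full = sm.add_constant(edge_table[cols].astype(float))
    rank = np.linalg.matrix_rank(x_full.to_numpy())
    if rank < x_full.shape[1]:
        corr = edge_table[cols].astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    y = edge_table[response].astype(float)
    reduced = sm.OLS(y, sm.add_constant(edge_table[list(naive_cols)].astype(float))).fit()
    full = sm.OLS(y, x_full).fit()
    ftest = anova_lm(reduced, full)
    ci = full.conf_int()
    coef = pd.DataFrame({
        "beta": full.params, "ci_low": ci[0], "ci_high": ci[1],
        "p": full.pvalues,
    })
    return {
        "coefficients": coef,
        "f_stat": float(ftest["F"].iloc[1]),
        "f_p": float(ftest["Pr(>F)"].iloc[1]),
        "r2_reduced": float(reduced.rsquared),
        "r2_full": float(full.rsquared),
    }


def to_sif(edges: pd.DataFrame, relation: str = "cooperates_with") -> str:
    """Simple-interaction-format text for network viewers."""
    lines = [f"{r.tf1}\t{relation}\t{r.tf2}" for r in edges.itertuples()]
    return "\n".join(lines) + ("\n" if lines else "")
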