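"""Module-disease enrichment and the TF-disease network.

Disease gene sets (more than five genes each, mirroring curated
genome-wide association catalogues) are tested for overlap with every
module's member set; a TF is linked to a disease whenever at least one
module is significantly associated with both. The module-disease
significance cutoff is calibrated on labeled training associations by
maximising AUROC over a grid of FDR thresholds (the published analysis
settled on 0.15). Predictive performance is summarised by AUROC and by
AUROC50, the unnormalised partial area under the ROC curve restricted
to false-positive rates below 0.5.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .association import IcaModule, bh_adjust, fisher_enrichment

__all__ = [
    "filter_disease_sets",
    "associate_module_disease",
    "link_tf_disease",
    "high_confidence_filter",
    "calibrate_module_disease_threshold",
    "roc_metrics",
    "combine_predictors_logistic",
]

logger = logging.getLogger(__name__)

MIN_DISEASE_GENES = 5  # strictly more than this many genes required


def filter_disease_sets(diseases: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Long-format (disease_id, gene_id) table -> dict of qualifying sets.

    Diseases with 5 or fewer distinct genes are dropped.
    """
    out = {}
    for dis, chunk in diseases.groupby("disease_id"):
        genes = frozenset(chunk["gene_id"])
        if len(genes) > MIN_DISEASE_GENES:
            out[str(dis)] = genes
    return out


def associate_module_disease(modules: dict[str, IcaModule],
                             disease_sets: dict[str, frozenset[str]],
                             universe,
                             fdr: float = 0.15) -> pd.DataFrame:
    """Fisher test of every module x disease overlap, BH over the family.

    Disease genes absent from the universe are dropped (count logged);
    a disease falling to 5 or fewer in-universe genes is excluded.
    Returns a tidy frame with a ``significant`` flag at ``p_adj < fdr``
    and odds ratio > 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    usable: dict[str, frozenset[str]] = {}
    n_dropped = 0
    for dis, genes in disease_sets.items():
        inside = frozenset(genes & universe)
        n_dropped += len(genes) - len(inside)
        if len(inside) > MIN_DISEASE_GENES:
            usable[dis] = inside
    if n_dropped:
        logger.warning("dropped %d disease genes absent from the universe", n_dropped)
    if not usable or not modules:
        raise ValueError("no testable module x disease pairs")
    rows = []
    for mod in sorted(modules):
        mset = modules[mod].members & universe
        for dis in sorted(usable):
            res = fisher_enrichment(usable[dis], mset, universe)
            rows.append({
                "module_id": mod, "disease_id": dis,
                "n_overlap": res.table.a, "disease_size": len(usable[dis]),
                "module_size": len(mset),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p,
            })
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p_adj"] < fdr) & (df["odds_ratio"] > 1)
    return df


def link_tf_disease(tf_module_assocs: pd.DataFrame,
                    module_disease: pd.DataFrame) -> pd.DataFrame:
    """Join significant TF-module and module-disease associations.

    Each (tf, disease) pair sharing at least one significant module
    yields one row: the supporting modules, the best (minimum)
    module-disease adjusted p as the association score, and the odds
    ratio / adjusted p of that best supporting module-disease test.
    """
    tm = tf_module_assocs
    if "retained" in tm:
        tm = tm[tm["retained"]]
    md = module_disease[module_disease["significant"]]
    merged = tm[["tf", "module_id"]].merge(
        md[["module_id", "disease_id", "odds_ratio", "p_adj"]], on="module_id")
    if merged.empty:
        return pd.DataFrame(columns=["tf", "disease_id", "supporting_modules",
                                     "score", "odds_ratio", "p_adj"])
    rows = []
    for (tf, dis), chunk in merged.groupby(["tf", "disease_id"]):
        best = chunk.loc[chunk["p_adj"].idxmin()]
        rows.append({
            "tf": tf, "disease_id": dis,
            "supporting_modules": ",".join(sorted(chunk["module_id"])),
            "score": float(best["p_adj"]),
            "odds_ratio": float(best["odds_ratio"]),
            "p_adj": float(best["p_adj"]),
        })
    return (pd.DataFrame(rows)
            .sort_values(["tf", "disease_id"], kind="mergesort")
            .reset_index(drop=True))


def high_confidence_filter(assocs: pd.DataFrame,
                           stringent_or: float = 3.0,
                           stringent_p: float = 0.001,
                           fallback_p: float = 0.01) -> pd.DataFrame:
    """Stringent associations plus per-disease best fallbacks.

    Stringent: supporting-module odds ratio > 3 and adjusted p < 0.001.
    For each disease with no stringent hit, its single best association
    (minimum adjusted p) is added provided it meets adjusted p < 0.01
    and odds ratio > 1. The returned frame carries a ``stringent``
    boolean column.
    """
    df = assocs.copy()
    if df.empty:
        df["stringent"] = pd.Series(dtype=bool)
        return df
    df["stringent"] = (df["odds_ratio"] > stringent_or) & (df["p_adj"] < stringent_p)
    keep = df[df["stringent"]]
    covered = set(keep["disease_id"])
    fallback_rows = []
    for dis, chunk in df.groupby("disease_id"):
        if dis in covered:
            continue
        ok = chunk[(chunk["p_adj"] < fallback_p) & (chunk["odds_ratio"] > 1)]
        if ok.empty:
            continue
        fallback_rows.append(ok.loc[ok["p_adj"].idxmin()])
    if fallback_rows:
        keep = pd.concat([keep, pd.DataFrame(fallback_rows)], ignore_index=True)
    return (keep.sort_values(["disease_id", "tf"], kind="mergesort")
            .reset_index(drop=True))


def calibrate_module_disease_threshold(tf_module_assocs: pd.DataFrame,
                                       module_disease: pd.DataFrame,
                                       labeled: pd.DataFrame,
                                       candidate_fdrs) -> tuple[float, pd.DataFrame]:
    """Pick the module-disease FDR cutoff maximising training AUROC.

    ``labeled`` must contain tf, disease_id and a binary ``label``
    column. At each candidate FDR the module-disease significance flag
    is recomputed, TF-disease links rebuilt, and each labeled pair
    scored by the negated best adjusted p (pairs without a link score
    -1, the worst possible). Ties in AUROC resolve to the smaller FDR.

    Returns (optimal FDR, per-candidate AUROC table).
    """
    labels = labeled["label"].astype(int).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    rows = []
    for fdr in sorted(candidate_fdrs):
        md = module_disease.copy()
        md["significant"] = (md["p_adj"] < fdr) & (md["odds_ratio"] > 1)
        links = link_tf_disease(tf_module_assocs, md)
        score_map = {(r.tf, r.disease_id): -r.score for r in links.itertuples()}
        scores = np.array([
            score_map.get((t, d), -1.0)
            for t, d in zip(labeled["tf"], labeled["disease_id"])
        ])
        auroc, _ = roc_metrics(scores, labels)
        rows.append({"fdr": float(fdr), "auroc": auroc})
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["auroc"].idxmax()]  # idxmax takes first = smallest fdr
    return float(best["fdr"]), grid


def roc_metrics(scores, labels, normalized: bool = False) -> tuple[float, float]:
    """AUROC and AUROC50 (partial area over FPR in [0, 0.5]).

    AUROC uses the trapezoidal rule with midrank tie handling (so it
    equals the Mann-Whitney concordance probability). AUROC50 is the
    unnormalised partial area, ranging 0-0.5; ``normalized=True``
    divides by the 0.5 maximum. Constant scores give AUROC 0.5 with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUROC fixed at 0.5", stacklevel=2)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    # interpolate the curve at FPR = 0.5 and integrate the left part
    tpr_at_half = float(np.interp(0.5, fpr, tpr))
    mask = fpr <= 0.5
    fpr50 = np.append(fpr[mask], 0.5)
    tpr50 = np.append(tpr[mask], tpr_at_half)
    auroc50 = float(np.trapezoid(tpr50, fpr50))
    if normalized:
        auroc50 /= 0.5
    return auroc, auroc50


def combine_predictors_logistic(labeled: pd.DataFrame, base_col: str,
                                added_col: str) -> dict:
    """Logistic combination of two predictors with a likelihood-ratio test.

    Fits label ~ base and label ~ base + added; reports AUROCs of the
    single predictors and of the combined fitted probability, plus the
    LR chi-squared (1 df) for the added term.
    """
    import statsmodels.api as sm

    y = labeled["label"].astype(int).to_numpy()
    x0 = sm.add_constant(labeled[[base_col]].astype(float))
    x1 = sm.add_constant(labeled[[base_col, added_col]].astype(float))
    m0 = sm.Logit(y, x0).fit(disp=0)
    m1 = sm.Logit(y, x1).fit(disp=0)
    lr = 2 * (m1.llf - m0.llf)
    p = float(stats.chi2.sf(lr, df=1))
    auroc_base, _ = roc_metrics(labeled[base_col].to_numpy(), y)
    auroc_added, _ = roc_metrics(labeled[added_col].to_numpy(), y)
    auroc_comb, _ = roc_metrics(m1.predict(x1), y)
    return {
        "auroc_base": auroc_base, "auroc_added": auroc_added,
        "auroc_combined": auroc_comb, "lr_chi2": float(lr), "lr_p": p,
    }
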