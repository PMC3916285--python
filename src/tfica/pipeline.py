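"""End-to-end orchestration: peaks -> targets -> modules -> partners -> diseases.

``run_pipeline`` executes every stage in order on files named in a
:class:`tfica.io.RunConfig`, writes versioned CSV outputs plus a
machine-readable manifest (input checksums, seed, thresholds, stage
counts), and -- when a planted-truth JSON is supplied -- a recovery
report with the sensitivity and false-discovery proportion of each
stage. All randomness derives from the single config seed, so two runs
with the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as tio
from .association import associate_tf_modules, modules_from_loadings
from .disease import (associate_module_disease, filter_disease_sets,
                      high_confidence_filter, link_tf_disease)
from .mapping import build_target_sets
from .projection import compare_to_naive, empirical_null_correlations
from .similarity import (build_tf_network, profiles_from_associations,
                         shared_module_enrichment, to_sif)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: tio.RunConfig, outdir) -> dict:
    """Run every stage and write outputs + manifest under ``outdir``.

    Returns the manifest dictionary. Any stage failure aborts with the
    stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {"seed": config.seed,
                      "thresholds": {
                          "window": config.window,
                          "association_alpha": config.association_alpha,
                          "disease_fdr": config.disease_fdr,
                          "tanimoto_threshold": config.tanimoto_threshold,
                          "stringent_or": config.stringent_or,
                          "stringent_p": config.stringent_p,
                      },
                      "inputs": {}, "counts": {}}

    # ---- load inputs -----------------------------------------------------
    @_stage("load")
    def _load():
        paths = {"peaks": config.peaks, "genes": config.genes,
                 "loadings": config.loadings, "expression": config.expression,
                 "diseases": config.diseases, "cohort": config.cohort,
                 "cohort_labels": config.cohort_labels}
        for name, p in paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file for {name}: {p}")
            manifest["inputs"][name] = _sha256(p)
        return (tio.read_bed(config.peaks), tio.read_genes(config.genes),
                tio.read_loadings(config.loadings),
                tio.read_expression(config.expression),
                tio.read_diseases(config.diseases))

    peaks, genes, loadings, expression, diseases = _load()

    # ---- map targets -----------------------------------------------------
    @_stage("map-targets")
    def _map():
        return build_target_sets(peaks, genes, window=config.window)

    target_sets = _map()
    manifest["counts"]["sites"] = int(len(peaks))
    manifest["counts"]["tfs"] = len(target_sets)
    tio.write_target_sets(target_sets, outdir / "target_sets.tsv")

    # ---- associate TFs to modules ---------------------------------------
    @_stage("associate")
    def _associate():
        modules = modules_from_loadings(loadings)
        universe = sorted(set(genes["gene_id"]) & set(loadings.index))
        assoc = associate_tf_modules(target_sets, modules, universe,
                                     alpha=config.association_alpha)
        return modules, universe, assoc

    modules, universe, associations = _associate()
    manifest["counts"]["tf_module_associations"] = int(len(associations))
    associations.to_csv(outdir / "associations.csv", index=False,
                        float_format=tio.FLOAT_FMT)

    # ---- expression validation ------------------------------------------
    truth = tio.read_truth_json(config.truth) if config.truth else None
    tf_genes = (truth["tf_genes"] if truth
                else {tf: tf for tf in target_sets if tf in expression.index})

    @_stage("project")
    def _project():
        if not len(associations) or not tf_genes:
            return pd.DataFrame(), 0
        pairs = [(r.tf, r.module_id) for r in associations.itertuples()
                 if r.tf in tf_genes]
        try:
            return empirical_null_correlations(expression, tf_genes, modules, pairs)
        except ValueError:
            return pd.DataFrame(), 0

    correlations, n_corr_sig = _project()
    manifest["counts"]["correlation_significant"] = int(n_corr_sig)
    correlations.to_csv(outdir / "correlations.csv", index=False,
                        float_format=tio.FLOAT_FMT)

    @_stage("compare-naive")
    def _compare():
        if not len(associations) or not tf_genes:
            return pd.DataFrame(), pd.DataFrame()
        usable = associations[associations["tf"].isin(tf_genes)]
        return compare_to_naive(usable, expression, modules, target_sets,
                                tf_genes, seed=config.seed)

    naive_pairs, naive_bins = _compare()
    naive_pairs.to_csv(outdir / "naive_comparison_pairs.csv", index=False,
                       float_format=tio.FLOAT_FMT)
    naive_bins.to_csv(outdir / "naive_comparison_bins.csv", index=False,
                      float_format=tio.FLOAT_FMT)

    # ---- TF-TF similarity ------------------------------------------------
    @_stage("similarity")
    def _similarity():
        profiles = profiles_from_associations(associations)
        if len(profiles) < 2:
            return pd.DataFrame(), pd.DataFrame()
        edges = shared_module_enrichment(profiles, n_modules=loadings.shape[1])
        network = build_tf_network(edges, mode="threshold",
                                   threshold=config.tanimoto_threshold)
        return edges, network

    edges, network = _similarity()
    manifest["counts"]["tf_pairs_significant"] = (
        int(edges["significant"].sum()) if len(edges) else 0)
    edges.to_csv(outdir / "tf_edges.csv", index=False, float_format=tio.FLOAT_FMT)
    (outdir / "tf_network.sif").write_text(to_sif(network) if len(network) else "")

    # ---- diseases ---------------------------------------------------------
    @_stage("disease")
    def _disease():
        disease_sets = filter_disease_sets(diseases)
        if not disease_sets:
            return pd.DataFrame(), pd.DataFrame(), pd.DataFrame()
        md = associate_module_disease(modules, disease_sets, universe,
                                      fdr=config.disease_fdr)
        links = link_tf_disease(associations, md)
        hc = high_confidence_filter(links, stringent_or=config.stringent_or,
                                    stringent_p=config.stringent_p)
        return md, links, hc

    module_disease, tf_disease, high_conf = _disease()
    manifest["counts"]["module_disease_significant"] = (
        int(module_disease["significant"].sum()) if len(module_disease) else 0)
    manifest["counts"]["tf_disease_associations"] = int(len(tf_disease))
    module_disease.to_csv(outdir / "module_disease.csv", index=False,
                          float_format=tio.FLOAT_FMT)
    tf_disease.to_csv(outdir / "tf_disease.csv", index=False,
                      float_format=tio.FLOAT_FMT)
    high_conf.to_csv(outdir / "tf_disease_high_confidence.csv", index=False,
                     float_format=tio.FLOAT_FMT)

    # ---- recovery report (synthetic runs only) ----------------------------
    if truth is not None:
        recovery = _recovery_report(truth, associations, module_disease,
                                    tf_disease, target_sets)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest["recovery"] = recovery

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _recovery_report(truth: dict, associations: pd.DataFrame,
                     module_disease: pd.DataFrame, tf_disease: pd.DataFrame,
                     target_sets) -> dict:
    """Sensitivity / false-discovery proportion of each stage vs planted truth."""
    out: dict = {}
    planted_tm = {tuple(p) for p in truth.get("true_tf_module", [])}
    found_tm = {(r.tf, r.module_id) for r in associations.itertuples()}
    out["tf_module"] = _prf(planted_tm, found_tm)

    planted_md = {tuple(p) for p in truth.get("true_module_disease", [])}
    if len(module_disease):
        sig = module_disease[module_disease["significant"]]
        found_md = {(r.module_id, r.disease_id) for r in sig.itertuples()}
    else:
        found_md = set()
    out["module_disease"] = _prf(planted_md, found_md)

    planted_td = {(tf, dis) for tf, mod in planted_tm
                  for mod2, dis in planted_md if mod == mod2}
    found_td = ({(r.tf, r.disease_id) for r in tf_disease.itertuples()}
                if len(tf_disease) else set())
    out["tf_disease"] = _prf(planted_td, found_td)

    # target recovery pooled over TFs
    tp = fp = fn = 0
    for tf, genes in truth.get("true_targets", {}).items():
        found = target_sets[tf].genes if tf in target_sets else frozenset()
        tp += len(set(genes) & found)
        fp += len(found - set(genes))
        fn += len(set(genes) - found)
    out["targets"] = {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "false_discovery": fp / (tp + fp) if tp + fp else None,
    }
    return out


def _prf(planted: set, found: set) -> dict:
    tp = len(planted & found)
    return {
        "n_planted": len(planted), "n_found": len(found), "n_true_found": tp,
        "sensitivity": tp / len(planted) if planted else None,
        "false_discovery": (len(found) - tp) / len(found) if found else None,
    }
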