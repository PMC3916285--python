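"""Readers and writers for the interchange formats.

All tables are plain text: 6-column BED for peaks (TF name in column
4, peak score in column 5, 0-based half-open coordinates), TSV for
gene models / expression / diseases / labels, CSV for loadings and
result tables, GMT for annotation sets, JSON for the planted truth and
the run manifest. Every writer/reader pair round-trips its schema
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .mapping import TargetSet

__all__ = [
    "read_bed", "write_bed",
    "read_genes", "write_genes",
    "read_loadings", "write_loadings",
    "read_expression", "write_expression",
    "read_diseases", "write_diseases",
    "read_labels", "write_labels",
    "read_gmt", "write_gmt",
    "read_target_sets", "write_target_sets",
    "read_truth_json", "write_truth_json",
    "RunConfig",
]

FLOAT_FMT = "%.10g"


def read_bed(path) -> pd.DataFrame:
    """Parse a 6-column BED peak file into a binding-site table.

    Columns become chrom, start, end, tf, score, strand; track and
    browser lines are skipped. Malformed coordinates raise with the
    offending line number.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >= 5 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                score = float(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, parts[3], score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf",
                                       "score", "strand"])


def write_bed(peaks: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "tf", "score", "strand"]
    df = peaks[cols].copy()
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format=FLOAT_FMT)


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    need = {"chrom", "start", "end", "strand", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"gene table missing columns {need - set(df.columns)}")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_loadings(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_loadings(loadings: pd.DataFrame, path) -> None:
    loadings.to_csv(path, float_format=FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_diseases(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"disease_id", "gene_id"} <= set(df.columns):
        raise ValueError("disease table needs disease_id and gene_id columns")
    return df


def write_diseases(diseases: pd.DataFrame, path) -> None:
    diseases.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("label")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT annotation file -> term -> deduplicated gene set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(terms: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            fh.write("\t".join([term, term] + sorted(terms[term])) + "\n")


def write_target_sets(target_sets: dict[str, TargetSet], path) -> None:
    rows = [(tf, g, ts.best_score_per_gene[g])
            for tf, ts in sorted(target_sets.items()) for g in sorted(ts.genes)]
    pd.DataFrame(rows, columns=["tf", "gene_id", "best_score"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_target_sets(path) -> dict[str, TargetSet]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene_id": str})
    out = {}
    for tf, chunk in df.groupby("tf"):
        scores = dict(zip(chunk["gene_id"], chunk["best_score"].astype(float)))
        out[str(tf)] = TargetSet(tf=str(tf), genes=frozenset(scores),
                                 best_score_per_gene=scores)
    return out


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclasses.dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    peaks: str = "peaks.bed"
    genes: str = "genes.tsv"
    loadings: str = "loadings.csv"
    expression: str = "expression.tsv"
    diseases: str = "diseases.tsv"
    cohort: str = "cohort.tsv"
    cohort_labels: str = "labels.tsv"
    truth: str | None = None
    window: int = 100_000
    association_alpha: float = 0.01
    disease_fdr: float = 0.15
    tanimoto_threshold: float = 0.2
    stringent_or: float = 3.0
    stringent_p: float = 0.001
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        for name in ("association_alpha", "disease_fdr", "stringent_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 <= self.tanimoto_threshold <= 1:
            raise ValueError("tanimoto_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def resolve(config: RunConfig, workdir) -> RunConfig:
    """Return a copy of the config with relative paths anchored at workdir."""
    workdir = Path(workdir)
    updates = {}
    for f in ("peaks", "genes", "loadings", "expression", "diseases",
              "cohort", "cohort_labels", "truth"):
        v = getattr(config, f)
        if v is not None and not Path(v).is_absolute():
            updates[f] = str(workdir / v)
    return dataclasses.replace(config, **updates)
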