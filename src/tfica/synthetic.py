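"""Synthetic benchmark data with planted ground truth.

Every downstream stage of the pipeline (target mapping, TF-module
enrichment, expression projection, disease linking, cohort validation)
is exercised against data generated here, where the true TF target
sets, TF-module couplings, module-disease enrichments and
differentially expressed modules are known by construction.

The generator emulates the structure of the real inputs the method was
designed for -- ChIP-Seq peaks concentrated on true target genes,
sparse ICA-style module loadings with overlapping membership, a
log-scale expression compendium driven by latent module activities,
genome-wide disease gene sets, and a two-group case/control cohort --
without reproducing platform-level artifacts of any particular dataset.

All randomness flows from ``SyntheticConfig.seed``; each generator
derives its own independent stream from that seed, so the outputs are
byte-identical across runs and independent of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "SyntheticDataset",
    "generate_genes",
    "generate_module_loadings",
    "plant_truth",
    "generate_binding_sites",
    "generate_expression",
    "generate_disease_sets",
    "generate_cohort",
    "generate_dataset",
]

# fixed spawn keys: one independent stream per stage, all rooted at config.seed
_STAGE_KEYS = {
    "genes": 1,
    "loadings": 2,
    "truth": 3,
    "peaks": 4,
    "expr": 5,
    "disease": 6,
    "cohort": 7,
}


def _rng(config: "SyntheticConfig", stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


class SizingError(ValueError):
    """Requested genes cannot fit on the chromosomes at this density."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic universe.

    Counts and sizes default to a desk-scale analogue of the real study
    (hundreds of ENCODE factors, 423 modules, thousands of arrays):
    10 TFs x 20 modules x 300 compendium samples, 2,000 genes.

    Parameters
    ----------
    genes_per_module : (mean, sd) of the normal from which module sizes
        are drawn (clipped to [1, n_genes]).
    planted_tf_module_pairs : list of (tf_id, module_id, target_fraction);
        that fraction of the module's members becomes true targets of
        the TF, and the TF gene's expression is coupled to the module
        activity with Spearman-scale strength ``tf_module_coupling``.
    background_peak_rate : background peaks per Mb per TF, placed
        uniformly on the genome with un-shifted scores.
    score_shift : mean peak-score excess of true-target peaks over
        background peaks (background mean is ``base_peak_score``).
    disease_module_pairs : list of (disease_id, module_id,
        enriched_fraction); that fraction of the disease's gene set is
        drawn from the module's members.
    cohort_effect_size : standardized mean shift, in within-group SD
        units, applied to genes of the differentially expressed modules
        in the case group of the cohort.
    de_module_ids : modules planted as differentially expressed in the
        cohort; default: every module named in ``disease_module_pairs``.
    """

    n_chromosomes: int = 2
    n_genes: int = 2000
    n_tfs: int = 10
    n_modules: int = 20
    n_samples: int = 300
    genes_per_module: tuple[float, float] = (30.0, 5.0)
    planted_tf_module_pairs: tuple[tuple[str, str, float], ...] = ()
    background_peak_rate: float = 5.0
    score_shift: float = 3.0
    expr_noise_sd: float = 1.0
    tf_module_coupling: float = 0.6
    disease_module_pairs: tuple[tuple[str, str, float], ...] = ()
    cohort_effect_size: float = 1.0
    seed: int = 0
    # universe geometry and secondary knobs
    chromosome_length: int = 10_000_000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    peak_width: int = 200
    base_peak_score: float = 5.0
    extra_peaks_per_target: float = 0.5  # Poisson mean on top of the guaranteed peak
    n_background_targets: int = 30
    disease_set_size: int = 20
    n_cases: int = 50
    n_controls: int = 50
    de_module_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_genes", "n_tfs", "n_modules", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for tf, mod, frac in self.planted_tf_module_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"target_fraction for ({tf},{mod}) not in [0,1]: {frac}")
        for dis, mod, frac in self.disease_module_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"enriched_fraction for ({dis},{mod}) not in [0,1]: {frac}")
        if not -1.0 <= self.tf_module_coupling <= 1.0:
            raise ValueError("tf_module_coupling must lie in [-1, 1]")
        if self.expr_noise_sd < 0 or self.score_shift < 0:
            raise ValueError("expr_noise_sd and score_shift must be nonnegative")
        if self.disease_set_size <= 5:
            raise ValueError("disease_set_size must exceed 5")
        # normalise lists to tuples so the config is hashable/frozen
        object.__setattr__(self, "planted_tf_module_pairs",
                           tuple((t, m, float(f)) for t, m, f in self.planted_tf_module_pairs))
        object.__setattr__(self, "disease_module_pairs",
                           tuple((d, m, float(f)) for d, m, f in self.disease_module_pairs))
        if self.de_module_ids is not None:
            object.__setattr__(self, "de_module_ids", tuple(self.de_module_ids))

    # canonical identifier vocabularies -------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    def module_ids(self) -> list[str]:
        return [f"M{i:03d}" for i in range(self.n_modules)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic dataset."""

    true_targets: dict[str, frozenset[str]]
    true_tf_module: frozenset[tuple[str, str]]
    true_module_disease: frozenset[tuple[str, str]]
    true_de_modules: frozenset[str]
    tf_genes: dict[str, str]  # the gene encoding each TF in the expression data

    def to_dict(self) -> dict:
        return {
            "true_targets": {tf: sorted(g) for tf, g in sorted(self.true_targets.items())},
            "true_tf_module": sorted(list(p) for p in self.true_tf_module),
            "true_module_disease": sorted(list(p) for p in self.true_module_disease),
            "true_de_modules": sorted(self.true_de_modules),
            "tf_genes": dict(sorted(self.tf_genes.items())),
        }


@dataclass
class SyntheticDataset:
    """All generated inputs plus the planted truth."""

    config: SyntheticConfig
    genes: pd.DataFrame
    loadings: pd.DataFrame
    truth: PlantedTruth
    peaks: pd.DataFrame
    expression: pd.DataFrame
    activities: pd.DataFrame
    diseases: pd.DataFrame
    cohort: pd.DataFrame
    cohort_labels: pd.Series


def generate_genes(config: SyntheticConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals across the chromosomes.

    Returns a table with columns chrom, start, end, strand, gene_id,
    0-based half-open, sorted by (chrom, start); gene ids are assigned
    in genomic order.
    """
    rng = _rng(config, "genes")
    # round-robin distribution of genes over chromosomes
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    lo, hi = config.gene_length_range
    rows = []
    for c, k in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        slack = config.chromosome_length - int(lengths.sum())
        if slack < 0:
            raise SizingError(
                f"{k} genes of mean length {(lo + hi) / 2:.0f} bp do not fit on a "
                f"{config.chromosome_length} bp chromosome"
            )
        # spread the remaining bp over k+1 intergenic gaps
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        start = 0
        for j in range(k):
            start += int(gaps[j])
            end = start + int(lengths[j])
            rows.append((chrom, start, end))
            start = end
    strands = rng.choice(["+", "-"], size=len(rows))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genes["strand"] = strands
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    genes["gene_id"] = config.gene_ids()
    return genes[["chrom", "start", "end", "strand", "gene_id"]]


def generate_module_loadings(config: SyntheticConfig) -> pd.DataFrame:
    """Sparse gene x module loading matrix.

    Each module draws its size from N(mean, sd) (clipped to [1, n_genes]),
    samples members without replacement, and assigns loadings
    sign_m * |N(1, 0.25)| with the sign fixed per module so that the
    module projection has a coherent direction. Non-members get exact 0.
    """
    mean, sd = config.genes_per_module
    if mean > config.n_genes:
        raise ValueError("genes_per_module mean exceeds n_genes")
    rng = _rng(config, "loadings")
    gene_ids = config.gene_ids()
    mat = np.zeros((config.n_genes, config.n_modules))
    for j in range(config.n_modules):
        size = int(np.clip(np.round(rng.normal(mean, sd)), 1, config.n_genes))
        members = rng.choice(config.n_genes, size=size, replace=False)
        sign = rng.choice([-1.0, 1.0])
        mat[members, j] = sign * np.abs(rng.normal(1.0, 0.25, size=size))
    return pd.DataFrame(mat, index=gene_ids, columns=config.module_ids())


def plant_truth(genes: pd.DataFrame, loadings: pd.DataFrame,
                config: SyntheticConfig) -> PlantedTruth:
    """Draw the planted ground truth consistent with the module membership.

    For each planted (tf, module, fraction) pair, ``fraction * |module|``
    members (rounded) become true targets of the TF. Every TF
    additionally receives ``n_background_targets`` true targets sampled
    from the remaining genes, so its target set is never a pure module.
    Each TF is identified with a gene drawn from outside all module
    memberships (when possible) so the coupled expression signal does
    not collide with module structure.
    """
    rng = _rng(config, "truth")
    all_genes = list(loadings.index)
    member_union: set[str] = set(loadings.index[(loadings != 0).any(axis=1)])

    targets: dict[str, set[str]] = {tf: set() for tf in config.tf_ids()}
    planted_members: dict[str, set[str]] = {tf: set() for tf in config.tf_ids()}
    pairs = []
    for tf, mod, frac in config.planted_tf_module_pairs:
        if tf not in targets:
            raise ValueError(f"planted pair references unknown TF {tf}")
        if mod not in loadings.columns:
            raise ValueError(f"planted pair references unknown module {mod}")
        members = sorted(loadings.index[loadings[mod] != 0])
        planted_members[tf].update(members)
        k = int(round(frac * len(members)))
        if k > 0:
            chosen = rng.choice(members, size=k, replace=False)
            targets[tf].update(chosen)
            pairs.append((tf, mod))
    for tf in config.tf_ids():
        # background targets avoid the TF's planted modules entirely so the
        # planted overlap fraction is exact
        pool = [g for g in all_genes
                if g not in targets[tf] and g not in planted_members[tf]]
        k = min(config.n_background_targets, len(pool))
        targets[tf].update(rng.choice(pool, size=k, replace=False))

    # one gene per TF, preferentially outside every module
    non_members = sorted(set(all_genes) - member_union)
    pool = non_members if len(non_members) >= config.n_tfs else sorted(all_genes)
    tf_gene_choice = rng.choice(pool, size=config.n_tfs, replace=False)
    tf_genes = dict(zip(config.tf_ids(), tf_gene_choice))

    module_disease = frozenset(
        (mod, dis) for dis, mod, frac in config.disease_module_pairs if frac > 0
    )
    if config.de_module_ids is not None:
        de_modules = frozenset(config.de_module_ids)
    else:
        de_modules = frozenset(mod for dis, mod, frac in config.disease_module_pairs)

    return PlantedTruth(
        true_targets={tf: frozenset(g) for tf, g in targets.items()},
        true_tf_module=frozenset(pairs),
        true_module_disease=module_disease,
        true_de_modules=de_modules,
        tf_genes=tf_genes,
    )


def generate_binding_sites(genes: pd.DataFrame, truth: PlantedTruth,
                           config: SyntheticConfig) -> pd.DataFrame:
    """ChIP-Seq-like peak table (BED-sortable).

    Every true target gene of each TF receives at least one peak placed
    inside the gene body (hence within 100 kb of, and nearest to, the
    gene) with score ~ N(base + score_shift, 1); additional true peaks
    follow a Poisson count. Background peaks land uniformly on the
    genome at ``background_peak_rate`` per Mb per TF with scores
    ~ N(base, 1). Scores are clipped at 0.
    """
    if genes.empty:
        raise ValueError("empty gene table")
    rng = _rng(config, "peaks")
    gene_iv = genes.set_index("gene_id")
    chroms = sorted(genes["chrom"].unique())
    w = config.peak_width

    rows: list[tuple[str, int, int, str, float]] = []
    for tf in sorted(truth.true_targets):
        for g in sorted(truth.true_targets[tf]):
            iv = gene_iv.loc[g]
            n_peaks = 1 + rng.poisson(config.extra_peaks_per_target)
            hi = max(int(iv.start) + 1, int(iv.end) - w)
            starts = rng.integers(int(iv.start), hi, size=n_peaks)
            scores = rng.normal(config.base_peak_score + config.score_shift, 1.0,
                                size=n_peaks)
            for s, sc in zip(starts, scores):
                rows.append((str(iv.chrom), int(s), int(s) + w, tf, max(0.0, float(sc))))
        # uniform background peaks
        for chrom in chroms:
            n_bg = rng.poisson(config.background_peak_rate
                               * config.chromosome_length / 1e6)
            if n_bg == 0:
                continue
            starts = rng.integers(0, config.chromosome_length - w, size=n_bg)
            scores = rng.normal(config.base_peak_score, 1.0, size=n_bg)
            for s, sc in zip(starts, scores):
                rows.append((chrom, int(s), int(s) + w, tf, max(0.0, float(sc))))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf", "score"])
    peaks["strand"] = "."
    return (peaks.sort_values(["chrom", "start", "end", "tf"], kind="mergesort")
                 .reset_index(drop=True))


def generate_expression(loadings: pd.DataFrame, truth: PlantedTruth,
                        config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compendium expression: loadings @ activities + Gaussian noise.

    Module activities are i.i.d. standard normal over samples. For each
    planted (tf, module) pair the TF gene's row is replaced by
    ``rho * z(activity) + sqrt(1 - rho^2) * eps`` with
    rho = ``tf_module_coupling``, giving expected Pearson (and to good
    approximation Spearman) correlation rho with the module activity.
    A TF planted to several modules is coupled to the first listed.

    Returns (expression gene x sample, activities module x sample).
    """
    if list(loadings.columns) != config.module_ids():
        raise ValueError("loadings columns do not match the configured modules")
    rng = _rng(config, "expr")
    n_g, n_m = loadings.shape
    n_s = config.n_samples
    activities = rng.normal(0.0, 1.0, size=(n_m, n_s))
    noise = rng.normal(0.0, 1.0, size=(n_g, n_s)) * config.expr_noise_sd
    expr = loadings.to_numpy() @ activities + noise

    expr_df = pd.DataFrame(expr, index=loadings.index, columns=config.sample_ids())
    act_df = pd.DataFrame(activities, index=loadings.columns,
                          columns=config.sample_ids())

    rho = config.tf_module_coupling
    coupled: set[str] = set()
    for tf, mod, frac in config.planted_tf_module_pairs:
        if tf in coupled:
            continue
        coupled.add(tf)
        g = truth.tf_genes[tf]
        a = act_df.loc[mod].to_numpy()
        z = (a - a.mean()) / a.std()
        eps = rng.normal(0.0, 1.0, size=n_s)
        expr_df.loc[g] = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    return expr_df, act_df


def generate_disease_sets(loadings: pd.DataFrame, truth: PlantedTruth,
                          config: SyntheticConfig) -> pd.DataFrame:
    """Long-format disease-gene table (disease_id, gene_id).

    Each configured (disease, module, enriched_fraction) triple yields a
    gene set of size ``disease_set_size`` (> 5 by construction), with
    ``enriched_fraction`` of it drawn from the module's members and the
    remainder uniformly from all genes. The disease universe is the
    whole gene table, mirroring genome-wide association catalogues.
    """
    rng = _rng(config, "disease")
    universe = list(loadings.index)
    size = config.disease_set_size
    rows = []
    for dis, mod, frac in config.disease_module_pairs:
        members = sorted(loadings.index[loadings[mod] != 0])
        k = int(round(frac * size))
        if k > len(members):
            raise ValueError(
                f"disease {dis}: enriched_fraction*size = {k} exceeds module "
                f"{mod} size {len(members)}"
            )
        chosen: list[str] = list(rng.choice(members, size=k, replace=False)) if k else []
        pool = [g for g in universe if g not in set(chosen)]
        chosen += list(rng.choice(pool, size=size - k, replace=False))
        rows += [(dis, g) for g in sorted(chosen)]
    return pd.DataFrame(rows, columns=["disease_id", "gene_id"])


def generate_cohort(loadings: pd.DataFrame, truth: PlantedTruth,
                    config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group cohort with planted module-level differential expression.

    Baseline expression is i.i.d. N(0,1) per gene and sample (unit
    within-group SD, so ``cohort_effect_size`` is a standardized shift).
    Genes belonging to any module in ``truth.true_de_modules`` -- and the
    TF gene of every planted pair whose module is differentially
    expressed -- are shifted upward by the effect size in cases.

    Returns (expression gene x sample, labels Series of 'case'/'control').
    """
    if config.n_cases < 2 or config.n_controls < 2:
        raise ValueError("need at least 2 samples per group")
    if config.cohort_effect_size != 0 and not truth.true_de_modules:
        raise ValueError("cohort_effect_size != 0 requires planted DE modules")
    rng = _rng(config, "cohort")
    n = config.n_cases + config.n_controls
    sample_ids = [f"P{i:04d}" for i in range(n)]
    labels = pd.Series(["case"] * config.n_cases + ["control"] * config.n_controls,
                       index=sample_ids, name="label")

    x = rng.normal(0.0, 1.0, size=(loadings.shape[0], n))
    cohort = pd.DataFrame(x, index=loadings.index, columns=sample_ids)

    # the module's latent activity rises in cases: each member gene moves
    # by the effect size in the direction of its loading sign, so the
    # projection itself is shifted upward regardless of the module's
    # (arbitrary) overall sign
    shift: dict[str, float] = {}
    for mod in sorted(truth.true_de_modules):
        col = loadings[mod]
        for g in loadings.index[col != 0]:
            shift.setdefault(g, config.cohort_effect_size * np.sign(col[g]))
    for tf, mod, frac in config.planted_tf_module_pairs:
        if mod in truth.true_de_modules:
            shift.setdefault(truth.tf_genes[tf], config.cohort_effect_size)
    if shift:
        case_cols = (labels == "case").to_numpy()
        genes_hit = [g for g in cohort.index if g in shift]
        delta = np.array([shift[g] for g in genes_hit])
        cohort.loc[genes_hit, case_cols] += delta[:, None]
    return cohort, labels


def demo_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A planted study design exercising every pipeline stage.

    Eight TFs are planted onto their namesake modules (80% of members
    as true targets); five diseases are enriched (70%) in the first
    five modules and ten more carry no signal, giving positive and
    negative tf -> module -> disease chains; the cohort carries
    module-level differential expression for the disease modules.
    """
    params = dict(
        planted_tf_module_pairs=tuple(
            (f"TF{i:03d}", f"M{i:03d}", 0.8) for i in range(8)),
        disease_module_pairs=tuple(
            [(f"D{i}", f"M{i:03d}", 0.7) for i in range(5)]
            + [(f"D{i}", f"M{i:03d}", 0.0) for i in range(5, 15)]),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generators in dependency order and bundle the outputs."""
    genes = generate_genes(config)
    loadings = generate_module_loadings(config)
    truth = plant_truth(genes, loadings, config)
    peaks = generate_binding_sites(genes, truth, config)
    expression, activities = generate_expression(loadings, truth, config)
    diseases = generate_disease_sets(loadings, truth, config)
    cohort, labels = generate_cohort(loadings, truth, config)
    return SyntheticDataset(config=config, genes=genes, loadings=loadings,
                            truth=truth, peaks=peaks, expression=expression,
                            activities=activities, diseases=diseases,
                            cohort=cohort, cohort_labels=labels)
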