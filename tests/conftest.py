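import pytest

from tfica.synthetic import SyntheticConfig, generate_dataset


def planted_config(seed: int, n_planted: int = 8, target_fraction: float = 0.8,
                   coupling: float = 0.6, enriched_fraction: float = 0.7,
                   **kwargs) -> SyntheticConfig:
    """Desk-scale study design with planted tf->module->disease chains.

    TF i is planted onto module i for the first ``n_planted`` TFs;
    diseases D0..D4 are enriched in modules 0..4, D5..D14 carry no
    signal and serve as negatives.
    """
    n_modules = kwargs.get("n_modules", 20)
    pairs = [(f"TF{i:03d}", f"M{i:03d}", target_fraction) for i in range(n_planted)]
    n_pos = min(5, n_planted)
    dis = ([(f"D{i}", f"M{i:03d}", enriched_fraction) for i in range(n_pos)]
           + [(f"D{i}", f"M{i % n_modules:03d}", 0.0) for i in range(n_pos, n_pos + 10)])
    return SyntheticConfig(planted_tf_module_pairs=pairs,
                           disease_module_pairs=dis,
                           tf_module_coupling=coupling,
                           seed=seed, **kwargs)


def null_config(seed: int, **kwargs) -> SyntheticConfig:
    """All planted effects zero: pure-background peaks, no coupling."""
    dis = [(f"D{i}", f"M{i % 20:03d}", 0.0) for i in range(10)]
    return SyntheticConfig(planted_tf_module_pairs=(),
                           disease_module_pairs=dis,
                           tf_module_coupling=0.0,
                           cohort_effect_size=0.0,
                           score_shift=0.0,
                           seed=seed, **kwargs)


@pytest.fixture(scope="session")
def planted_dataset():
    return generate_dataset(planted_config(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    return generate_dataset(null_config(seed=2))


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny universe for fast unit tests."""
    cfg = planted_config(seed=3, n_planted=2, n_genes=300, n_modules=5,
                         n_tfs=3, n_samples=60, n_background_targets=15)
    return generate_dataset(cfg)
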