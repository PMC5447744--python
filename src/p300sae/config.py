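"""Study configuration: one serializable object drives the whole run.

A :class:`StudyConfig` bundles simulator settings, cohort composition,
feature parameters, per-model hyperparameters and the master seed, and
round-trips through YAML so a saved config reproduces a study
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from p300sae.sae import SAEHyperparams
from p300sae.simulate import NoiseModel, SimulationConfig


@dataclass
class FeatureParams:
    """Epoching and windowed-means parameters (milliseconds)."""

    pre_ms: float = 500.0
    post_ms: float = 1000.0
    baseline_ms: float = 500.0
    start_ms: float = 150.0
    end_ms: float = 700.0
    width_ms: float = 50.0


@dataclass
class CohortParams:
    """Synthetic cohort composition: disjoint training and testing
    subjects with P300 amplitudes drawn uniformly from a range."""

    n_train: int = 4
    n_test: int = 11
    amplitude_range: tuple[float, float] = (2.0, 10.0)
    latency: float = 400.0
    latency_jitter: float = 30.0
    width: float = 60.0


@dataclass
class StudyConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortParams = field(default_factory=CohortParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    sae: SAEHyperparams = field(default_factory=SAEHyperparams)
    mlp_iterations: int = 1000
    models: tuple[str, ...] = ("lda", "mlp", "sae")
    validation_fraction: float = 0.2
    repetitions: int = 1
    seed: int = 0
    # optional real-data mode: paths to .vhdr headers or container files
    train_files: tuple[str, ...] = ()
    test_files: tuple[str, ...] = ()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: StudyConfig) -> dict:
    return _to_plain(config)


def config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    sim = dict(d.pop("simulation", {}))
    noise = NoiseModel(**sim.pop("noise", {}))
    cohort = dict(d.pop("cohort", {}))
    if "amplitude_range" in cohort:
        cohort["amplitude_range"] = tuple(cohort["amplitude_range"])
    sae = dict(d.pop("sae", {}))
    if "layer_sizes" in sae:
        sae["layer_sizes"] = tuple(sae["layer_sizes"])
    for key in ("models", "train_files", "test_files"):
        if key in d:
            d[key] = tuple(d[key])
    return StudyConfig(
        simulation=SimulationConfig(noise=noise, **sim),
        cohort=CohortParams(**cohort),
        features=FeatureParams(**d.pop("features", {})),
        sae=SAEHyperparams(**sae),
        **d,
    )


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(config), f, sort_keys=False)


def load_config(path) -> StudyConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f))


def config_hash(config: StudyConfig) -> str:
    """Stable hash of the full configuration, for provenance logs."""
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> StudyConfig:
    """A minutes-scale demonstration study: full feature pipeline but a
    small cohort, short sessions and a reduced iteration budget."""
    return StudyConfig(
        simulation=SimulationConfig(targets_per_phase=5),
        cohort=CohortParams(n_train=2, n_test=2),
        sae=SAEHyperparams(
            layer_sizes=(50, 20),
            max_pretrain_epochs=30,
            softmax_iterations=50,
            finetune_iterations=30,
        ),
        mlp_iterations=60,
        seed=seed,
    )
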