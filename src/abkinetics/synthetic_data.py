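"""Synthetic observable datasets with the structure of the seeding assays.

The elongation experiments add 2, 4 or 7 µM isolated protofibrils to 30 µM
freshly purified, seed-free monomer and follow ThT fluorescence for 1–60
minutes; the lateral-association experiment triggers association of 4 µM
protofibrils with 150 mM NaCl and follows the DLS count rate for 120
minutes. This module simulates those designs with any chosen rate
constants, adds a constant positive baseline plus seeded additive Gaussian
noise, and records the generating ground truth — so the whole
generate → preprocess → refit pipeline is testable end to end without any
instrument data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .observables import ObservableSeries, dls_signal, tht_signal
from .ode_engine import SolverSettings, integrate
from .reaction_models import (
    KineticParams,
    ModelConfig,
    build_complete_model,
    build_lateral_model,
    build_simple_model,
    uM_to_mM,
)

__all__ = [
    "ExperimentDesign",
    "TruthRecord",
    "generate_tht_dataset",
    "generate_dls_dataset",
]


def _default_interval_s(modality: str, duration_min: float) -> float:
    # ThT traces are read every second on short runs, every 30 s on the
    # hour-long run; DLS count rates once a minute.
    if modality == "DLS":
        return 60.0
    return 1.0 if duration_min <= 5 else 30.0


@dataclass(frozen=True)
class ExperimentDesign:
    """One synthetic experiment: design constants plus the noise model.

    ``noise_sigma_frac`` is the Gaussian noise standard deviation and
    ``baseline_offset_frac`` the constant positive offset, both as fractions
    of the noise-free signal range of each series (defaults 2% and 5%).
    ``sampling_interval_s`` defaults by modality and duration.
    """

    modality: str = "ThT"
    monomer_uM: float = 30.0
    protofibril_uM_list: tuple[float, ...] = (2.0, 4.0, 7.0)
    duration_min: float = 1.0
    sampling_interval_s: float | None = None
    noise_sigma_frac: float = 0.02
    baseline_offset_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("ThT", "DLS"):
            raise ValueError("modality must be 'ThT' or 'DLS'")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sigma_frac < 0 or self.baseline_offset_frac < 0:
            raise ValueError("noise and baseline fractions must be non-negative")
        if self.sampling_interval_s is None:
            object.__setattr__(
                self,
                "sampling_interval_s",
                _default_interval_s(self.modality, self.duration_min),
            )

    @classmethod
    def dls_default(cls, seed: int = 0) -> "ExperimentDesign":
        """The 120-min, 4 µM protofibril DLS design (no monomer)."""
        return cls(
            modality="DLS",
            monomer_uM=0.0,
            protofibril_uM_list=(4.0,),
            duration_min=120.0,
            seed=seed,
        )

    def time_grid_h(self) -> np.ndarray:
        n = int(round(self.duration_min * 60.0 / self.sampling_interval_s))
        return np.arange(n + 1) * (self.sampling_interval_s / 3600.0)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind a synthetic dataset; JSON round-trippable."""

    params: KineticParams
    config: ModelConfig
    design: ExperimentDesign
    model_choice: str
    series_seeds: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": asdict(self.params),
                "config": asdict(self.config),
                "design": asdict(self.design),
                "model_choice": self.model_choice,
                "series_seeds": list(self.series_seeds),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        raw = json.loads(text)
        design = dict(raw["design"])
        design["protofibril_uM_list"] = tuple(design["protofibril_uM_list"])
        return cls(
            params=KineticParams(**raw["params"]),
            config=ModelConfig(**raw["config"]),
            design=ExperimentDesign(**design),
            model_choice=raw["model_choice"],
            series_seeds=tuple(raw["series_seeds"]),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _corrupt(
    signal: np.ndarray, design: ExperimentDesign, rng: np.random.Generator
) -> np.ndarray:
    span = float(signal.max() - signal.min())
    baseline = design.baseline_offset_frac * span
    noise = (
        rng.normal(0.0, design.noise_sigma_frac * span, size=signal.shape)
        if design.noise_sigma_frac > 0
        else 0.0
    )
    return signal + baseline + noise


def generate_tht_dataset(
    params: KineticParams | None = None,
    design: ExperimentDesign | None = None,
    model_choice: str = "simple",
    config: ModelConfig | None = None,
    settings: SolverSettings | None = None,
) -> tuple[list[ObservableSeries], TruthRecord]:
    """Simulated seeded-elongation ThT curves, one per protofibril level."""
    params = params or KineticParams()
    design = design or ExperimentDesign()
    config = config or ModelConfig()
    settings = settings or SolverSettings()
    if design.modality != "ThT":
        raise ValueError("generate_tht_dataset needs a ThT design")
    if model_choice not in ("simple", "complete"):
        raise ValueError("model_choice must be 'simple' or 'complete'")
    build = build_simple_model if model_choice == "simple" else build_complete_model
    model = build(config)
    t_grid = design.time_grid_h()
    series_seeds = tuple(design.seed + k for k in range(len(design.protofibril_uM_list)))
    out = []
    for pf_uM, s in zip(design.protofibril_uM_list, series_seeds):
        initial = model.initial_state(
            monomer_mM=uM_to_mM(design.monomer_uM),
            protofibril_mM=uM_to_mM(pf_uM),
        )
        traj = integrate(model, initial, params, t_grid, settings)
        clean = tht_signal(traj, params.b_tht)
        rng = np.random.default_rng(s)
        out.append(
            ObservableSeries(
                times=t_grid,
                signal=_corrupt(clean.signal, design, rng),
                modality="ThT",
                label=f"ThT_{pf_uM:g}uM",
                monomer_mM=uM_to_mM(design.monomer_uM),
                protofibril_mM=uM_to_mM(pf_uM),
            )
        )
    truth = TruthRecord(params, config, design, model_choice, series_seeds)
    return out, truth


def generate_dls_dataset(
    params: KineticParams | None = None,
    design: ExperimentDesign | None = None,
    config: ModelConfig | None = None,
    settings: SolverSettings | None = None,
) -> tuple[ObservableSeries, TruthRecord]:
    """Simulated lateral-association DLS count-rate curve (no monomer)."""
    params = params or KineticParams()
    design = design or ExperimentDesign.dls_default()
    config = config or ModelConfig()
    settings = settings or SolverSettings()
    if design.modality != "DLS":
        raise ValueError("generate_dls_dataset needs a DLS design")
    if design.monomer_uM != 0:
        raise ValueError("the lateral-association design contains no monomer")
    model = build_lateral_model(config)
    pf_uM = design.protofibril_uM_list[0]
    t_grid = design.time_grid_h()
    initial = model.initial_state(protofibril_mM=uM_to_mM(pf_uM))
    traj = integrate(model, initial, params, t_grid, settings)
    clean = dls_signal(traj, params.b_dls)
    rng = np.random.default_rng(design.seed)
    series = ObservableSeries(
        times=t_grid,
        signal=_corrupt(clean.signal, design, rng),
        modality="DLS",
        label=f"DLS_{pf_uM:g}uM",
        monomer_mM=0.0,
        protofibril_mM=uM_to_mM(pf_uM),
    )
    truth = TruthRecord(params, config, design, "lateral", (design.seed,))
    return series, truth
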