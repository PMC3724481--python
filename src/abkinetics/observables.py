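"""Mapping trajectories to ThT-fluorescence and DLS count-rate signals.

Thioflavin-T fluorescence reports amyloid *elongation*: every monomer added
to a protofibril creates new dye binding sites, whereas lateral association
of two protofibrils creates none. The ThT signal is therefore modeled as
``S(t) = b · Σ_i i·[F_i](t)`` — each elongated protofibril weighted by the
number ``i`` of added monomers — with the unelongated seed pool F excluded
(its average size is only a nominal estimate, and baseline subtraction of
the data removes its constant contribution anyway).

The DLS count rate reports particle size growth during lateral association
and is mapped by the same scheme over the associated species,
``S(t) = b · Σ_{i≥1} w_i·[G_i](t)`` with weights ``w_i = i`` by default
(G_0, the unassociated pool, is excluded). ``b`` is one constant per
modality per fitting run, never per curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ode_engine import Trajectory
from .reaction_models import UM_PER_MM

__all__ = [
    "ObservableSeries",
    "tht_signal",
    "dls_signal",
    "baseline_subtract",
    "read_series_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class ObservableSeries:
    """A (time, signal) series in instrument units with its provenance."""

    times: np.ndarray  # hours
    signal: np.ndarray  # arbitrary units (ThT fluorescence or DLS Kcnts/s)
    modality: str  # "ThT" | "DLS"
    label: str = ""
    monomer_mM: float = 0.0
    protofibril_mM: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same length")
        if self.modality not in ("ThT", "DLS"):
            raise ValueError("modality must be 'ThT' or 'DLS'")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "signal": self.signal,
                "modality": self.modality,
                "label": self.label,
                "monomer_uM": self.monomer_mM * UM_PER_MM,
                "protofibril_uM": self.protofibril_mM * UM_PER_MM,
            }
        )


def _weighted_sum(traj: Trajectory, weights: np.ndarray) -> np.ndarray:
    # clamp solver overshoot to zero in observables only, never in the state
    return np.clip(traj.states, 0.0, None) @ weights


def tht_signal(traj: Trajectory, b_map: float) -> ObservableSeries:
    """ThT fluorescence S(t) = b · Σ_i i·[F_i](t) from an elongation run."""
    model = traj.model
    if model.kind not in ("simple", "complete"):
        raise ValueError(
            f"ThT mapping needs an elongation model with F_i species, got {model.kind!r}"
        )
    weights = np.zeros(model.n_species)
    for idx, label in enumerate(model.species):
        if label.startswith("F") and label != "F":
            weights[idx] = int(label[1:])
    series = _weighted_sum(traj, weights) * b_map
    return ObservableSeries(
        times=traj.times,
        signal=series,
        modality="ThT",
        monomer_mM=float(traj.states[0, model.index("A1")]),
        protofibril_mM=float(traj.states[0, model.index("F")]),
    )


def dls_signal(
    traj: Trajectory, b_map: float, weights: str = "added"
) -> ObservableSeries:
    """DLS count rate S(t) = b · Σ_{i≥1} w_i·[G_i](t) from a lateral run.

    ``weights="added"`` uses w_i = i (count of associated units, the direct
    analogue of the ThT scheme); ``weights="total"`` uses w_i = i + 1 (total
    size in 1600-mer units). Because b is a free scale the two differ only
    in the inferred b, not in fit quality, once G_0 is excluded.
    """
    model = traj.model
    if model.kind != "lateral":
        raise ValueError(
            f"DLS mapping needs the lateral model with G_i species, got {model.kind!r}"
        )
    if weights not in ("added", "total"):
        raise ValueError("weights must be 'added' or 'total'")
    w = np.array(
        [
            0.0 if i == 0 else (i if weights == "added" else i + 1)
            for i in range(model.n_species)
        ]
    )
    series = _weighted_sum(traj, w) * b_map
    return ObservableSeries(
        times=traj.times,
        signal=series,
        modality="DLS",
        protofibril_mM=float(traj.states[0, model.index("G0")]),
    )


def baseline_subtract(series: ObservableSeries) -> ObservableSeries:
    """Subtract each series' own minimum so the signal starts from zero.

    Applied per series independently, exactly as raw instrument traces are
    preprocessed before fitting; idempotent.
    """
    if len(series) == 0:
        raise ValueError("cannot baseline-subtract an empty series")
    return replace(series, signal=series.signal - series.signal.min())


def write_series_csv(series_list: list[ObservableSeries], path: str | Path) -> None:
    """Write one or more series to a single CSV (long format)."""
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )


def read_series_csv(path: str | Path) -> list[ObservableSeries]:
    """Read series from the CSV schema written by :func:`write_series_csv`."""
    df = pd.read_csv(path)
    required = {"time_h", "signal", "modality", "label", "monomer_uM", "protofibril_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            ObservableSeries(
                times=grp["time_h"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                modality=str(grp["modality"].iloc[0]),
                label=str(label),
                monomer_mM=float(grp["monomer_uM"].iloc[0]) / UM_PER_MM,
                protofibril_mM=float(grp["protofibril_uM"].iloc[0]) / UM_PER_MM,
            )
        )
    return out
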