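"""Ground-truth-carrying synthetic data for validating the analysis chain.

Every generator returns its generating parameters alongside the data, so
metric and fitting operations can be validated as parameter recovery.  The
event-trace generator emulates a continuous miniature-PSC recording: Poisson
event times, dual-exponential conductance templates scaled by right-skewed
(lognormal by default) amplitude draws, linear event summation and additive
Gaussian noise.  The genotype-dataset generator emulates the structure of
per-cell mPSC summary tables (two genotype groups with between-cell
variability in amplitude, frequency and kinetics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biophysics import SynapseKind, SynapseSpec, waveform_peak_time
from .engine import Trace
from .morphology import (
    MorphNode,
    MorphogenParams,
    Morphology,
    NodeKind,
    morphogen_preset,
    synthesize_morphology,
)

__all__ = [
    "EventStatModel",
    "SyntheticError",
    "generate_event_trace",
    "generate_genotype_dataset",
    "fixture_morphologies",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class EventStatModel:
    """Statistical model of one cell's miniature-PSC stream."""

    amplitude_mean_pa: float
    amplitude_sd_pa: float
    frequency_hz: float
    kinetics: SynapseSpec
    noise_sd_pa: float = 0.0
    amplitude_family: str = "lognormal"  # or "normal"
    genotype: str = ""

    def __post_init__(self):
        if self.amplitude_mean_pa <= 0:
            raise SyntheticError("amplitude mean must be > 0")
        if self.frequency_hz < 0 or self.noise_sd_pa < 0:
            raise SyntheticError("frequency and noise sd must be >= 0")
        if self.amplitude_family not in ("lognormal", "normal"):
            raise SyntheticError(f"unknown family {self.amplitude_family!r}")


def _draw_amplitudes(model: EventStatModel, n: int, rng) -> np.ndarray:
    m, s = model.amplitude_mean_pa, model.amplitude_sd_pa
    if n == 0:
        return np.empty(0)
    if model.amplitude_family == "normal":
        return np.maximum(0.1 * m, rng.normal(m, s, size=n))
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _unit_template(kinetics: SynapseSpec, t_ms: np.ndarray) -> np.ndarray:
    """Dual-exponential template normalized to unit peak."""
    tr, td = kinetics.tau_rise_ms, kinetics.tau_decay_ms
    tpk = waveform_peak_time(tr, td)
    norm = 1.0 / (math.exp(-tpk / td) - math.exp(-tpk / tr))
    shape = norm * (np.exp(-t_ms / td) - np.exp(-t_ms / tr))
    return np.where(t_ms >= 0, shape, 0.0)


def generate_event_trace(
    model: EventStatModel, duration_ms: float, dt_ms: float, seed: int
) -> tuple[Trace, np.ndarray, np.ndarray]:
    """A continuous synthetic PSC recording with its ground truth.

    Returns (trace, event_times_ms, event_amplitudes_pa).  Events sum
    linearly; noise is additive Gaussian.  Seed-deterministic.
    """
    if duration_ms <= 0 or dt_ms <= 0:
        raise SyntheticError("duration and dt must be > 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_ms / dt_ms))
    t = np.arange(n_samples) * dt_ms
    n_events = rng.poisson(model.frequency_hz * duration_ms * 1e-3)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n_events))
    amps = _draw_amplitudes(model, n_events, rng)
    values = np.zeros(n_samples)
    span = 10.0 * model.kinetics.tau_decay_ms
    for t0, a in zip(times, amps):
        i0 = int(math.ceil(t0 / dt_ms))
        i1 = min(n_samples, i0 + int(span / dt_ms))
        if i0 >= n_samples:
            continue
        values[i0:i1] += a * _unit_template(model.kinetics, t[i0:i1] - t0)
    if model.noise_sd_pa > 0:
        values += rng.normal(0.0, model.noise_sd_pa, size=n_samples)
    return Trace(t0=0.0, dt=dt_ms, values=values, unit="pA"), times, amps


def generate_genotype_dataset(
    wt_model: EventStatModel,
    ko_model: EventStatModel,
    n_cells_per_group: int,
    seed: int,
    between_cell_cv: float = 0.15,
) -> pd.DataFrame:
    """Per-cell summary table for two genotype groups.

    Each cell's mean amplitude and event frequency are drawn around its
    group model with the stated between-cell coefficient of variation; rise
    and t50 derive from the group kinetics with mild per-cell jitter.
    Columns: genotype, mean_amplitude_pa, frequency_hz, rise_ms, t50_ms.
    """
    if n_cells_per_group < 2:
        raise SyntheticError("need at least 2 cells per group")
    rng = np.random.default_rng(seed)
    rows = []
    for model in (wt_model, ko_model):
        tr, td = model.kinetics.tau_rise_ms, model.kinetics.tau_decay_ms
        rise_nominal = 1.2 * tr  # 20-80% rise of the dual-exp template
        t50_nominal = td * math.log(2)
        for _ in range(n_cells_per_group):
            amp = max(
                0.1,
                rng.normal(
                    model.amplitude_mean_pa,
                    between_cell_cv * model.amplitude_mean_pa,
                ),
            )
            freq = max(
                0.0,
                rng.normal(
                    model.frequency_hz, between_cell_cv * model.frequency_hz
                ),
            )
            rows.append(
                {
                    "genotype": model.genotype,
                    "mean_amplitude_pa": amp,
                    "frequency_hz": freq,
                    "rise_ms": rise_nominal * (1 + 0.05 * rng.standard_normal()),
                    "t50_ms": t50_nominal * (1 + 0.05 * rng.standard_normal()),
                }
            )
    return pd.DataFrame(rows)


def _stick(n_soma_radius: float, length: float, n_nodes: int, direction=(1, 0, 0)):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    nodes = [
        MorphNode(1, -1, NodeKind.soma, 0.0, 0.0, 0.0, n_soma_radius)
    ]
    for i in range(1, n_nodes + 1):
        p = d * (length * i / n_nodes)
        nodes.append(
            MorphNode(
                len(nodes) + 1,
                len(nodes),
                NodeKind.dendrite,
                float(p[0]),
                float(p[1]),
                float(p[2]),
                0.5,
            )
        )
    return nodes


def fixture_morphologies() -> dict[str, Morphology]:
    """Canonical deterministic morphologies with known analytic properties.

    * ``sphere``   — a lone 10 µm-radius soma.
    * ``stick100`` — soma plus one straight 100 µm dendrite.
    * ``Y_tree``   — 50 µm stem bifurcating into two 40 µm daughters.
    * ``star4``    — four straight 80 µm dendrites at right angles.
    * ``wt_preset`` / ``ko_preset`` — fixed-seed draws of the genotype
      presets of the synthetic generator.
    """
    sphere = Morphology(
        [MorphNode(1, -1, NodeKind.soma, 0.0, 0.0, 0.0, 10.0)], label="sphere"
    )
    stick = Morphology(_stick(7.0, 100.0, 10), label="stick100")

    y_nodes = _stick(7.0, 50.0, 5)
    fork_id = len(y_nodes)
    for direction in ((1.0, 1.0, 0.0), (1.0, -1.0, 0.0)):
        d = np.asarray(direction) / math.sqrt(2.0)
        start = np.array([50.0, 0.0, 0.0])
        parent = fork_id
        for i in range(1, 5):
            p = start + d * (40.0 * i / 4)
            y_nodes.append(
                MorphNode(
                    len(y_nodes) + 1,
                    parent,
                    NodeKind.dendrite,
                    float(p[0]),
                    float(p[1]),
                    float(p[2]),
                    0.5,
                )
            )
            parent = len(y_nodes)
    y_tree = Morphology(y_nodes, label="Y_tree")

    star_nodes = [MorphNode(1, -1, NodeKind.soma, 0.0, 0.0, 0.0, 7.0)]
    for direction in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)):
        d = np.asarray(direction, dtype=float)
        parent = 1
        for i in range(1, 9):
            p = d * (80.0 * i / 8)
            star_nodes.append(
                MorphNode(
                    len(star_nodes) + 1,
                    parent,
                    NodeKind.dendrite,
                    float(p[0]),
                    float(p[1]),
                    float(p[2]),
                    0.5,
                )
            )
            parent = len(star_nodes)
    star4 = Morphology(star_nodes, label="star4")

    return {
        "sphere": sphere,
        "stick100": stick,
        "Y_tree": y_tree,
        "star4": star4,
        "wt_preset": synthesize_morphology(morphogen_preset("wt"), seed=42),
        "ko_preset": synthesize_morphology(morphogen_preset("ko"), seed=43),
    }
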