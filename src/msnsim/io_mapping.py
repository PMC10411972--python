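"""Input–output mapping of the D1-MSN model under stochastic E/I drive.

The cell receives ``n_exc`` excitatory (AMPA+NMDA) and ``n_inh`` inhibitory
(GABA_A) inputs randomly distributed along the dendrites.  In every
iteration each input's activation frequency is an independent draw from a
Normal distribution (truncated at zero) centred on the condition's nominal
rate, and event times follow a Poisson (or jittered-regular) process.
Sweeping the nominal excitatory and inhibitory rates yields a firing-rate
surface; iso-firing contours and threshold-linear (or sigmoid) fits of the
rate-vs-excitation curves quantify how inhibition, morphology and synaptic
weights shift the offset (subtractive/additive) and gain
(divisive/multiplicative) of the transformation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from skimage import measure as _sk_measure

from .biophysics import ModelSpec, SynapseKind, default_model_spec
from .calibration import match_psc
from .engine import (
    CableModel,
    SimulationConfig,
    detect_spikes,
    discretize,
    integrate,
    place_synapses,
)
from .morphology import (
    Morphology,
    morphogen_preset,
    synthesize_morphology,
    total_dendritic_length,
)

__all__ = [
    "EnsembleSpec",
    "IOGrid",
    "GainOffset",
    "IOComparison",
    "IOMappingError",
    "generate_input_trains",
    "run_io_grid",
    "extract_contours",
    "excitation_threshold",
    "fit_io_curve",
    "compare_io",
    "build_genotype_setup",
]


class IOMappingError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnsembleSpec:
    """Statistics of one stochastic E/I input ensemble."""

    n_exc: int = 100
    n_inh: int = 100
    exc_rate_hz: float = 10.0
    inh_rate_hz: float = 10.0
    rate_sd_frac: float = 0.2  # per-input rate dispersion, fraction of mean
    train_kind: str = "poisson"  # or "regular_jittered"
    duration_ms: float = 2000.0

    def __post_init__(self):
        if self.n_exc < 0 or self.n_inh < 0:
            raise IOMappingError("input counts must be >= 0")
        if self.duration_ms <= 0:
            raise IOMappingError("duration must be > 0")
        if self.train_kind not in ("poisson", "regular_jittered"):
            raise IOMappingError(f"unknown train kind {self.train_kind!r}")


def _one_train(rate_hz: float, duration_ms: float, kind: str, rng) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    if kind == "poisson":
        n = rng.poisson(rate_hz * duration_ms * 1e-3)
        return np.sort(rng.uniform(0.0, duration_ms, size=n))
    period = 1000.0 / rate_hz
    times = np.arange(period, duration_ms, period)
    times = times + rng.uniform(-0.2 * period, 0.2 * period, size=times.size)
    return np.sort(times[(times > 0) & (times < duration_ms)])


def generate_input_trains(
    ensemble: EnsembleSpec, rng_seed: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Event-time lists (ms) for the excitatory and inhibitory populations.

    Each input's rate is Normal(mean, sd) truncated at 0 with
    sd = rate_sd_frac · mean; events are drawn per ``train_kind``.
    Seed-deterministic.
    """
    rng = np.random.default_rng(rng_seed)

    def population(n: int, mean: float) -> list[np.ndarray]:
        sd = ensemble.rate_sd_frac * mean
        rates = np.maximum(0.0, rng.normal(mean, sd, size=n)) if mean > 0 else np.zeros(n)
        return [
            _one_train(r, ensemble.duration_ms, ensemble.train_kind, rng)
            for r in rates
        ]

    return (
        population(ensemble.n_exc, ensemble.exc_rate_hz),
        population(ensemble.n_inh, ensemble.inh_rate_hz),
    )


@dataclass
class IOGrid:
    """Mean firing rate (Hz) over an excitation × inhibition rate grid."""

    exc_rates: np.ndarray  # Hz, along columns
    inh_rates: np.ndarray  # Hz, along rows
    rate_matrix: np.ndarray  # shape (n_inh, n_exc)
    sd_matrix: np.ndarray
    n_iterations: int

    def __post_init__(self):
        if self.rate_matrix.shape != (len(self.inh_rates), len(self.exc_rates)):
            raise IOMappingError("rate matrix shape inconsistent with rate lists")
        if np.any(self.rate_matrix < 0):
            raise IOMappingError("negative firing rates")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, fi in enumerate(self.inh_rates):
            for j, fe in enumerate(self.exc_rates):
                rows.append(
                    {
                        "f_exc_hz": fe,
                        "f_inh_hz": fi,
                        "mean_rate_hz": self.rate_matrix[i, j],
                        "sd_hz": self.sd_matrix[i, j],
                        "n": self.n_iterations,
                    }
                )
        return pd.DataFrame(rows)


def _simulate_ensemble(
    model: CableModel,
    ensemble: EnsembleSpec,
    config: SimulationConfig,
    seed_seq: np.random.SeedSequence,
) -> float:
    """One iteration: fresh placements and trains, returns firing rate (Hz)."""
    place_seed, train_seed = (int(s) for s in seed_seq.generate_state(2))
    sim = dataclasses.replace(model, synapses=[])
    exc_sites = place_synapses(sim, ensemble.n_exc, SynapseKind.AMPA, place_seed)
    inh_sites = place_synapses(
        sim, ensemble.n_inh, SynapseKind.GABA_A, place_seed + 1
    )
    exc_trains, inh_trains = generate_input_trains(ensemble, train_seed)
    ampa = sim.spec.synapses[SynapseKind.AMPA]
    nmda = sim.spec.synapses[SynapseKind.NMDA]
    gaba = sim.spec.synapses[SynapseKind.GABA_A]
    for site, train in zip(exc_sites, exc_trains):
        if train.size:
            sim.attach_synapse(site, ampa, train)
            sim.attach_synapse(site, nmda, train)
    for site, train in zip(inh_sites, inh_trains):
        if train.size:
            sim.attach_synapse(site, gaba, train)
    trace = integrate(sim, config)[0]
    spikes = detect_spikes(trace, config.spike_threshold_mv, config.refractory_ms)
    return len(spikes) / (ensemble.duration_ms * 1e-3)


def run_io_grid(
    model: CableModel,
    ensemble_template: EnsembleSpec,
    exc_rates,
    inh_rates,
    n_iterations: int = 100,
    base_seed: int = 0,
    dt_ms: float = 0.05,
) -> IOGrid:
    """Firing-rate surface over all (excitation, inhibition) rate pairs.

    Every grid cell runs ``n_iterations`` independent ensembles (fresh
    synapse placements and trains, seeds derived deterministically from
    ``base_seed`` and the cell/iteration indices); the cell value is the
    iteration-mean firing rate, with the across-iteration SD stored
    alongside.
    """
    exc_rates = np.asarray(list(exc_rates), dtype=float)
    inh_rates = np.asarray(list(inh_rates), dtype=float)
    if exc_rates.size == 0 or inh_rates.size == 0:
        raise IOMappingError("rate lists must be non-empty")
    config = SimulationConfig(
        dt_ms=dt_ms, duration_ms=ensemble_template.duration_ms
    )
    rates = np.zeros((inh_rates.size, exc_rates.size))
    sds = np.zeros_like(rates)
    for i, fi in enumerate(inh_rates):
        for j, fe in enumerate(exc_rates):
            ens = dataclasses.replace(
                ensemble_template, exc_rate_hz=float(fe), inh_rate_hz=float(fi)
            )
            vals = np.array(
                [
                    _simulate_ensemble(
                        model,
                        ens,
                        config,
                        np.random.SeedSequence((base_seed, i, j, it)),
                    )
                    for it in range(n_iterations)
                ]
            )
            rates[i, j] = vals.mean()
            sds[i, j] = vals.std(ddof=1) if n_iterations > 1 else 0.0
    return IOGrid(
        exc_rates=exc_rates,
        inh_rates=inh_rates,
        rate_matrix=rates,
        sd_matrix=sds,
        n_iterations=n_iterations,
    )


def extract_contours(
    grid: IOGrid, levels_hz=(1.0, 5.0, 10.0)
) -> dict[float, list[np.ndarray]]:
    """Iso-firing contours in (f_exc, f_inh) coordinates.

    Marching squares on the rate matrix with linear interpolation; each
    polyline is an (n, 2) array of (f_exc, f_inh) points.  Levels the
    surface never attains map to empty lists.
    """
    out: dict[float, list[np.ndarray]] = {}
    col_idx = np.arange(grid.exc_rates.size)
    row_idx = np.arange(grid.inh_rates.size)
    for level in levels_hz:
        polylines = []
        for contour in _sk_measure.find_contours(grid.rate_matrix, level):
            fe = np.interp(contour[:, 1], col_idx, grid.exc_rates)
            fi = np.interp(contour[:, 0], row_idx, grid.inh_rates)
            polylines.append(np.column_stack([fe, fi]))
        out[float(level)] = polylines
    return out


def excitation_threshold(grid: IOGrid, level_hz: float) -> np.ndarray:
    """Per inhibition rate, the excitatory rate at which the mean firing
    rate first crosses ``level_hz`` (linear interpolation; NaN where the
    level is never attained)."""
    out = np.full(grid.inh_rates.size, np.nan)
    for i in range(grid.inh_rates.size):
        row = grid.rate_matrix[i]
        above = np.nonzero(row >= level_hz)[0]
        if above.size == 0:
            continue
        j = above[0]
        if j == 0:
            out[i] = grid.exc_rates[0]
        else:
            f0, f1 = grid.exc_rates[j - 1], grid.exc_rates[j]
            r0, r1 = row[j - 1], row[j]
            out[i] = f0 + (level_hz - r0) * (f1 - f0) / (r1 - r0)
    return out


# -- gain / offset ------------------------------------------------------------


@dataclass(frozen=True)
class GainOffset:
    """Parameters of a fitted input-rate → output-rate curve."""

    offset_hz: float  # input-rate threshold (or half-activation abscissa)
    gain: float  # slope (threshold-linear) or max slope (sigmoid)
    fit_form: str  # 'threshold_linear' or 'sigmoid'
    rmse_hz: float


@dataclass(frozen=True)
class IOComparison:
    delta_offset_hz: float
    delta_gain: float
    classification: str


def fit_io_curve(
    exc_rates, output_rates, fit_form: str = "threshold_linear"
) -> GainOffset:
    """Fit the rate-vs-excitation curve with a threshold-linear or sigmoid
    model.

    Threshold-linear: r = gain · max(0, f − offset), fitted by a coarse
    offset scan with closed-form gain followed by local least-squares
    refinement.  Sigmoid: 4-parameter logistic; gain is the maximal slope
    and offset the half-activation input rate.
    """
    f = np.asarray(list(exc_rates), dtype=float)
    r = np.asarray(list(output_rates), dtype=float)
    if f.size < 4:
        raise IOMappingError("need at least 4 points")
    if np.any(r < 0):
        raise IOMappingError("output rates must be non-negative")
    if np.all(r == 0):
        raise IOMappingError("all-zero outputs: degenerate fit")

    if fit_form == "threshold_linear":
        def gain_for(offset: float) -> float:
            x = np.maximum(0.0, f - offset)
            denom = float(x @ x)
            return max(0.0, float(x @ r) / denom) if denom > 0 else 0.0

        def sse(offset: float) -> float:
            g = gain_for(offset)
            resid = r - g * np.maximum(0.0, f - offset)
            return float(resid @ resid)

        scan = np.linspace(f.min() - 1.0, f.max(), 256)
        offset0 = float(scan[np.argmin([sse(o) for o in scan])])
        gain0 = gain_for(offset0)

        def residuals(p):
            return p[0] * np.maximum(0.0, f - p[1]) - r

        sol = least_squares(residuals, x0=[gain0, offset0], method="lm")
        gain, offset = float(sol.x[0]), float(sol.x[1])
        if gain < 0:
            gain, offset = gain0, offset0
        resid = r - gain * np.maximum(0.0, f - offset)
        return GainOffset(
            offset_hz=offset,
            gain=gain,
            fit_form=fit_form,
            rmse_hz=float(np.sqrt(np.mean(resid**2))),
        )

    if fit_form == "sigmoid":
        def logistic(x, base, span, x0, k):
            return base + span / (1.0 + np.exp(-(x - x0) / k))

        span0 = float(r.max() - r.min())
        p0 = (float(r.min()), span0, float(np.median(f)), max(1.0, float(np.ptp(f)) / 8))
        popt, _ = curve_fit(logistic, f, r, p0=p0, maxfev=10000)
        base, span, x0, k = (float(v) for v in popt)
        resid = r - logistic(f, *popt)
        return GainOffset(
            offset_hz=x0,
            gain=span / (4.0 * k),  # maximal slope of the logistic
            fit_form=fit_form,
            rmse_hz=float(np.sqrt(np.mean(resid**2))),
        )

    raise IOMappingError(f"unknown fit form {fit_form!r}")


def compare_io(
    reference: GainOffset,
    test: GainOffset,
    offset_tol_hz: float = 0.5,
    gain_tol_frac: float = 0.05,
) -> IOComparison:
    """Classify the change from reference to test curve.

    Offset increases beyond tolerance are subtractive (threshold raised),
    decreases additive; gain increases beyond the relative tolerance are
    multiplicative, decreases divisive; combinations are mixed.
    """
    if reference.fit_form != test.fit_form:
        raise IOMappingError("cannot compare fits of different forms")
    d_off = test.offset_hz - reference.offset_hz
    d_gain = test.gain - reference.gain
    off_change = (
        "subtractive" if d_off > offset_tol_hz
        else "additive" if d_off < -offset_tol_hz
        else None
    )
    rel_gain = d_gain / reference.gain if reference.gain != 0 else np.inf * np.sign(d_gain or 1)
    gain_change = (
        "multiplicative" if rel_gain > gain_tol_frac
        else "divisive" if rel_gain < -gain_tol_frac
        else None
    )
    if off_change and gain_change:
        label = "mixed"
    elif off_change:
        label = off_change
    elif gain_change:
        label = gain_change
    else:
        label = "none"
    return IOComparison(
        delta_offset_hz=float(d_off),
        delta_gain=float(d_gain),
        classification=label,
    )


# -- genotype pipeline --------------------------------------------------------


def build_genotype_setup(
    genotype: str,
    seed: int,
    calibrate: bool = True,
    n_exc_ref: int = 100,
    n_inh: int = 100,
    duration_ms: float = 2000.0,
    max_seg_length_um: float = 20.0,
    calib_iterations: int = 8,
) -> tuple[CableModel, EnsembleSpec]:
    """Assemble a calibrated genotype model and its input ensemble.

    The genotype picks the synthetic-morphology preset and the mPSC targets.
    When ``calibrate`` is set, AMPA and GABA_A peak conductances and decay
    constants are matched to the genotype's targets with the randomized
    placement procedure.  The number of excitatory contacts scales with
    total dendritic length relative to the wild-type preset (spine density
    is genotype-independent, so synapse count follows cable length);
    inhibitory contacts stay at ``n_inh``.
    """
    spec = default_model_spec(genotype)
    # calibration recordings are Mg-free, but the in-vivo-like ensemble drive
    # sees the physiological voltage-dependent Mg block on NMDA receptors
    spec = spec.with_synapse(
        dataclasses.replace(
            spec.synapses[SynapseKind.NMDA], mg_block=True, mg_mm=1.0
        )
    )
    morph = synthesize_morphology(morphogen_preset(spec.morphology_preset), seed)
    model = discretize(morph, spec, max_seg_length_um)

    if calibrate:
        for kind in (SynapseKind.AMPA, SynapseKind.GABA_A):
            target = spec.psc_targets[kind]
            matched = match_psc(
                model,
                kind,
                target.amplitude_pa,
                target.t50_ms,
                n_iterations=calib_iterations,
                rng_seed=seed,
                tolerance=0.02,
                v_hold_mv=target.v_hold_mv,
            )
            spec = spec.with_synapse(matched)
        model = dataclasses.replace(model, spec=spec)

    if genotype == "wt":
        wt_length = total_dendritic_length(morph)
    else:
        wt_length = total_dendritic_length(
            synthesize_morphology(morphogen_preset("wt"), seed)
        )
    n_exc = int(round(n_exc_ref * total_dendritic_length(morph) / wt_length))
    ensemble = EnsembleSpec(
        n_exc=n_exc, n_inh=n_inh, duration_ms=duration_ms
    )
    return model, ensemble
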