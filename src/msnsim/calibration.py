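"""Measurement and calibration of the model against recorded currents.

Covers the quantities used to constrain and interpret the D1-MSN model:
passive properties (resting potential, input resistance, membrane time
constant), the f–I curve from sustained somatic current steps, trace metrics
of postsynaptic currents (amplitude, 20–80% rise time, time-to-half-decay
t50, paired-pulse ratio, percent reduction), mono-exponential decay fitting
(A1·exp(−t/τ1) + baseline), the 100-iteration randomized-placement miniature
PSC simulation under an ideal somatic voltage clamp, and the two-parameter
(gpeak, τ_decay) search that matches the simulated mean mPSC to an
experimental amplitude/t50 target.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .biophysics import SynapseKind, SynapseSpec
from .engine import (
    CableModel,
    CurrentStep,
    SimulationConfig,
    Trace,
    VoltageClamp,
    detect_spikes,
    integrate,
    place_synapses,
)

__all__ = [
    "ExpFit",
    "PSCMetrics",
    "CellProperties",
    "MPSCResult",
    "CalibrationError",
    "FitError",
    "MatchError",
    "measure_passive",
    "fi_curve",
    "fit_monoexponential",
    "psc_metrics",
    "ppr",
    "percent_reduction",
    "simulate_mpsc",
    "match_psc",
    "estimate_nmda_amplitude",
]


class CalibrationError(RuntimeError):
    pass


class FitError(CalibrationError):
    pass


class MatchError(CalibrationError):
    """Conductance matching failed; carries the best spec found so far."""

    def __init__(self, message: str, best_spec: SynapseSpec | None = None):
        self.best_spec = best_spec
        super().__init__(message)


@dataclass(frozen=True)
class ExpFit:
    """Mono-exponential decay fit A1·exp(−t/τ1) + baseline."""

    a1_pa: float
    tau1_ms: float
    baseline_pa: float
    fit_window_ms: tuple[float, float]
    rmse_pa: float

    def __post_init__(self):
        if self.tau1_ms <= 0:
            raise FitError("tau1 must be > 0")


@dataclass(frozen=True)
class PSCMetrics:
    amplitude_pa: float
    rise_ms: float  # 20-80% rise time
    t50_ms: float  # peak to 50% decay
    charge_pa_ms: float


@dataclass(frozen=True)
class CellProperties:
    v_rest_mv: float
    input_resistance_mohm: float
    tau_m_ms: float
    ap_threshold_mv: float | None = None
    ap_peak_mv: float | None = None
    fi_curve: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class MPSCResult:
    mean_trace: Trace
    fit: ExpFit
    metrics: PSCMetrics


# -- passive / active characterization ----------------------------------------


def measure_passive(
    model: CableModel,
    config: SimulationConfig | None = None,
    step_pa: float = -10.0,
) -> CellProperties:
    """Resting potential, input resistance and membrane time constant.

    The resting potential is the stimulus-free steady state; R_in and τ_m
    come from a small hyperpolarizing somatic step (ΔV/I, and a
    mono-exponential fit to the charging transient).
    """
    config = config or SimulationConfig(duration_ms=500.0)
    settle = dataclasses.replace(config, duration_ms=max(500.0, config.duration_ms))
    state = None
    for _ in range(10):  # settle in chunks until the baseline stops drifting
        res = integrate(model, settle, initial_state=state, return_state=True)
        trace, state = res[0], res["state"]
        v = trace.values
        tail = int(50.0 / trace.dt)
        if abs(v[-1] - v[-tail]) < 0.005:
            break
    else:
        raise CalibrationError("baseline did not converge to a steady state")
    v_rest = float(v[-1])

    onset, step_ms = 50.0, 500.0
    cfg2 = dataclasses.replace(
        settle, duration_ms=onset + step_ms, v_init_mv=v_rest
    )
    tr = integrate(
        model, cfg2, stimuli=[CurrentStep(0, step_pa, onset, step_ms)]
    )[0]
    # the fitted asymptote gives the steady-state deflection even when the
    # step window is shorter than a few membrane time constants
    fit = fit_monoexponential(tr, (onset, onset + step_ms))
    delta_v = fit.baseline_pa - v_rest
    r_in = delta_v / (step_pa * 1e-3)  # mV / nA = MΩ
    return CellProperties(
        v_rest_mv=v_rest, input_resistance_mohm=float(r_in), tau_m_ms=fit.tau1_ms
    )


def fi_curve(
    model: CableModel,
    config: SimulationConfig | None = None,
    amplitudes_pa=tuple(range(10, 90, 10)),
    step_ms: float = 500.0,
) -> list[tuple[float, float]]:
    """Firing rate (Hz) for sustained somatic current steps of increasing
    amplitude; rate = spike count / step duration."""
    amplitudes = list(amplitudes_pa)
    if not amplitudes:
        raise CalibrationError("need at least one amplitude")
    config = config or SimulationConfig()
    onset = 50.0
    cfg = dataclasses.replace(config, duration_ms=onset + step_ms + 50.0)
    out = []
    for amp in amplitudes:
        trace = integrate(model, cfg, stimuli=[CurrentStep(0, amp, onset, step_ms)])[0]
        spikes = detect_spikes(
            trace, config.spike_threshold_mv, config.refractory_ms
        )
        spikes = spikes[(spikes >= onset) & (spikes < onset + step_ms)]
        out.append((float(amp), len(spikes) / (step_ms * 1e-3)))
    return out


# -- trace metrics ------------------------------------------------------------


def fit_monoexponential(
    trace: Trace, fit_window_ms: tuple[float, float]
) -> ExpFit:
    """Least-squares mono-exponential decay fit within the stated window.

    The baseline is seeded from the window tail and the decay is fitted from
    the point of maximum deviation (the peak) onward.  Raises
    :class:`FitError` when no decaying component is identifiable.
    """
    t = trace.times()
    lo, hi = fit_window_ms
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 5:
        raise FitError("fit window contains too few samples")
    tw, yw = t[mask], trace.values[mask].astype(float)

    tail = max(3, int(0.05 * len(yw)))
    baseline0 = float(yw[-tail:].mean())
    dev = yw - baseline0
    ipk = int(np.argmax(np.abs(dev)))
    a0 = float(dev[ipk])
    if abs(a0) < 1e-12:
        raise FitError("flat trace: no peak to fit")
    if ipk >= len(yw) - 3:
        raise FitError("signal does not decay within the window")

    td, yd = tw[ipk:] - tw[ipk], yw[ipk:]
    # initial tau from time to half decay
    half_dev = 0.5 * abs(a0)
    below = np.nonzero(np.abs(yd - baseline0) <= half_dev)[0]
    tau0 = float(td[below[0]] / math.log(2)) if below.size else float(td[-1] / 3)
    tau0 = max(tau0, 2 * trace.dt)

    def model_fn(tt, a1, tau1, base):
        return a1 * np.exp(-tt / tau1) + base

    try:
        popt, _ = curve_fit(
            model_fn,
            td,
            yd,
            p0=(a0, tau0, baseline0),
            bounds=(
                [-np.inf, trace.dt * 1e-3, -np.inf],
                [np.inf, 1e6, np.inf],
            ),
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit failed: {exc}") from None
    a1, tau1, base = (float(x) for x in popt)
    if a0 * a1 < 0:
        raise FitError("fitted amplitude has the wrong sign: not a decay")
    resid = yd - model_fn(td, *popt)
    return ExpFit(
        a1_pa=a1,
        tau1_ms=tau1,
        baseline_pa=base,
        fit_window_ms=(float(tw[ipk]), float(hi)),
        rmse_pa=float(np.sqrt(np.mean(resid**2))),
    )


def _interp_crossing(t0, t1, y0, y1, level):
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def psc_metrics(trace: Trace, polarity: int) -> PSCMetrics:
    """Amplitude, 20–80% rise time, peak-to-half-decay time and charge of a
    single-event trace.  ``polarity`` is +1 for outward (upward) events and
    −1 for inward (downward) events."""
    if polarity not in (+1, -1):
        raise CalibrationError("polarity must be +1 or -1")
    t = trace.times()
    y = trace.values.astype(float) * polarity  # analyze as an upward event
    n_base = max(1, int(0.01 * len(y)))
    baseline = float(y[:n_base].mean())
    ipk = int(np.argmax(y))
    amplitude = y[ipk] - baseline
    if amplitude <= 0 or ipk == 0:
        raise CalibrationError("no identifiable peak above baseline")

    lvl20 = baseline + 0.2 * amplitude
    lvl80 = baseline + 0.8 * amplitude
    lvl50 = baseline + 0.5 * amplitude

    # rising limb: walk back from the peak
    i80 = ipk
    while i80 > 0 and y[i80 - 1] >= lvl80:
        i80 -= 1
    t80 = _interp_crossing(t[i80 - 1], t[i80], y[i80 - 1], y[i80], lvl80) if i80 > 0 else t[0]
    i20 = i80
    while i20 > 0 and y[i20 - 1] >= lvl20:
        i20 -= 1
    t20 = _interp_crossing(t[i20 - 1], t[i20], y[i20 - 1], y[i20], lvl20) if i20 > 0 else t[0]

    # decay: first drop below the 50% level after the peak
    after = np.nonzero(y[ipk:] <= lvl50)[0]
    if after.size == 0:
        raise CalibrationError("event does not decay to 50% within the trace")
    j = ipk + after[0]
    t50 = _interp_crossing(t[j - 1], t[j], y[j - 1], y[j], lvl50) - t[ipk]

    charge = float(np.trapezoid(np.clip(y - baseline, 0, None), dx=trace.dt))
    return PSCMetrics(
        amplitude_pa=float(amplitude),
        rise_ms=float(t80 - t20),
        t50_ms=float(t50),
        charge_pa_ms=charge,
    )


def ppr(amp1: float, amp2: float) -> float:
    """Paired-pulse ratio: second over first response amplitude."""
    if amp1 <= 0:
        raise CalibrationError("first amplitude must be > 0")
    return amp2 / amp1


def percent_reduction(before: float, after: float) -> float:
    """Percent reduction 100·(before − after)/before."""
    if before <= 0:
        raise CalibrationError("baseline amplitude must be > 0")
    return 100.0 * (before - after) / before


# -- miniature PSC simulation and matching ------------------------------------

_DEFAULT_VHOLD = {
    SynapseKind.AMPA: -70.0,
    SynapseKind.NMDA: +40.0,
    SynapseKind.GABA_A: +40.0,
}


def simulate_mpsc(
    model: CableModel,
    synapse_spec: SynapseSpec,
    n_iterations: int = 100,
    rng_seed: int = 0,
    v_hold_mv: float | None = None,
    settle_ms: float = 400.0,
    dt_ms: float = 0.025,
    block_channels: bool = True,
) -> MPSCResult:
    """Mean somatic miniature PSC over randomized synapse placements.

    Each iteration places one synapse at a random dendritic location (drawn
    uniformly per unit length), delivers a single release event and records
    the somatic electrode current under an ideal voltage clamp.  The
    iteration-mean current is baseline-subtracted and summarized by a
    mono-exponential decay fit and the standard PSC metrics.
    Seed-deterministic.

    ``block_channels`` (default) removes the voltage-gated conductances for
    the clamp run, emulating the Cs⁺/QX-314 internal solution used in the
    recordings; without it, depolarized holding potentials lose space clamp
    through the potassium conductances.
    """
    if v_hold_mv is None:
        v_hold_mv = _DEFAULT_VHOLD[synapse_spec.kind]
    clamp = VoltageClamp(site=0, v_hold_mv=v_hold_mv)

    if block_channels:
        model = dataclasses.replace(
            model, spec=dataclasses.replace(model.spec, channels=())
        )
    # settle the clamped cell once (slow K gates need hundreds of ms when
    # channels stay in), then branch every iteration from the settled state
    base = dataclasses.replace(model, synapses=[])
    settle_cfg = SimulationConfig(
        dt_ms=dt_ms, duration_ms=settle_ms, v_init_mv=v_hold_mv
    )
    state = integrate(base, settle_cfg, clamp=clamp, return_state=True)["state"]

    onset = 10.0
    duration = onset + max(60.0, 8.0 * synapse_spec.tau_decay_ms)
    cfg = SimulationConfig(dt_ms=dt_ms, duration_ms=duration, v_init_mv=v_hold_mv)
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_iterations)
    total = None
    for it in range(n_iterations):
        sim = dataclasses.replace(base, synapses=[])
        comp = place_synapses(sim, 1, synapse_spec.kind, int(seeds[it]))[0]
        sim.attach_synapse(comp, synapse_spec, [onset])
        current = integrate(sim, cfg, clamp=clamp, initial_state=state)["clamp"]
        total = current.values if total is None else total + current.values
    mean_values = total / n_iterations
    i_on = int(onset / dt_ms)
    baseline = mean_values[1:i_on].mean()
    values = mean_values - baseline
    values[0] = values[1]  # sample 0 predates the settled segment
    mean_trace = Trace(t0=0.0, dt=dt_ms, values=values, unit="pA")

    polarity = +1 if v_hold_mv > synapse_spec.reversal_mv else -1
    metrics = psc_metrics(mean_trace, polarity)
    tau_guess = max(metrics.t50_ms / math.log(2), 4 * dt_ms)
    tpk = onset + float(np.argmax(polarity * mean_trace.values[i_on:])) * dt_ms
    fit = fit_monoexponential(
        mean_trace, (tpk, min(duration, tpk + 5.0 * tau_guess))
    )
    return MPSCResult(mean_trace=mean_trace, fit=fit, metrics=metrics)


def match_psc(
    model: CableModel,
    kind: SynapseKind,
    target_amplitude_pa: float,
    target_t50_ms: float,
    search_bounds: dict | None = None,
    n_iterations: int = 10,
    rng_seed: int = 0,
    tolerance: float = 0.02,
    max_outer: int = 15,
    v_hold_mv: float | None = None,
) -> SynapseSpec:
    """Find (gpeak, τ_decay) whose simulated mean mPSC matches the target.

    Exploits near-proportionality of the clamped somatic amplitude in gpeak
    and of the somatic t50 in τ_decay: a damped fixed-point update on both
    parameters, simulated with the same placement seeds every iteration so
    the search surface is deterministic.  Converges when both relative
    errors are within ``tolerance`` (default 2%).
    """
    base = model.spec.synapses[kind]
    bounds = {
        "gpeak_us": (base.gpeak_us * 1e-3, base.gpeak_us * 1e3),
        "tau_decay_ms": (
            max(1.5 * base.tau_rise_ms, 0.5),
            50.0 * base.tau_decay_ms,
        ),
    }
    if search_bounds:
        bounds.update(search_bounds)
    if target_amplitude_pa < 0 or target_t50_ms <= 0:
        raise MatchError("targets must be positive (amplitude may be zero)")
    if target_amplitude_pa == 0.0:
        warnings.warn("target amplitude 0: boundary solution gpeak = 0")
        return dataclasses.replace(base, gpeak_us=0.0)

    g, tau = base.gpeak_us, base.tau_decay_ms
    best_err, best_spec = np.inf, None
    for _ in range(max_outer):
        g = float(np.clip(g, *bounds["gpeak_us"]))
        tau = float(np.clip(tau, *bounds["tau_decay_ms"]))
        spec = dataclasses.replace(base, gpeak_us=g, tau_decay_ms=tau)
        result = simulate_mpsc(
            model, spec, n_iterations=n_iterations, rng_seed=rng_seed,
            v_hold_mv=v_hold_mv,
        )
        amp, t50 = result.metrics.amplitude_pa, result.metrics.t50_ms
        err = max(
            abs(amp - target_amplitude_pa) / target_amplitude_pa,
            abs(t50 - target_t50_ms) / target_t50_ms,
        )
        if err < best_err:
            best_err, best_spec = err, spec
        if err <= tolerance:
            return spec
        g *= target_amplitude_pa / amp
        tau *= target_t50_ms / t50
    raise MatchError(
        f"no convergence within budget (best relative error {best_err:.1%})",
        best_spec=best_spec,
    )


def estimate_nmda_amplitude(
    amp_ampa_pa: float,
    nmda_ampa_ratio: float,
    df_nmda_mv: float,
    df_ampa_mv: float,
) -> float:
    """NMDA mEPSC amplitude predicted from the AMPA amplitude, the
    driving-force-corrected NMDA/AMPA ratio, and the two driving forces:
    amp_AMPA · ratio · (DF_NMDA / DF_AMPA)."""
    if df_ampa_mv == 0:
        raise CalibrationError("AMPA driving force must be nonzero")
    if min(amp_ampa_pa, nmda_ampa_ratio, abs(df_nmda_mv), abs(df_ampa_mv)) < 0:
        raise CalibrationError("magnitudes must be non-negative")
    return amp_ampa_pa * nmda_ampa_ratio * (df_nmda_mv / df_ampa_mv)
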