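"""Branched-cable discretization and implicit integration of the membrane
equations.

A :class:`Morphology` is discretized into frustum compartments (the soma is a
sphere, represented by its area-equivalent cylinder).  The membrane equation
is advanced with an implicit theta-method (backward Euler by default,
Crank–Nicolson optional); the tree-structured linear system is solved exactly
at every step by ordered (Hines) elimination, which costs O(n) because
compartments are stored parent-before-child.  Gating variables advance
between voltage solves with exponential (Rush–Larsen) updates.  Synaptic
inputs are event-driven dual-exponential conductances; an ideal somatic
voltage clamp is available for miniature-PSC protocols.

Internal units: mV, ms, nA, µS, nF.  Conductance densities (S/cm²) and
currents (pA) are converted at the interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numba import njit

from .biophysics import (
    ChannelSpec,
    ModelSpec,
    Region,
    SynapseKind,
    SynapseSpec,
    waveform_peak_time,
)
from .morphology import Morphology, NodeKind

logger = logging.getLogger(__name__)

__all__ = [
    "CableModel",
    "SimulationConfig",
    "Trace",
    "CurrentStep",
    "VoltageClamp",
    "SimState",
    "IntegrationMethod",
    "EngineError",
    "NumericalError",
    "discretize",
    "integrate",
    "place_synapses",
    "detect_spikes",
    "AIS_LENGTH_UM",
    "AIS_DIAMETER_UM",
]

# Axon initial segment geometry used when a morphology lacks an axon.
AIS_LENGTH_UM = 50.0
AIS_DIAMETER_UM = 0.5

KIND_SOMA, KIND_AXON, KIND_DEND = 0, 1, 2


class EngineError(RuntimeError):
    pass


class NumericalError(EngineError):
    """Integration produced non-finite values; carries the failure time."""

    def __init__(self, t_ms: float):
        self.t_ms = t_ms
        super().__init__(f"non-finite voltage at t = {t_ms:.3f} ms")


class IntegrationMethod(Enum):
    backward_euler = "backward_euler"
    crank_nicolson = "crank_nicolson"


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series with units."""

    t0: float
    dt: float
    values: np.ndarray
    unit: str  # 'mV', 'pA' or 'uS'

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimulationConfig:
    dt_ms: float = 0.025
    duration_ms: float = 500.0
    method: IntegrationMethod = IntegrationMethod.backward_euler
    v_init_mv: float = -85.0
    spike_threshold_mv: float = -20.0
    refractory_ms: float = 2.0

    def __post_init__(self):
        if self.dt_ms <= 0 or self.duration_ms < self.dt_ms:
            raise EngineError("need dt > 0 and duration >= dt")


@dataclass(frozen=True)
class CurrentStep:
    site: int
    amplitude_pa: float
    onset_ms: float
    duration_ms: float


@dataclass(frozen=True)
class VoltageClamp:
    site: int
    v_hold_mv: float


@dataclass(frozen=True)
class SimState:
    """Snapshot of voltages and gate states, reusable as an initial
    condition (e.g. to settle a model once and branch many protocols)."""

    v_mv: np.ndarray
    act: np.ndarray
    inact: np.ndarray


@dataclass
class SynapseAttachment:
    compartment: int
    spec: SynapseSpec
    event_times_ms: np.ndarray


@dataclass
class CableModel:
    """Discretized cell: per-compartment geometry, channels and synapses.

    All per-compartment arrays are indexed with parents before children
    (compartment 0 is the soma), which is what the Hines solver requires.
    """

    spec: ModelSpec
    parent: np.ndarray  # int, -1 at root
    length_um: np.ndarray
    diam_um: np.ndarray  # mean diameter, used for axial resistance
    area_cm2: np.ndarray  # frustum lateral area (sphere for the soma)
    kind: np.ndarray  # KIND_SOMA / KIND_AXON / KIND_DEND
    synapses: list[SynapseAttachment] = field(default_factory=list)
    recording_sites: list[int] = field(default_factory=lambda: [0])

    @property
    def n_comp(self) -> int:
        return len(self.parent)

    @property
    def dendritic(self) -> np.ndarray:
        return np.nonzero(self.kind == KIND_DEND)[0]

    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())

    def attach_synapse(
        self, compartment: int, spec: SynapseSpec, event_times_ms
    ) -> None:
        self.synapses.append(
            SynapseAttachment(
                compartment=int(compartment),
                spec=spec,
                event_times_ms=np.asarray(event_times_ms, dtype=float),
            )
        )

    def clear_synapses(self) -> None:
        self.synapses = []

    # -- derived electrical arrays (µS, nF) -----------------------------------

    def capacitance_nf(self) -> np.ndarray:
        return self.spec.passive.cm_uf_cm2 * self.area_cm2 * 1e3

    def leak_us(self) -> np.ndarray:
        return self.spec.passive.g_leak_s_cm2 * self.area_cm2 * 1e6

    def axial_us(self) -> np.ndarray:
        """Axial conductance linking each compartment to its parent (µS);
        entry 0 (the root) is unused."""
        ra = self.spec.passive.ra_ohm_cm
        # half-resistance of each compartment, in MΩ:
        #   R/2 = Ra * (L/2) / (π r²),  lengths in cm
        half_r = (
            ra
            * (self.length_um * 1e-4 / 2.0)
            / (math.pi * (self.diam_um * 1e-4 / 2.0) ** 2)
        ) * 1e-6  # Ω → MΩ
        g = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            g[i] = 1.0 / (half_r[i] + half_r[self.parent[i]])
        return g


# -- discretization -----------------------------------------------------------


def _frustum_area_cm2(length_um: float, r0_um: float, r1_um: float) -> float:
    slant = math.sqrt(length_um**2 + (r1_um - r0_um) ** 2)
    return math.pi * (r0_um + r1_um) * slant * 1e-8  # µm² → cm²


def discretize(
    morphology: Morphology, spec: ModelSpec, max_seg_length_um: float = 10.0
) -> CableModel:
    """Split a morphology into compartments no longer than the stated limit.

    Membrane area equals the summed frustum areas of the morphology exactly
    (the soma is represented by the spherical area of its mean-radius node
    set).  If the spec places sodium channels in the axon initial segment and
    the morphology has no axon, a 50 µm × 0.5 µm initial segment is appended
    to the soma and the action is logged.
    """
    if max_seg_length_um <= 0:
        raise EngineError("max_seg_length_um must be > 0")

    soma_nodes = [n for n in morphology.nodes if n.kind is NodeKind.soma]
    soma_r = float(np.mean([n.radius for n in soma_nodes]))
    parent: list[int] = [-1]
    length: list[float] = [2.0 * soma_r]
    diam: list[float] = [2.0 * soma_r]
    area: list[float] = [4.0 * math.pi * soma_r**2 * 1e-8]
    kind: list[int] = [KIND_SOMA]

    node_to_comp = {n.id: 0 for n in soma_nodes}
    index = {n.id: n for n in morphology.nodes}

    for child in morphology.nodes:
        if child.parent_id == -1 or child.kind is NodeKind.soma:
            continue
        p = index[child.parent_id]
        seg_len = float(np.linalg.norm(child.xyz - p.xyz))
        if seg_len == 0.0:
            node_to_comp[child.id] = node_to_comp[p.id]
            continue
        k = KIND_AXON if child.kind is NodeKind.axon else KIND_DEND
        n_pieces = max(1, math.ceil(seg_len / max_seg_length_um - 1e-12))
        # radius interpolates linearly from parent to child along the edge;
        # stems attaching to the soma use the child's own calibre.
        r_start = child.radius if p.kind is NodeKind.soma else p.radius
        prev_comp = node_to_comp[p.id]
        for j in range(n_pieces):
            f0, f1 = j / n_pieces, (j + 1) / n_pieces
            r0 = r_start + (child.radius - r_start) * f0
            r1 = r_start + (child.radius - r_start) * f1
            piece_len = seg_len / n_pieces
            parent.append(prev_comp)
            length.append(piece_len)
            diam.append(r0 + r1)  # mean diameter = 2 * mean radius
            area.append(_frustum_area_cm2(piece_len, r0, r1))
            kind.append(k)
            prev_comp = len(parent) - 1
        node_to_comp[child.id] = prev_comp

    needs_ais = any(
        ch.region is Region.axon_initial_segment and ch.gbar_s_cm2 > 0
        for ch in spec.channels
    )
    has_axon = any(k == KIND_AXON for k in kind)
    if needs_ais and not has_axon:
        logger.info(
            "morphology lacks an axon; appending %g um x %g um initial segment",
            AIS_LENGTH_UM,
            AIS_DIAMETER_UM,
        )
        n_pieces = max(1, math.ceil(AIS_LENGTH_UM / max_seg_length_um))
        prev = 0
        r = AIS_DIAMETER_UM / 2.0
        for _ in range(n_pieces):
            piece_len = AIS_LENGTH_UM / n_pieces
            parent.append(prev)
            length.append(piece_len)
            diam.append(AIS_DIAMETER_UM)
            area.append(_frustum_area_cm2(piece_len, r, r))
            kind.append(KIND_AXON)
            prev = len(parent) - 1

    return CableModel(
        spec=spec,
        parent=np.asarray(parent, dtype=np.int64),
        length_um=np.asarray(length, dtype=float),
        diam_um=np.asarray(diam, dtype=float),
        area_cm2=np.asarray(area, dtype=float),
        kind=np.asarray(kind, dtype=np.int64),
    )


# -- channel table compilation ------------------------------------------------


def _compile_channels(model: CableModel):
    """Flatten channel placements into (entry -> compartment) arrays."""
    comp_list: list[int] = []
    gbar_list: list[float] = []
    chan_of_entry: list[int] = []
    erev = []
    for ci, ch in enumerate(model.spec.channels):
        erev.append(ch.reversal_mv)
        if ch.region is Region.axon_initial_segment:
            comps = np.nonzero(model.kind == KIND_AXON)[0]
        else:
            comps = np.nonzero(model.kind != KIND_AXON)[0]
        for c in comps:
            comp_list.append(int(c))
            gbar_list.append(ch.gbar_s_cm2 * model.area_cm2[c] * 1e6)  # µS
            chan_of_entry.append(ci)
    return (
        np.asarray(comp_list, dtype=np.int64),
        np.asarray(gbar_list, dtype=float),
        np.asarray(chan_of_entry, dtype=np.int64),
        np.asarray(erev, dtype=float),
    )


def _compile_synapses(model: CableModel, dt: float, n_steps: int):
    ns = len(model.synapses)
    syn_comp = np.zeros(ns, dtype=np.int64)
    syn_erev = np.zeros(ns)
    syn_gnorm = np.zeros(ns)
    syn_rise_mult = np.zeros(ns)
    syn_decay_mult = np.zeros(ns)
    syn_mg = np.zeros(ns)  # 0 => no block; else Mg concentration (mM)
    ev_step: list[int] = []
    ev_syn: list[int] = []
    for i, att in enumerate(model.synapses):
        s = att.spec
        syn_comp[i] = att.compartment
        syn_erev[i] = s.reversal_mv
        tpk = waveform_peak_time(s.tau_rise_ms, s.tau_decay_ms)
        norm = 1.0 / (math.exp(-tpk / s.tau_decay_ms) - math.exp(-tpk / s.tau_rise_ms))
        syn_gnorm[i] = s.gpeak_us * norm
        syn_rise_mult[i] = math.exp(-dt / s.tau_rise_ms)
        syn_decay_mult[i] = math.exp(-dt / s.tau_decay_ms)
        syn_mg[i] = s.mg_mm if (s.mg_block and s.kind is SynapseKind.NMDA) else 0.0
        for t in att.event_times_ms:
            step = int(math.ceil(t / dt - 1e-9))  # snap to next grid time
            if 0 <= step < n_steps:
                ev_step.append(step)
                ev_syn.append(i)
    order = np.argsort(np.asarray(ev_step, dtype=np.int64), kind="stable")
    return (
        syn_comp,
        syn_erev,
        syn_gnorm,
        syn_rise_mult,
        syn_decay_mult,
        syn_mg,
        np.asarray(ev_step, dtype=np.int64)[order],
        np.asarray(ev_syn, dtype=np.int64)[order],
    )


# -- the integration kernel ---------------------------------------------------


# Gate kinetics are evaluated through voltage lookup tables (steady state and
# the Rush–Larsen factor 1 - exp(-dt/tau)), built once per integrate() call.
VTAB_MIN_MV = -130.0
VTAB_MAX_MV = 70.0
VTAB_N = 2001


@njit(cache=False)
def _integrate_kernel(
    n_steps,
    dt,
    theta,
    v,
    parent,
    cm_nf,
    g_ax,
    g_leak,
    e_leak,
    ch_comp,
    ch_gbar,
    ch_of,
    ch_erev,
    act_exp,
    inact_exp,
    act_xinf,
    act_alpha,
    inact_xinf,
    inact_alpha,
    act_state,
    inact_state,
    syn_comp,
    syn_erev,
    syn_gnorm,
    syn_rise_mult,
    syn_decay_mult,
    syn_mg,
    ev_step,
    ev_syn,
    stim_comp,
    stim_amp,
    stim_on,
    stim_off,
    clamp_comp,
    clamp_v,
    rec_sites,
):
    n = v.shape[0]
    ne = ch_comp.shape[0]
    ns = syn_comp.shape[0]
    nrec = rec_sites.shape[0]
    g_clamp = 1.0e6  # µS; ideal clamp limit

    out_v = np.empty((nrec, n_steps + 1))
    out_ic = np.empty(n_steps + 1)
    for r in range(nrec):
        out_v[r, 0] = v[rec_sites[r]]
    out_ic[0] = 0.0

    diag = np.empty(n)
    off = np.empty(n)
    rhs = np.empty(n)
    g_ion = np.empty(n)
    e_ion_g = np.empty(n)
    syn_a = np.zeros(ns)
    syn_b = np.zeros(ns)

    ev_ptr = 0
    nev = ev_step.shape[0]
    fail_step = -1

    for step in range(n_steps):
        # synaptic state decay, then event arrivals for this step
        for s in range(ns):
            syn_a[s] *= syn_rise_mult[s]
            syn_b[s] *= syn_decay_mult[s]
        while ev_ptr < nev and ev_step[ev_ptr] == step:
            s = ev_syn[ev_ptr]
            syn_a[s] += 1.0
            syn_b[s] += 1.0
            ev_ptr += 1

        # ionic conductances with Rush–Larsen gate updates (table lookup)
        for i in range(n):
            g_ion[i] = g_leak[i]
            e_ion_g[i] = g_leak[i] * e_leak
        inv_dv = (VTAB_N - 1) / (VTAB_MAX_MV - VTAB_MIN_MV)
        for j in range(ne):
            c = ch_comp[j]
            k = ch_of[j]
            u = (v[c] - VTAB_MIN_MV) * inv_dv
            if u < 0.0:
                u = 0.0
            elif u > VTAB_N - 1.000001:
                u = VTAB_N - 1.000001
            i0 = int(u)
            w = u - i0
            g = ch_gbar[j]
            ea = act_exp[k]
            if ea > 0:
                xinf = act_xinf[k, i0] * (1.0 - w) + act_xinf[k, i0 + 1] * w
                aa = act_alpha[k, i0] * (1.0 - w) + act_alpha[k, i0 + 1] * w
                x = act_state[j] + (xinf - act_state[j]) * aa
                act_state[j] = x
                for _ in range(ea):
                    g *= x
            ei = inact_exp[k]
            if ei > 0:
                xinf = inact_xinf[k, i0] * (1.0 - w) + inact_xinf[k, i0 + 1] * w
                aa = inact_alpha[k, i0] * (1.0 - w) + inact_alpha[k, i0 + 1] * w
                x = inact_state[j] + (xinf - inact_state[j]) * aa
                inact_state[j] = x
                for _ in range(ei):
                    g *= x
            g_ion[c] += g
            e_ion_g[c] += g * ch_erev[k]
        for s in range(ns):
            c = syn_comp[s]
            g = syn_gnorm[s] * (syn_b[s] - syn_a[s])
            if syn_mg[s] > 0.0:
                g *= 1.0 / (1.0 + (syn_mg[s] / 3.57) * math.exp(-0.062 * v[c]))
            g_ion[c] += g
            e_ion_g[c] += g * syn_erev[s]

        # assemble theta-method system: ionic current g*(v-E) weighted theta
        # at the new time (linearized via frozen conductances) and (1-theta)
        # at the old time
        for i in range(n):
            diag[i] = cm_nf[i] / dt + theta * g_ion[i]
            rhs[i] = (
                cm_nf[i] / dt * v[i]
                - (1.0 - theta) * (g_ion[i] * v[i] - e_ion_g[i])
                + theta * e_ion_g[i]
            )
            off[i] = 0.0

        for i in range(1, n):
            p = parent[i]
            off[i] = -theta * g_ax[i]
            diag[i] += theta * g_ax[i]
            diag[p] += theta * g_ax[i]
            if theta < 1.0:
                ax_old = g_ax[i] * (v[p] - v[i])
                rhs[i] += (1.0 - theta) * ax_old
                rhs[p] -= (1.0 - theta) * ax_old

        for q in range(stim_comp.shape[0]):
            if stim_on[q] <= step < stim_off[q]:
                rhs[stim_comp[q]] += stim_amp[q]

        if clamp_comp >= 0:
            diag[clamp_comp] += g_clamp
            rhs[clamp_comp] += g_clamp * clamp_v

        # Hines elimination (children before parents), then back-substitution
        for i in range(n - 1, 0, -1):
            p = parent[i]
            factor = off[i] / diag[i]
            diag[p] -= factor * off[i]
            rhs[p] -= factor * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] - off[i] * v[parent[i]]) / diag[i]

        if not math.isfinite(v[0]):
            fail_step = step
            break

        for r in range(nrec):
            out_v[r, step + 1] = v[rec_sites[r]]
        if clamp_comp >= 0:
            out_ic[step + 1] = g_clamp * (clamp_v - v[clamp_comp])
        else:
            out_ic[step + 1] = 0.0

    return out_v, out_ic, fail_step


# -- public simulation API ----------------------------------------------------


def _init_gate_states(channels, ch_of, v_init):
    ne = len(ch_of)
    act = np.ones(ne)
    inact = np.ones(ne)
    for j in range(ne):
        ch = channels[ch_of[j]]
        if ch.activation is not None:
            act[j] = float(ch.activation.steady_state(v_init))
        if ch.inactivation is not None:
            inact[j] = float(ch.inactivation.steady_state(v_init))
    return act, inact


def _gate_tables(channels, dt: float):
    """Voltage lookup tables for every channel's gates at this time step."""
    nchan = len(channels)
    vgrid = np.linspace(VTAB_MIN_MV, VTAB_MAX_MV, VTAB_N)
    act_exp = np.zeros(nchan, dtype=np.int64)
    inact_exp = np.zeros(nchan, dtype=np.int64)
    act_xinf = np.zeros((nchan, VTAB_N))
    act_alpha = np.zeros((nchan, VTAB_N))
    inact_xinf = np.zeros((nchan, VTAB_N))
    inact_alpha = np.zeros((nchan, VTAB_N))
    for k, ch in enumerate(channels):
        if ch.activation is not None:
            act_exp[k] = ch.activation.exponent
            act_xinf[k] = ch.activation.steady_state(vgrid)
            act_alpha[k] = 1.0 - np.exp(-dt / ch.activation.tau(vgrid))
        if ch.inactivation is not None:
            inact_exp[k] = ch.inactivation.exponent
            inact_xinf[k] = ch.inactivation.steady_state(vgrid)
            inact_alpha[k] = 1.0 - np.exp(-dt / ch.inactivation.tau(vgrid))
    return act_exp, inact_exp, act_xinf, act_alpha, inact_xinf, inact_alpha


def integrate(
    model: CableModel,
    config: SimulationConfig,
    stimuli: tuple[CurrentStep, ...] | list[CurrentStep] = (),
    clamp: VoltageClamp | None = None,
    initial_state: SimState | None = None,
    return_state: bool = False,
) -> dict:
    """Integrate the model and return traces at the recording sites.

    Returns a dict mapping each recording-site compartment index to a
    voltage :class:`Trace` (mV); under a :class:`VoltageClamp` the electrode
    current is returned under the key ``'clamp'`` as a pA trace (inward
    current negative).  ``initial_state`` (from a previous run with
    ``return_state``, key ``'state'``) replaces the uniform cold start.
    Deterministic: identical inputs give identical output arrays.
    """
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    theta = 1.0 if config.method is IntegrationMethod.backward_euler else 0.5

    ch_comp, ch_gbar, ch_of, ch_erev = _compile_channels(model)
    act_exp, inact_exp, act_xinf, act_alpha, inact_xinf, inact_alpha = _gate_tables(
        model.spec.channels, dt
    )
    (
        syn_comp,
        syn_erev,
        syn_gnorm,
        syn_rm,
        syn_dm,
        syn_mg,
        ev_step,
        ev_syn,
    ) = _compile_synapses(model, dt, n_steps)

    if initial_state is not None:
        v = initial_state.v_mv.copy()
        act_state = initial_state.act.copy()
        inact_state = initial_state.inact.copy()
        if len(v) != model.n_comp or len(act_state) != len(ch_comp):
            raise EngineError("initial state does not match this model")
    else:
        v = np.full(model.n_comp, config.v_init_mv, dtype=float)
        if clamp is not None:
            v[:] = clamp.v_hold_mv
        act_state, inact_state = _init_gate_states(
            model.spec.channels, ch_of, float(v[0])
        )

    stim_comp = np.asarray([s.site for s in stimuli], dtype=np.int64)
    stim_amp = np.asarray([s.amplitude_pa * 1e-3 for s in stimuli], dtype=float)
    stim_on = np.asarray(
        [int(round(s.onset_ms / dt)) for s in stimuli], dtype=np.int64
    )
    stim_off = np.asarray(
        [int(round((s.onset_ms + s.duration_ms) / dt)) for s in stimuli],
        dtype=np.int64,
    )

    rec_sites = np.asarray(model.recording_sites, dtype=np.int64)

    out_v, out_ic, fail_step = _integrate_kernel(
        n_steps,
        dt,
        theta,
        v,
        model.parent,
        model.capacitance_nf(),
        model.axial_us(),
        model.leak_us(),
        model.spec.passive.e_leak_mv,
        ch_comp,
        ch_gbar,
        ch_of,
        ch_erev,
        act_exp,
        inact_exp,
        act_xinf,
        act_alpha,
        inact_xinf,
        inact_alpha,
        act_state,
        inact_state,
        syn_comp,
        syn_erev,
        syn_gnorm,
        syn_rm,
        syn_dm,
        syn_mg,
        ev_step,
        ev_syn,
        stim_comp,
        stim_amp,
        stim_on,
        stim_off,
        -1 if clamp is None else int(clamp.site),
        0.0 if clamp is None else float(clamp.v_hold_mv),
        rec_sites,
    )
    if fail_step >= 0:
        raise NumericalError(t_ms=fail_step * dt)

    result: dict = {}
    for r, site in enumerate(model.recording_sites):
        result[site] = Trace(t0=0.0, dt=dt, values=out_v[r].copy(), unit="mV")
    if clamp is not None:
        result["clamp"] = Trace(
            t0=0.0, dt=dt, values=out_ic * 1e3, unit="pA"
        )  # nA → pA
    if return_state:
        result["state"] = SimState(
            v_mv=v.copy(), act=act_state.copy(), inact=inact_state.copy()
        )
    return result


def place_synapses(
    model: CableModel, n: int, kind: SynapseKind, rng_seed: int
) -> np.ndarray:
    """Draw n dendritic compartments uniformly per unit dendritic length.

    Returns the compartment indices only; attaching specs and event trains
    is the caller's job.  Seed-deterministic.
    """
    if n < 0:
        raise EngineError("n must be >= 0")
    dend = model.dendritic
    if dend.size == 0:
        raise EngineError("model has no dendritic compartments")
    weights = model.length_um[dend]
    total = weights.sum()
    if total <= 0:
        raise EngineError("model has zero dendritic length")
    rng = np.random.default_rng(rng_seed)
    return rng.choice(dend, size=n, replace=True, p=weights / total)


def detect_spikes(
    voltage_trace: Trace, threshold_mv: float = -20.0, refractory_ms: float = 2.0
) -> np.ndarray:
    """Upward threshold-crossing times (ms) separated by the refractory gap."""
    v = voltage_trace.values
    crossings = np.nonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))[0]
    times = voltage_trace.t0 + (crossings + 1) * voltage_trace.dt
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)
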