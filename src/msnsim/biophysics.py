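"""Declarative membrane and synapse specifications for the D1-MSN model.

Channel complement and surface densities follow the published D1-MSN model:
fast sodium confined to the axon initial segment (2.4 S/cm²), L-type calcium
(CaV1.2 6.7e-6, CaV1.3 1.0e-4 S/cm²) and four potassium conductances
(KAs 4.0e-5, KDR 5.0e-3, KIR 1.0e-4, KRP 2.0e-4 S/cm²) on soma and
dendrites, passive leak everywhere.  Synaptic inputs are conductance-based
dual-exponential waveforms with published starting peak conductances
(AMPA 7.2e-4 µS, GABA_A 3.6e-4 µS, NMDA 6.8e-5 µS).

Gate kinetics are expressed as Boltzmann steady states with constant or
bell-shaped voltage-dependent time constants.  The specific rate parameters
used here are this package's own calibration: they are data, chosen to give
MSN-like behaviour (hyperpolarized rest dominated by the inward rectifier,
delayed spike onset, f–I growth over 10–80 pA somatic steps), and can be
overridden wholesale from configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "PassiveSpec",
    "GateSpec",
    "ChannelSpec",
    "SynapseSpec",
    "PSCTarget",
    "ModelSpec",
    "Region",
    "SynapseKind",
    "BiophysicsError",
    "default_model_spec",
    "synaptic_conductance_waveform",
    "waveform_peak_time",
    "nmda_mg_factor",
]


class BiophysicsError(ValueError):
    pass


class Region(Enum):
    axon_initial_segment = "axon_initial_segment"
    soma_and_dendrites = "soma_and_dendrites"


class SynapseKind(Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA_A = "GABA_A"


@dataclass(frozen=True)
class PassiveSpec:
    """Passive membrane: capacitance, axial resistivity and leak."""

    cm_uf_cm2: float = 1.0
    ra_ohm_cm: float = 150.0
    g_leak_s_cm2: float = 8.0e-6
    e_leak_mv: float = -70.0

    def __post_init__(self):
        if min(self.cm_uf_cm2, self.ra_ohm_cm, self.g_leak_s_cm2) <= 0:
            raise BiophysicsError("passive parameters must be positive")


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin–Huxley gate: Boltzmann steady state, parametric tau.

    ``x_inf(v) = 1 / (1 + exp(-(v - vhalf)/slope))`` — a positive slope opens
    the gate with depolarization (activation), a negative slope closes it
    (inactivation / inward rectification).  The time constant is either the
    constant ``tau_base_ms`` or, when ``tau_amp_ms > 0``, the bell
    ``tau_base + tau_amp / (exp((v - tau_vmax)/tau_sig) +
    exp(-(v - tau_vmax)/tau_sig))``.
    """

    exponent: int
    vhalf_mv: float
    slope_mv: float
    tau_base_ms: float
    tau_amp_ms: float = 0.0
    tau_vmax_mv: float = 0.0
    tau_sig_mv: float = 15.0

    def __post_init__(self):
        if self.exponent < 0:
            raise BiophysicsError("gate exponent must be >= 0")
        if self.slope_mv == 0:
            raise BiophysicsError("gate slope must be nonzero")
        if self.tau_base_ms <= 0:
            raise BiophysicsError("tau_base_ms must be > 0")

    def steady_state(self, v_mv):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v_mv, float) - self.vhalf_mv) / self.slope_mv))

    def tau(self, v_mv):
        v = np.asarray(v_mv, float)
        if self.tau_amp_ms == 0.0:
            return np.full_like(v, self.tau_base_ms)
        u = (v - self.tau_vmax_mv) / self.tau_sig_mv
        return self.tau_base_ms + self.tau_amp_ms / (np.exp(u) + np.exp(-u))


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage-gated conductance population with placement region."""

    name: str
    gbar_s_cm2: float
    reversal_mv: float
    region: Region
    activation: GateSpec | None = None
    inactivation: GateSpec | None = None

    def __post_init__(self):
        if self.gbar_s_cm2 < 0:
            raise BiophysicsError(f"{self.name}: gbar must be >= 0")
        if self.name == "Na" and self.region is not Region.axon_initial_segment:
            raise BiophysicsError("Na channels are restricted to the axon initial segment")
        if self.name != "Na" and self.region is Region.axon_initial_segment:
            raise BiophysicsError(f"{self.name} belongs on soma and dendrites")


@dataclass(frozen=True)
class SynapseSpec:
    """A conductance-based synapse with dual-exponential kinetics."""

    kind: SynapseKind
    gpeak_us: float
    tau_rise_ms: float
    tau_decay_ms: float
    reversal_mv: float
    mg_block: bool = False
    mg_mm: float = 1.0

    def __post_init__(self):
        if self.gpeak_us < 0:
            raise BiophysicsError("gpeak must be >= 0")
        if not (0 < self.tau_rise_ms < self.tau_decay_ms):
            raise BiophysicsError("need tau_decay > tau_rise > 0")
        if self.mg_block and self.kind is not SynapseKind.NMDA:
            raise BiophysicsError("Mg block applies to NMDA only")


@dataclass(frozen=True)
class PSCTarget:
    """Calibration target for one synapse type: somatic mPSC amplitude and
    time from peak to half decay."""

    amplitude_pa: float
    t50_ms: float
    v_hold_mv: float


@dataclass(frozen=True)
class ModelSpec:
    """Full declarative model: passive membrane, channels, synapses, and the
    genotype-specific mPSC calibration targets and morphology preset."""

    genotype: str
    passive: PassiveSpec
    channels: tuple[ChannelSpec, ...]
    synapses: dict[SynapseKind, SynapseSpec]
    psc_targets: dict[SynapseKind, PSCTarget]
    morphology_preset: str

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise BiophysicsError(f"no channel named {name!r}")

    def with_synapse(self, spec: SynapseSpec) -> "ModelSpec":
        synapses = dict(self.synapses)
        synapses[spec.kind] = spec
        return replace(self, synapses=synapses)


# Published surface densities (S/cm²); one channel set serves both genotypes.
_CHANNEL_DENSITIES = {
    "Na": 2.4,
    "CaV12": 6.7e-6,
    "CaV13": 1.0e-4,
    "KAS": 4.0e-5,
    "KDR": 5.0e-3,
    "KIR": 1.0e-4,
    "KRP": 2.0e-4,
}

E_NA_MV = 50.0
E_K_MV = -90.0
E_CA_MV = 120.0
E_EXC_MV = 0.0
E_GABA_MV = -60.0


def _default_channels() -> tuple[ChannelSpec, ...]:
    g = _CHANNEL_DENSITIES
    sd = Region.soma_and_dendrites
    return (
        ChannelSpec(
            "Na",
            g["Na"],
            E_NA_MV,
            Region.axon_initial_segment,
            activation=GateSpec(3, -38.0, 6.0, 0.2, tau_amp_ms=0.5, tau_vmax_mv=-40.0, tau_sig_mv=15.0),
            inactivation=GateSpec(1, -60.0, -4.0, 1.0, tau_amp_ms=8.0, tau_vmax_mv=-65.0, tau_sig_mv=15.0),
        ),
        ChannelSpec(
            "CaV12",
            g["CaV12"],
            E_CA_MV,
            sd,
            activation=GateSpec(2, -8.9, 6.7, 1.0),
        ),
        ChannelSpec(
            "CaV13",
            g["CaV13"],
            E_CA_MV,
            sd,
            activation=GateSpec(1, -33.0, 6.7, 1.0),
        ),
        ChannelSpec(
            "KAS",
            g["KAS"],
            E_K_MV,
            sd,
            activation=GateSpec(2, -27.0, 16.0, 5.0),
            inactivation=GateSpec(1, -58.0, -10.0, 300.0),
        ),
        ChannelSpec(
            "KDR",
            g["KDR"],
            E_K_MV,
            sd,
            activation=GateSpec(2, -25.0, 12.0, 1.0, tau_amp_ms=15.0, tau_vmax_mv=-50.0, tau_sig_mv=15.0),
        ),
        ChannelSpec(
            "KIR",
            g["KIR"],
            E_K_MV,
            sd,
            activation=GateSpec(1, -82.0, -13.0, 1.0),
        ),
        ChannelSpec(
            "KRP",
            g["KRP"],
            E_K_MV,
            sd,
            activation=GateSpec(1, -13.0, 9.0, 80.0),
        ),
    )


def _default_synapses() -> dict[SynapseKind, SynapseSpec]:
    return {
        SynapseKind.AMPA: SynapseSpec(
            SynapseKind.AMPA, 7.2e-4, 0.5, 4.3, E_EXC_MV
        ),
        SynapseKind.GABA_A: SynapseSpec(
            SynapseKind.GABA_A, 3.6e-4, 0.8, 10.0, E_GABA_MV
        ),
        # Recordings constraining the model were done Mg-free; block off.
        SynapseKind.NMDA: SynapseSpec(
            SynapseKind.NMDA, 6.8e-5, 3.0, 50.0, E_EXC_MV, mg_block=False
        ),
    }


# Genotype-specific somatic mPSC targets.  AMPA amplitudes are the measured
# means at Vhold=-70 mV (15.0 pA wild type, 19.3 pA knockout); NMDA targets
# are the driving-force-scaled estimates at +40 mV.  GABA targets encode the
# measured direction (smaller, faster mIPSCs in the knockout) with magnitudes
# typical of mIPSCs at +40 mV.
_PSC_TARGETS = {
    "wt": {
        SynapseKind.AMPA: PSCTarget(15.0, 4.5, -70.0),
        SynapseKind.GABA_A: PSCTarget(25.0, 8.0, +40.0),
        SynapseKind.NMDA: PSCTarget(5.8, 35.0, +40.0),
    },
    "ko": {
        SynapseKind.AMPA: PSCTarget(19.3, 4.5, -70.0),
        SynapseKind.GABA_A: PSCTarget(19.0, 6.0, +40.0),
        SynapseKind.NMDA: PSCTarget(6.3, 35.0, +40.0),
    },
}


def default_model_spec(genotype: str) -> ModelSpec:
    """The default D1-MSN model for ``'wt'`` or ``'ko'``.

    Channel densities and kinetics are identical across genotypes (the model
    uses one channel set); the genotype selects the synthetic-morphology
    preset and the mPSC calibration targets.
    """
    if genotype not in ("wt", "ko"):
        raise BiophysicsError(f"unknown genotype {genotype!r}")
    return ModelSpec(
        genotype=genotype,
        passive=PassiveSpec(),
        channels=_default_channels(),
        synapses=_default_synapses(),
        psc_targets=dict(_PSC_TARGETS[genotype]),
        morphology_preset=genotype,
    )


def waveform_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time to peak of the dual-exponential conductance (ms)."""
    tr, td = tau_rise_ms, tau_decay_ms
    return math.log(td / tr) * tr * td / (td - tr)


def synaptic_conductance_waveform(spec: SynapseSpec, t_ms):
    """Dual-exponential conductance g(t) in µS, normalized to peak at gpeak.

    ``g(t) = gpeak · N · (exp(-t/τ_d) - exp(-t/τ_r))`` with N such that the
    maximum equals gpeak; zero for t < 0.
    """
    t = np.asarray(t_ms, dtype=float)
    tr, td = spec.tau_rise_ms, spec.tau_decay_ms
    tpk = waveform_peak_time(tr, td)
    norm = 1.0 / (math.exp(-tpk / td) - math.exp(-tpk / tr))
    g = spec.gpeak_us * norm * (np.exp(-t / td) - np.exp(-t / tr))
    return np.where(t >= 0, g, 0.0)


def nmda_mg_factor(v_mv, mg_mm: float = 1.0):
    """Fraction of NMDA conductance unblocked by Mg²⁺ at voltage v.

    Standard sigmoidal voltage dependence,
    ``1 / (1 + (mg/3.57 mM) · exp(-0.062 · V))``; equals 1 everywhere when
    mg is 0.
    """
    if mg_mm < 0:
        raise BiophysicsError("mg_mm must be >= 0")
    v = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + (mg_mm / 3.57) * np.exp(-0.062 * v))
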