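"""Two-compartment membrane machinery.

The neuron is a somatic leaky integrate-and-fire compartment coupled to a
single dendritic compartment through directional conductances: ``g_cds``
(dendrite -> soma, zeroed during refractoriness) and ``g_csd`` (soma ->
dendrite). In the calcium model variants a somatic spike jumps the soma to a
peak voltage and transiently boosts ``g_csd`` by a double-exponential pulse
of amplitude ``m_csd`` (the bAP strength), emulating the invasion of the
backpropagating action potential into the dendrite. The dendrite carries
double-exponential excitatory/inhibitory synaptic conductances and,
optionally, an HVA Ca2+ channel with m^2 h kinetics and an NMDA conductance
with the Jahr-Stevens magnesium block.

Units throughout: mV, ms, nS, pF; currents therefore come out in pA and
``dV/dt = I / C`` is in mV/ms with no extra factors.

The functions in this module are straightforward scalar/vector reference
implementations used for unit testing and small simulations; the production
trial loop lives in :mod:`baplearn._kernels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPIKE_TRACE", "CALCIUM", "CALCIUM_NMDAR", "VARIANTS",
    "SomaParams", "DendriteParams", "ChannelKinetics", "HVAParams",
    "NMDAParams", "CouplingParams", "HomeostasisParams",
    "DoubleExpState", "HVAState", "HomeostasisState",
    "double_exp_t_peak", "double_exp_norm", "double_exp_response",
    "step_conductance", "hva_rates", "step_hva", "mg_block", "nmda_currents",
    "step_coupling", "step_soma", "step_dendrite", "homeostatic_rescale",
]

# model variant codes (shared with the numba kernels)
SPIKE_TRACE = 0
CALCIUM = 1
CALCIUM_NMDAR = 2
VARIANTS = {"spike_trace": SPIKE_TRACE, "calcium": CALCIUM, "calcium_nmdar": CALCIUM_NMDAR}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaParams:
    c_s: float = 150.0      # pF
    g_ls: float = 10.0      # nS
    g_lsr: float = 150.0    # nS, refractory leak (calcium variants), >> g_ls
    v_ls: float = -70.0     # mV
    v_th: float = -50.0     # mV
    v_re: float = -70.0     # mV
    v_peak: float = 40.0    # mV (calcium variants)
    tau_ref: float = 2.5    # ms, in [2, 3]

    def __post_init__(self):
        if not (self.v_re < self.v_th < self.v_peak):
            raise ValueError("require V_re < V_th < V_peak")
        if not 2.0 <= self.tau_ref <= 3.0:
            raise ValueError("tau_ref must lie in [2, 3] ms")


@dataclass(frozen=True)
class ChannelKinetics:
    """Double-exponential conductance channel (peak-normalized)."""

    tau_rise: float
    tau_decay: float
    gbar: float = 1.0  # nS per unit weighted impulse

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_rise == self.tau_decay:
            raise ValueError("tau_rise must differ from tau_decay (alpha limit unsupported)")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("require tau_rise < tau_decay")


@dataclass(frozen=True)
class DendriteParams:
    c_d: float = 120.0
    g_ld: float = 8.0
    v_ld: float = -70.0
    v_er: float = 0.0
    v_ir: float = -80.0
    exc: ChannelKinetics = field(default_factory=lambda: ChannelKinetics(0.5, 5.0, 0.84))
    inh: ChannelKinetics = field(default_factory=lambda: ChannelKinetics(1.0, 10.0, 0.57))
    rho: float = 40.0  # Gaussian membrane current noise amplitude, pA per sqrt(ms)

    def __post_init__(self):
        if not (self.v_ir < self.v_ld < self.v_er):
            raise ValueError("require V_ir < V_ld < V_er")


@dataclass(frozen=True)
class HVAParams:
    g_ca: float = 5.0   # nS
    v_ca: float = 120.0  # mV


@dataclass(frozen=True)
class NMDAParams:
    kinetics: ChannelKinetics = field(default_factory=lambda: ChannelKinetics(3.3, 102.38, 0.07))
    v_rev: float = 0.0
    f_ca: float = 0.05      # fraction of NMDA current carried by Ca2+
    mg: float = 1.0         # mM
    fraction: float = 0.75  # share of excitatory synapses with NMDARs

    def __post_init__(self):
        if self.mg < 0:
            raise ValueError("Mg concentration must be >= 0")
        if not 0.0 <= self.f_ca <= 1.0:
            raise ValueError("f_ca must lie in [0, 1]")


@dataclass(frozen=True)
class CouplingParams:
    g_cds: float = 35.0    # nS, dendrite -> soma (0 during refractoriness)
    g_csdr: float = 23.0   # nS, resting soma -> dendrite
    m_csd: float = 0.0     # nS, bAP pulse amplitude
    tau_rise: float = 0.2
    tau_decay: float = 2.5

    def __post_init__(self):
        if self.m_csd < 0:
            raise ValueError("m_csd must be >= 0")


@dataclass(frozen=True)
class HomeostasisParams:
    t_kappa: float = 100.0  # ms between multiplicative rescaling updates


# ---------------------------------------------------------------------------
# double-exponential filter
# ---------------------------------------------------------------------------

def double_exp_t_peak(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of the (rise, decay) double exponential."""
    return (tau_decay * tau_rise) / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def double_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Denominator normalizing the filter so a unit impulse peaks at 1."""
    tp = double_exp_t_peak(tau_rise, tau_decay)
    return np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)


def double_exp_response(t, tau_rise: float, tau_decay: float):
    """Closed-form peak-normalized response to a unit impulse at t=0."""
    t = np.asarray(t, dtype=np.float64)
    out = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / double_exp_norm(tau_rise, tau_decay)
    return np.where(t >= 0, out, 0.0)


@dataclass
class DoubleExpState:
    """Filter state: the two exponentials and derived normalized output F."""

    kin: ChannelKinetics
    xi_rise: float = 0.0
    xi_decay: float = 0.0

    @property
    def f(self) -> float:
        return (self.xi_decay - self.xi_rise) / double_exp_norm(self.kin.tau_rise, self.kin.tau_decay)

    @property
    def conductance(self) -> float:
        return self.kin.gbar * self.f


def step_conductance(state: DoubleExpState, impulse_sum: float, dt: float) -> DoubleExpState:
    """Advance the linear filter one step; the impulse (weighted presynaptic
    spike sum, or the bAP pulse ``m_csd``) enters both exponentials.

    The exponentials decay with their exact per-step factors, so the impulse
    response on the grid equals the closed-form double exponential."""
    k = state.kin
    state.xi_decay = state.xi_decay * np.exp(-dt / k.tau_decay) + impulse_sum
    state.xi_rise = state.xi_rise * np.exp(-dt / k.tau_rise) + impulse_sum
    return state


# ---------------------------------------------------------------------------
# HVA Ca2+ channel (m^2 h kinetics)
# ---------------------------------------------------------------------------

def hva_rates(v_d):
    """Voltage-dependent HVA rate constants and their steady-state summaries.

    Returns ``(m_alpha, m_beta, h_alpha, h_beta, m_inf, h_inf, tau_m, tau_h)``.
    The removable singularity of ``m_alpha`` at V_d = -27 mV is evaluated by
    its analytic limit 0.055 * 3.8.
    """
    v = np.asarray(v_d, dtype=np.float64)
    x = (-27.0 - v) / 3.8
    with np.errstate(over="ignore", invalid="ignore"):
        m_alpha = np.where(
            np.abs(x) < 1e-7, 0.055 * 3.8, 0.055 * 3.8 * x / np.expm1(x)
        )
    m_beta = 0.94 * np.exp((-75.0 - v) / 17.0)
    h_alpha = 0.000457 * np.exp((-13.0 - v) / 50.0)
    h_beta = 0.0065 / (np.exp((-v - 15.0) / 28.0) + 1.0)
    m_inf = m_alpha / (m_alpha + m_beta)
    h_inf = h_alpha / (h_alpha + h_beta)
    tau_m = 1.0 / (m_alpha + m_beta)
    tau_h = 1.0 / (h_alpha + h_beta)
    return m_alpha, m_beta, h_alpha, h_beta, m_inf, h_inf, tau_m, tau_h


@dataclass
class HVAState:
    m: float = 0.0
    h: float = 1.0
    params: HVAParams = field(default_factory=HVAParams)


def step_hva(state: HVAState, v_d: float, dt: float) -> tuple[HVAState, float]:
    """Euler-advance the gates and return the (inward, depolarizing) Ca current
    ``I_Ca = g_Ca m^2 h (V_Ca - V_d)`` in pA."""
    *_, m_inf, h_inf, tau_m, tau_h = hva_rates(v_d)
    state.m += dt * (m_inf - state.m) / tau_m
    state.h += dt * (h_inf - state.h) / tau_h
    for name in ("m", "h"):
        g = getattr(state, name)
        if g < -1e-9 or g > 1.0 + 1e-9:
            warnings.warn(f"HVA gate {name} left [0,1]; clamping")
        setattr(state, name, min(max(g, 0.0), 1.0))
    i_ca = state.params.g_ca * state.m**2 * state.h * (state.params.v_ca - v_d)
    return state, i_ca


# ---------------------------------------------------------------------------
# NMDA receptor
# ---------------------------------------------------------------------------

def mg_block(v, mg: float = 1.0):
    """Jahr-Stevens magnesium-block factor ``1 / (1 + [Mg]/3.57 e^{-0.062 V})``."""
    return 1.0 / (1.0 + mg / 3.57 * np.exp(-0.062 * np.asarray(v, dtype=np.float64)))


def nmda_currents(v_d: float, g_nmda: float, mg: float, f_ca: float, v_rev: float = 0.0):
    """Split the NMDA conductance into its non-Ca and Ca current components.

    ``I_NMDA = g MgB (V_rev - V_d)(1-f)`` and ``I_Ca^{NMDA} = g MgB (V_rev - V_d) f``;
    the latter adds to the HVA Ca current before integration into C(t)."""
    if mg < 0:
        raise ValueError("Mg must be >= 0")
    drive = g_nmda * mg_block(v_d, mg) * (v_rev - v_d)
    return drive * (1.0 - f_ca), drive * f_ca


# ---------------------------------------------------------------------------
# coupling, soma, dendrite
# ---------------------------------------------------------------------------

def step_coupling(state: DoubleExpState, somatic_spike: bool, params: CouplingParams,
                  dt: float) -> float:
    """Advance the bAP pulse filter and return the boosted conductance
    ``g_csd = g_csdr + F_csd(t)`` (the pulse peaks at ``m_csd`` nS)."""
    step_conductance(state, params.m_csd if somatic_spike else 0.0, dt)
    return params.g_csdr + state.kin.gbar * state.f


def step_soma(v_s: float, params: SomaParams, coupling: CouplingParams, v_d: float,
              dt: float, refractory: int, variant: int = SPIKE_TRACE
              ) -> tuple[float, bool, int]:
    """One Euler step of the somatic compartment.

    Returns ``(v_s, spiked, refractory_steps_remaining)``. During the
    refractory period the spike-trace variant halts integration at ``V_re``;
    the calcium variants hyperpolarize through the enlarged leak ``g_lsr``
    with all dendritic/synaptic input to the soma gated off."""
    if not np.isfinite(v_s) or not np.isfinite(v_d):
        bad = "V_s" if not np.isfinite(v_s) else "V_d"
        raise FloatingPointError(f"membrane potential diverged: {bad} is not finite")
    if refractory > 0:
        if variant != SPIKE_TRACE:
            v_s += dt * params.g_lsr * (params.v_ls - v_s) / params.c_s
        return v_s, False, refractory - 1
    v_s += dt * (coupling.g_cds * (v_d - v_s) + params.g_ls * (params.v_ls - v_s)) / params.c_s
    if v_s > params.v_th:
        n_ref = int(round(params.tau_ref / dt))
        v_s = params.v_re if variant == SPIKE_TRACE else params.v_peak
        return v_s, True, n_ref
    return v_s, False, 0


def step_dendrite(v_d: float, params: DendriteParams, dt: float, *, g_e: float = 0.0,
                  g_i: float = 0.0, i_csd: float = 0.0, i_ca: float = 0.0,
                  i_nmda: float = 0.0, noise: float = 0.0) -> float:
    """One Euler step of the dendritic compartment (currents in pA)."""
    if not np.isfinite(v_d):
        raise FloatingPointError("membrane potential diverged: V_d is not finite")
    i_total = (
        params.g_ld * (params.v_ld - v_d)
        + g_e * (params.v_er - v_d)
        + g_i * (params.v_ir - v_d)
        + i_csd + i_ca + i_nmda + noise
    )
    return v_d + dt * i_total / params.c_d


# ---------------------------------------------------------------------------
# homeostatic rescaling
# ---------------------------------------------------------------------------

@dataclass
class HomeostasisState:
    kappa: float = 1.0
    theta: float = 0.0  # reference total displacement sum |w_i|


def homeostatic_rescale(weights: np.ndarray, state: HomeostasisState) -> HomeostasisState:
    """Periodic multiplicative renormalization of the effective input strength.

    kappa multiplies the weights at conductance-integration time only (the
    stored weights are never mutated). The update preserves the product
    ``kappa * sum|w|`` across the call, so the total effective synaptic
    displacement seen by the dendrite stays at its reference value; the
    reference is then advanced to the new displacement sum."""
    theta_star = float(np.sum(np.abs(weights)))
    if theta_star == 0.0:
        warnings.warn("sum |w| is zero; skipping homeostatic update")
        return state
    if state.theta == 0.0:
        state.theta = theta_star
        return state
    state.kappa = state.kappa * state.theta / theta_star
    state.theta = theta_star
    return state
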