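"""Self-supervised Hebbian plasticity rule.

The induced plasticity of synapse i is the three-factor product

    PI(i, t) = e(t) * PSP(i, t) * zeta(|w_i|)

where ``e(t)`` is a purely postsynaptic short-term excitability signal (a
fast activity trace minus its own low-pass average), ``PSP(i, t)`` is a
per-synapse low-pass filter of weighted presynaptic impulses, and ``zeta``
is an alpha-function scaling that lets small weights grow quickly while
saturating large ones, shaping long-tailed weight distributions.

Two flavors of the excitability signal exist: the spike-trace form
``e = Y - Ybar`` (Y jumps by 1 at each somatic spike and decays with tau_Y)
and the calcium form ``e_c = C - Cbar`` with C integrating the dendritic
calcium current. PI is low-pass filtered into an eligibility ``dw`` which
the weight integrates at learning rate ``eta``; a Dale clamp zeroes any
eligibility whose application would flip the sign of the synapse.

None of these traces feed back into the membrane equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams", "TraceSet", "SynapseArray",
    "zeta", "step_spike_traces", "step_calcium_trace", "step_psp",
    "plasticity_induction", "step_weight_update",
]


@dataclass(frozen=True)
class PlasticityParams:
    tau_y: float = 20.0       # ms, fast spike trace
    tau_ybar: float = 35.0    # ms, its running average
    tau_c: float = 20.0       # ms, calcium trace
    tau_cbar: float = 35.0    # ms, its running average
    c0: float = 0.05          # resting calcium (arbitrary units)
    phi: float = 0.25         # scales I_Ca (pA) into concentration per ms
    tau_p: float = 7.0        # ms, PSP trace
    phi_zeta: float = 0.0     # alpha-function root of the weight scaling
    tau_zeta: float = 2.2     # alpha-function scale (peak at phi_zeta + tau_zeta)
    eta: float = 2.8          # learning rate, 1/ms
    tau_delta: float = 260.0  # ms, eligibility filter

    def __post_init__(self):
        for name in ("tau_y", "tau_ybar", "tau_c", "tau_cbar", "tau_p",
                     "tau_zeta", "tau_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class TraceSet:
    """Postsynaptic plasticity traces (never feed back into the membrane)."""

    params: PlasticityParams
    y: float = 0.0
    ybar: float = 0.0
    c: float = 0.0
    cbar: float = 0.0

    def __post_init__(self):
        if self.c == 0.0:
            self.c = self.params.c0
        if self.cbar == 0.0:
            self.cbar = self.params.c0

    @property
    def e(self) -> float:
        """Spike-trace excitability signal."""
        return self.y - self.ybar

    @property
    def e_c(self) -> float:
        """Calcium excitability signal."""
        return self.c - self.cbar


@dataclass
class SynapseArray:
    """Per-afferent plastic state: weight, eligibility, PSP trace, Dale sign."""

    w: np.ndarray
    sign: np.ndarray
    params: PlasticityParams
    dw: np.ndarray = None
    psp: np.ndarray = None
    nmda_mask: np.ndarray = None

    def __post_init__(self):
        n = len(self.w)
        if self.dw is None:
            self.dw = np.zeros(n)
        if self.psp is None:
            self.psp = np.zeros(n)
        if self.nmda_mask is None:
            self.nmda_mask = np.zeros(n, dtype=bool)
        if np.any(self.w * self.sign < 0):
            raise ValueError("weights must obey their Dale signs")


def zeta(w_abs, phi_zeta: float = 0.0, tau_zeta: float = 2.0):
    """Alpha-function weight scaling, clipped to [0, 1].

    ``zeta(x) = ((x - phi)/tau) exp(-(x - phi - tau)/tau)`` has its root at
    ``x = phi`` and unit peak at ``x = phi + tau``; below the root it is
    clipped to 0 so the factor remains a scaling in [0, 1]."""
    x = (np.asarray(w_abs, dtype=np.float64) - phi_zeta) / tau_zeta
    return np.clip(x * np.exp(1.0 - x), 0.0, 1.0)


def step_spike_traces(traces: TraceSet, somatic_spike: bool, dt: float) -> TraceSet:
    """Advance Y (jump +1 on a spike, exact exponential decay) and its
    low-pass average Ybar."""
    p = traces.params
    if somatic_spike:
        traces.y += 1.0
    a = np.exp(-dt / p.tau_ybar)
    traces.ybar = a * traces.ybar + (1.0 - a) * traces.y
    traces.y *= np.exp(-dt / p.tau_y)
    return traces


def step_calcium_trace(traces: TraceSet, i_ca_total: float, dt: float) -> TraceSet:
    """Advance C(t) from the total dendritic Ca current (HVA + NMDA share)
    and its low-pass average Cbar."""
    p = traces.params
    traces.c += dt * (p.phi * i_ca_total - (traces.c - p.c0) / p.tau_c)
    a = np.exp(-dt / p.tau_cbar)
    traces.cbar = a * traces.cbar + (1.0 - a) * traces.c
    return traces


def step_psp(syn: SynapseArray, presyn_impulses: np.ndarray, dt: float) -> SynapseArray:
    """Advance the per-synapse PSP traces.

    ``presyn_impulses`` counts presynaptic spikes per synapse this step; each
    delta adds ``|w_i| / tau_p`` (impulse response of tau_p dPSP/dt = I - PSP).
    The trace carries the synaptic *magnitude* for both classes, so positive
    excitability potentiates coincident excitation and weakens coincident
    inhibition (both signed weights move upward), while the negative phase
    reverses both — the combination that lets learned responses disinhibit
    themselves and strengthen rival-pattern inhibition."""
    p = syn.params
    syn.psp *= np.exp(-dt / p.tau_p)
    if np.any(presyn_impulses):
        syn.psp += np.abs(syn.w) * presyn_impulses / p.tau_p
    return syn


def plasticity_induction(e: float, syn: SynapseArray) -> np.ndarray:
    """Three-factor product ``PI_i = e * PSP_i * zeta(|w_i|)``."""
    return e * syn.psp * zeta(np.abs(syn.w), syn.params.phi_zeta, syn.params.tau_zeta)


def step_weight_update(syn: SynapseArray, pi: np.ndarray, dt: float) -> SynapseArray:
    """Integrate eligibility and weights with the Dale clamp.

    The eligibility low-pass filters PI; the candidate weight is then
    checked against the synapse's sign and the eligibility zeroed (weight
    left unchanged this step) wherever applying it would flip the sign."""
    p = syn.params
    syn.dw += dt * (pi - syn.dw) / p.tau_delta
    candidate = syn.w + p.eta * syn.dw * dt
    flip = candidate * syn.sign <= 0.0
    syn.dw[flip] = 0.0
    syn.w = np.where(flip, syn.w, candidate)
    return syn
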