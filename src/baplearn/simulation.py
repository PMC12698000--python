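"""Single-neuron trial orchestration.

Glues the input generator, the compiled membrane/plasticity loop and the
metrics together: a :class:`TrialConfig` fully specifies one seeded trial,
:func:`run_trial` executes it and returns a :class:`TrialResult` carrying
output spikes, weight snapshots, the selectivity-index series per pattern,
the tuning verdict and the homeostatic-scale trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from . import metrics, rng, spikegen
from .neuron import (
    CouplingParams,
    DendriteParams,
    HomeostasisParams,
    HVAParams,
    NMDAParams,
    SomaParams,
    VARIANTS,
)
from .plasticity import PlasticityParams

__all__ = ["NeuronConfig", "TrialConfig", "TrialResult", "pack_params",
           "run_trial", "frozen_response", "default_neuron_config"]


@dataclass(frozen=True)
class NeuronConfig:
    """Complete parameterization of one model neuron."""

    variant: str = "spike_trace"  # spike_trace | calcium | calcium_nmdar
    soma: SomaParams = field(default_factory=SomaParams)
    dendrite: DendriteParams = field(default_factory=DendriteParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    hva: HVAParams = field(default_factory=HVAParams)
    nmda: NMDAParams = field(default_factory=NMDAParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; known: {sorted(VARIANTS)}")


def default_neuron_config(variant: str = "spike_trace", m_csd: float | None = None,
                          **overrides) -> NeuronConfig:
    """Calibrated per-variant neuron configuration.

    The spike-trace variant keeps the dataclass defaults. The calcium
    variants use a slower refractory repolarization (so the somatic peak can
    drive the dendrite during the bAP window), a smaller resting
    soma->dendrite coupling, a subcritical HVA conductance, and a default
    bAP pulse of 60 nS (set ``m_csd`` explicitly for sweeps)."""
    if variant == "spike_trace":
        coupling = CouplingParams(m_csd=0.0 if m_csd is None else m_csd)
        return NeuronConfig(variant=variant, coupling=coupling, **overrides)
    soma = overrides.pop("soma", SomaParams(g_lsr=150.0, tau_ref=3.0))
    hva = overrides.pop("hva", HVAParams(g_ca=5.0))
    coupling = overrides.pop("coupling", CouplingParams(
        g_csdr=8.0, m_csd=60.0 if m_csd is None else m_csd))
    plasticity = overrides.pop("plasticity", PlasticityParams(phi=0.2))
    return NeuronConfig(variant=variant, soma=soma, hva=hva, coupling=coupling,
                        plasticity=plasticity, **overrides)


@dataclass(frozen=True)
class TrialConfig:
    """One seeded tuning trial: input scheme, neuron, and recording strides."""

    input: spikegen.InputStreamSpec = field(default_factory=spikegen.InputStreamSpec)
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    weights: spikegen.WeightInitSpec = field(default_factory=spikegen.WeightInitSpec)
    seed: int = 0
    plast_stride: int = 5      # membrane steps per plasticity update (0.5 ms at dt=0.1)
    zeta_stride: int = 2       # plasticity steps per zeta refresh
    snapshot_ms: float = 100.0  # weight snapshot grid for the selectivity index
    record_ms: float = 0.0     # trace recording stride (0 = off)
    si_threshold_mode: str = "sem"  # literal | sem | tanh (Eq-7 escape hatch)
    si_pool: str = "exc"            # exc | all: weight pooling for the index


@dataclass
class TrialResult:
    config: TrialConfig
    spike_times: np.ndarray           # ms
    schedule: spikegen.PresentationSchedule
    communities: dict[str, np.ndarray]
    weights0: np.ndarray
    weights: np.ndarray               # final
    weight_snapshots: np.ndarray      # (n_snap, n_syn) float32
    snapshot_times: np.ndarray        # ms
    selectivity: dict[str, np.ndarray]
    tuned_patterns: tuple[str, ...]
    tuning_time: float | None         # s
    presentations_to_convergence: int | None
    snr: float
    kappa_history: np.ndarray
    kappa_min: float
    nmda_mask: np.ndarray
    recordings: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def tuned(self) -> bool:
        return len(self.tuned_patterns) == 1

    @property
    def classification(self) -> str:
        """'pattern<k>', 'others' (multi-tuned) or 'none'."""
        if len(self.tuned_patterns) == 0:
            return "none"
        if len(self.tuned_patterns) > 1:
            return "others"
        return self.tuned_patterns[0]


def pack_params(cfg: NeuronConfig, dt: float) -> np.ndarray:
    """Flatten the neuron dataclasses into the kernel parameter vector."""
    p = np.zeros(K.N_PARAMS)
    s, d, c = cfg.soma, cfg.dendrite, cfg.coupling
    p[K.DT] = dt
    p[K.C_S] = s.c_s; p[K.G_LS] = s.g_ls; p[K.G_LSR] = s.g_lsr
    p[K.V_LS] = s.v_ls; p[K.V_TH] = s.v_th; p[K.V_RE] = s.v_re
    p[K.V_PEAK] = s.v_peak; p[K.TREF] = s.tau_ref
    p[K.C_D] = d.c_d; p[K.G_LD] = d.g_ld; p[K.V_LD] = d.v_ld
    p[K.V_ER] = d.v_er; p[K.V_IR] = d.v_ir
    p[K.TAU_ER] = d.exc.tau_rise; p[K.TAU_ED] = d.exc.tau_decay; p[K.GBAR_E] = d.exc.gbar
    p[K.TAU_IR] = d.inh.tau_rise; p[K.TAU_ID] = d.inh.tau_decay; p[K.GBAR_I] = d.inh.gbar
    p[K.G_CDS] = c.g_cds; p[K.G_CSDR] = c.g_csdr; p[K.M_CSD] = c.m_csd
    p[K.TAU_CR] = c.tau_rise; p[K.TAU_CD] = c.tau_decay
    p[K.G_CA] = cfg.hva.g_ca; p[K.V_CA] = cfg.hva.v_ca
    n = cfg.nmda
    p[K.TAU_NR] = n.kinetics.tau_rise; p[K.TAU_ND] = n.kinetics.tau_decay
    p[K.GBAR_N] = n.kinetics.gbar; p[K.V_N] = n.v_rev
    p[K.F_CA] = n.f_ca; p[K.MG] = n.mg
    pl = cfg.plasticity
    p[K.TAU_Y] = pl.tau_y; p[K.TAU_YBAR] = pl.tau_ybar
    p[K.TAU_C] = pl.tau_c; p[K.TAU_CBAR] = pl.tau_cbar
    p[K.C0] = pl.c0; p[K.PHI] = pl.phi
    p[K.TAU_P] = pl.tau_p; p[K.PHI_Z] = pl.phi_zeta; p[K.TAU_Z] = pl.tau_zeta
    p[K.ETA] = pl.eta; p[K.TAU_DELTA] = pl.tau_delta
    p[K.T_KAPPA] = cfg.homeostasis.t_kappa
    p[K.RHO] = d.rho
    return p


def _events_from_stream(stream: spikegen.InputStream, dt: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    steps = np.round(stream.times / dt).astype(np.int64)
    order = np.lexsort((stream.units, steps))
    return steps[order], stream.units[order].astype(np.int64)


def _noise_array(rho: float, n_steps: int, dt: float,
                 noise_rng: np.random.Generator) -> np.ndarray:
    if rho <= 0.0:
        return np.empty(0)
    return rho / np.sqrt(dt) * noise_rng.standard_normal(n_steps)


def run_trial(config: TrialConfig,
              stream: spikegen.InputStream | None = None,
              weights0: np.ndarray | None = None) -> TrialResult:
    """Run one closed-loop tuning trial.

    Input generation, weight initialization, NMDA-mask sampling and membrane
    noise each draw from their own named sub-stream of ``config.seed``, so
    e.g. switching the neuron variant does not change the input realization.
    """
    spec = config.input
    dt = spec.dt
    if stream is None:
        stream, _ = spikegen.build_input_stream(
            spec,
            rng=rng.stream(config.seed, "input"),
            failure_rng=rng.stream(config.seed, "failure"),
        )
    schedule = stream.schedule
    n_steps = int(round(spec.trial_duration / dt))
    ev_step, ev_unit = _events_from_stream(stream, dt)

    if weights0 is None:
        weights0 = spikegen.sample_initial_weights(
            config.weights, spec.n_exc, spec.n_inh, rng.stream(config.seed, "weights"))
    sign = np.where(np.arange(spec.n_units) < spec.n_exc, 1.0, -1.0)
    w_rng = rng.stream(config.seed, "weights")
    nmda_mask = np.zeros(spec.n_units, dtype=bool)
    if config.neuron.variant == "calcium_nmdar":
        nmda_mask[:spec.n_exc] = w_rng.random(spec.n_exc) < config.neuron.nmda.fraction

    p = pack_params(config.neuron, dt)
    noise = _noise_array(config.neuron.dendrite.rho, n_steps, dt,
                         rng.stream(config.seed, "noise"))
    snap_stride = max(1, int(round(config.snapshot_ms / dt)))
    rec_stride = int(round(config.record_ms / dt)) if config.record_ms > 0 else 0

    (status, spike_steps, w_final, w_snaps, kappa_hist, _kappa, kappa_min,
     rec_vs, rec_vd, rec_e, rec_gcsd, rec_tr, rec_trbar) = K.run_single_neuron(
        p, VARIANTS[config.neuron.variant], n_steps, ev_step, ev_unit,
        weights0.copy(), sign, nmda_mask, np.empty(0, dtype=np.int64), noise,
        config.plast_stride, config.zeta_stride, snap_stride, rec_stride,
        False, 1.0,
    )
    if status == K.DIVERGED:
        raise FloatingPointError(
            f"membrane potential diverged (seed={config.seed}, "
            f"variant={config.neuron.variant})")

    spike_times = spike_steps.astype(np.float64) * dt
    snapshot_times = np.arange(w_snaps.shape[0]) * snap_stride * dt

    selectivity = {
        pid: metrics.selectivity_index(w_snaps, members, n_exc=spec.n_exc,
                                       pool=config.si_pool)
        for pid, members in stream.communities.items()
    }
    tuning_s, tuned = metrics.tuning_time(
        selectivity, w_snaps, snapshot_times, stream.communities,
        mode=config.si_threshold_mode, n_exc=spec.n_exc, pool=config.si_pool)
    pres = None
    snr_val = np.nan
    if len(tuned) == 1:
        pres = metrics.presentations_before(schedule, tuned[0], tuning_s * 1e3)
        snr_val = metrics.snr(spike_times, schedule, tuned[0])
    elif len(tuned) > 1:
        snr_val = metrics.snr(spike_times, schedule, tuned[0])

    recordings = {}
    if rec_stride > 0:
        recordings = {
            "t": np.arange(len(rec_vs)) * rec_stride * dt,
            "v_s": rec_vs, "v_d": rec_vd, "e": rec_e, "g_csd": rec_gcsd,
            "trace": rec_tr, "trace_bar": rec_trbar,
        }

    return TrialResult(
        config=config, spike_times=spike_times, schedule=schedule,
        communities=stream.communities, weights0=weights0, weights=w_final,
        weight_snapshots=w_snaps, snapshot_times=snapshot_times,
        selectivity=selectivity, tuned_patterns=tuple(tuned),
        tuning_time=tuning_s, presentations_to_convergence=pres,
        snr=snr_val, kappa_history=kappa_hist, kappa_min=kappa_min,
        nmda_mask=nmda_mask, recordings=recordings,
    )


def frozen_response(config: TrialConfig, weights: np.ndarray,
                    stream: spikegen.InputStream, kappa: float = 1.0,
                    nmda_mask: np.ndarray | None = None,
                    noise_rng: np.random.Generator | None = None) -> np.ndarray:
    """Somatic spike times (ms) of a neuron with frozen weights driven by
    ``stream`` — the read-out used by the jitter-robustness protocol."""
    spec = config.input
    dt = spec.dt
    n_steps = int(round(stream.duration / dt))
    ev_step, ev_unit = _events_from_stream(stream, dt)
    sign = np.where(np.arange(spec.n_units) < spec.n_exc, 1.0, -1.0)
    if nmda_mask is None:
        nmda_mask = np.zeros(spec.n_units, dtype=bool)
    p = pack_params(config.neuron, dt)
    if noise_rng is None:
        noise = np.empty(0)
    else:
        noise = _noise_array(config.neuron.dendrite.rho, n_steps, dt, noise_rng)
    out = K.run_single_neuron(
        p, VARIANTS[config.neuron.variant], n_steps, ev_step, ev_unit,
        weights.copy(), sign, nmda_mask, np.empty(0, dtype=np.int64), noise,
        config.plast_stride, config.zeta_stride, 0, 0, True, kappa,
    )
    if out[0] != K.OK:
        raise FloatingPointError("membrane potential diverged in frozen response")
    return out[1].astype(np.float64) * dt
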