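"""Experiment orchestration.

End-to-end protocols around the single-neuron trial loop: seeded tuning
batches, bAP-strength SNR sweeps across model variants, frozen-weight jitter
robustness, initial-weight bias analysis, burst-fraction convergence, and
spike-pairing (STDP) protocols on the calcium model.

Every protocol takes a base seed and derives per-trial seeds from it, so a
whole experiment is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import metrics, rng, spikegen
from .simulation import (NeuronConfig, TrialConfig, TrialResult,
                         default_neuron_config, frozen_response, run_trial)
from . import _kernels as K
from .simulation import pack_params
from .neuron import VARIANTS
from .plasticity import PlasticityParams

__all__ = [
    "STDPProtocolSpec", "STDPCurve", "run_tuning_trial", "run_tuning_batch",
    "run_bap_sweep", "run_jitter_robustness", "run_initial_bias_study",
    "run_burst_convergence_study", "run_stdp_protocol",
]


def run_tuning_trial(config: TrialConfig) -> TrialResult:
    """Run one closed-loop tuning trial (input -> membrane -> plasticity,
    with periodic homeostatic rescaling); alias of :func:`simulation.run_trial`."""
    return run_trial(config)


def make_trial_config(seed: int, variant: str = "spike_trace",
                      m_csd: float | None = None,
                      input_spec: spikegen.InputStreamSpec | None = None,
                      **trial_kwargs) -> TrialConfig:
    """Standard trial configuration with variant-calibrated neuron defaults."""
    return TrialConfig(
        seed=seed,
        input=input_spec or spikegen.InputStreamSpec(),
        neuron=default_neuron_config(variant, m_csd=m_csd),
        **trial_kwargs,
    )


def run_tuning_batch(n_trials: int, seed: int = 0, variant: str = "spike_trace",
                     m_csd: float | None = None,
                     input_spec: spikegen.InputStreamSpec | None = None,
                     **trial_kwargs) -> list[TrialResult]:
    """Independent seeded tuning trials (trial seeds derived from ``seed``)."""
    out = []
    for k in range(n_trials):
        cfg = make_trial_config(seed * 100_003 + k, variant, m_csd,
                                input_spec, **trial_kwargs)
        out.append(run_trial(cfg))
    return out


# ---------------------------------------------------------------------------
# bAP-strength sweep
# ---------------------------------------------------------------------------

def run_bap_sweep(m_csd_values, n_trials: int, seed: int = 0,
                  variant: str = "calcium", discard_failures: bool = True,
                  input_spec: spikegen.InputStreamSpec | None = None) -> dict:
    """SNR distributions per bAP pulse amplitude.

    ``discard_failures`` drops trials that tuned to no pattern; with it off,
    untuned trials contribute the SNR of their most responsive pattern, so
    chance-level performance is represented rather than censored.
    Returns {m_csd: {"snr": [...], "n_failures": int}}."""
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    out = {}
    for m in m_csd_values:
        snrs, failures = [], 0
        for k in range(n_trials):
            cfg = make_trial_config(seed * 100_003 + k, variant, m_csd=float(m),
                                    input_spec=input_spec)
            res = run_trial(cfg)
            if res.tuned_patterns:
                val = res.snr
            else:
                failures += 1
                if discard_failures:
                    continue
                val = _best_pattern_snr(res)
            if np.isfinite(val):
                snrs.append(float(val))
        out[float(m)] = {"snr": snrs, "n_failures": failures}
    return out


def _best_pattern_snr(res: TrialResult) -> float:
    vals = [metrics.snr(res.spike_times, res.schedule, pid)
            for pid in res.communities]
    vals = [v for v in vals if np.isfinite(v)]
    return max(vals) if vals else np.nan


# ---------------------------------------------------------------------------
# jitter robustness
# ---------------------------------------------------------------------------

def _test_segment(template: spikegen.PatternTemplate,
                  spec: spikegen.InputStreamSpec,
                  members: np.ndarray, seg_rng: np.random.Generator,
                  mean_jitter: float, jit_rng: np.random.Generator,
                  gap: float = 200.0, tail: float = 100.0,
                  replay: bool = True) -> tuple[spikegen.InputStream, float]:
    """One [noise | pattern | noise] probe segment.

    Returns the stream and the pattern onset time. With ``replay`` off the
    pattern window carries fresh noise instead (the chance-level probe)."""
    duration = gap + spec.t_pat + tail
    all_units = np.arange(spec.n_units)
    chunks_u, chunks_t = [], []
    u, t = spikegen._population_poisson(all_units, gap, spec.rate, spec.dt, seg_rng)
    chunks_u.append(u); chunks_t.append(t)
    background = np.setdiff1d(all_units, members)
    u, t = spikegen._population_poisson(background if replay else all_units,
                                        spec.t_pat, spec.rate, spec.dt, seg_rng)
    chunks_u.append(u); chunks_t.append(t + gap)
    if replay:
        for unit, ts in template.unit_spikes.items():
            ts = spikegen.apply_jitter(ts, mean_jitter, jit_rng, 0.0, spec.t_pat)
            if len(ts):
                chunks_u.append(np.full(len(ts), unit, dtype=np.int64))
                chunks_t.append(ts + gap)
    else:
        u, t = spikegen._population_poisson(members, spec.t_pat, spec.rate, spec.dt, seg_rng)
        chunks_u.append(u); chunks_t.append(t + gap)
    u, t = spikegen._population_poisson(all_units, tail, spec.rate, spec.dt, seg_rng)
    chunks_u.append(u); chunks_t.append(t + gap + spec.t_pat)
    units = np.concatenate(chunks_u); times = np.concatenate(chunks_t)
    order = np.lexsort((units, times))
    sched = spikegen.PresentationSchedule(
        np.array([0.0, gap, gap + spec.t_pat]),
        np.array([gap, gap + spec.t_pat, duration]),
        np.array([spikegen.NOISE_LABEL, template.pattern_id, spikegen.NOISE_LABEL],
                 dtype=object))
    stream = spikegen.InputStream(units[order], times[order], spec.n_units,
                                  duration, sched, {template.pattern_id: members})
    return stream, gap


def run_jitter_robustness(result: TrialResult, mean_jitters,
                          n_repeats: int = 10, seed: int = 0,
                          bin_width: float = 10.0, window_ms: float = 50.0) -> dict:
    """Frozen-weight robustness of a tuned response to input-timing jitter.

    The tuned trial's final weights are frozen (plasticity off, homeostatic
    scale held at its end-of-trial value) and the learned pattern's template
    is presented repeatedly: clean once (the ground-truth response) and then
    with per-spike uniform jitter of the requested mean absolute size. The
    read-out is the Pearson correlation of binned output spike counts over
    the pattern window (+``window_ms``), concatenated over repeats. The
    chance level is estimated identically with fresh noise in place of the
    template."""
    if not result.tuned_patterns:
        raise ValueError("jitter robustness requires a tuned trial")
    pid = result.tuned_patterns[0]
    spec = result.config.input
    template = _trial_template(result, pid)
    members = result.communities[pid]
    kappa_end = float(result.kappa_history[-1])

    def response(stream, onset):
        st = frozen_response(result.config, result.weights, stream,
                             kappa=kappa_end, nmda_mask=result.nmda_mask)
        return metrics.bin_spikes(st, onset, onset + spec.t_pat + window_ms, bin_width)

    def probe(jit_rng=None, mean_jitter=0.0, replay=True):
        """Concatenated response to n_repeats probe segments whose noise
        background is fixed per segment index — conditions differ only in
        the pattern window."""
        chunks = []
        for rep in range(n_repeats):
            seg_rng = rng.substream(seed, "protocol", rep)
            jr = jit_rng if jit_rng is not None else seg_rng
            chunks.append(response(*_test_segment(
                template, spec, members, seg_rng, float(mean_jitter), jr,
                replay=replay)))
        return np.concatenate(chunks)

    gt = probe()
    out = {"ground_truth_counts": gt, "pattern": pid, "correlations": {},
           "chance": []}
    for mj in mean_jitters:
        cors = []
        for k in range(n_repeats):
            if mj == 0.0:
                resp = probe()  # bit-identical input by construction
            else:
                resp = probe(rng.substream(seed, "jitter", k), mj)
            cors.append(_safe_corr(gt, resp))
        out["correlations"][float(mj)] = cors
    for k in range(n_repeats):
        resp = probe(rng.substream(seed, "jitter", 10_000 + k), replay=False)
        out["chance"].append(_safe_corr(gt, resp))
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a.astype(float), b.astype(float))[0, 1])


def _trial_template(result: TrialResult, pid: str) -> spikegen.PatternTemplate:
    """Recover the frozen template of a trial (regenerated from its seed)."""
    stream, _ = spikegen.build_input_stream(
        result.config.input,
        rng=rng.stream(result.config.seed, "input"),
        failure_rng=rng.stream(result.config.seed, "failure"))
    return stream.templates[pid]


# ---------------------------------------------------------------------------
# initial-bias sensitivity
# ---------------------------------------------------------------------------

def run_initial_bias_study(n_sims: int = 100, seed: int = 0,
                           distributions=("gaussian", "uniform", "lognormal"),
                           variant: str = "spike_trace",
                           input_spec: spikegen.InputStreamSpec | None = None) -> dict:
    """Does initial synaptic bias predict which pattern gets detected?

    For each weight law, ``n_sims`` seeded trials are run; each pattern
    contributes the median initial weight over its excitatory community
    members, split by whether that pattern was eventually detected. A
    two-sided Mann-Whitney U test compares the two groups per distribution.
    Simulations with no detected or no undetected pattern cannot contribute
    a within-trial contrast but their patterns still enter the pooled test.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20 for a meaningful rank test")
    input_spec = input_spec or spikegen.InputStreamSpec(burst_fraction=0.0)
    out = {}
    for dist in distributions:
        detected, non_detected = [], []
        n_degenerate = 0
        for k in range(n_sims):
            cfg = replace(
                make_trial_config(seed * 100_003 + k, variant, input_spec=input_spec),
                weights=spikegen.WeightInitSpec(distribution=dist))
            res = run_trial(cfg)
            tuned = set(res.tuned_patterns)
            medians = {
                pid: float(np.median(res.weights0[m[m < input_spec.n_exc]]))
                for pid, m in res.communities.items()
            }
            if not tuned or tuned == set(medians):
                n_degenerate += 1
            for pid, med in medians.items():
                (detected if pid in tuned else non_detected).append(med)
        if detected and non_detected:
            u, p = stats.mannwhitneyu(detected, non_detected, alternative="two-sided")
        else:
            u, p = np.nan, np.nan
        out[dist] = {
            "detected": detected, "non_detected": non_detected,
            "U": float(u), "p": float(p), "n_degenerate": n_degenerate,
        }
    return out


# ---------------------------------------------------------------------------
# burst-fraction convergence
# ---------------------------------------------------------------------------

def run_burst_convergence_study(burst_fractions, n_trials: int, seed: int = 0,
                                variant: str = "spike_trace") -> dict:
    """Presentations-to-convergence vs the fraction of bursting input units.

    Untuned trials are excluded from the presentation counts but reported."""
    out = {}
    for bf in burst_fractions:
        spec = spikegen.InputStreamSpec(burst_fraction=float(bf))
        pres, n_untuned = [], 0
        for k in range(n_trials):
            cfg = make_trial_config(seed * 100_003 + k, variant, input_spec=spec)
            res = run_trial(cfg)
            if res.tuned and res.presentations_to_convergence is not None:
                pres.append(res.presentations_to_convergence)
            else:
                n_untuned += 1
        out[float(bf)] = {"presentations": pres, "n_untuned": n_untuned}
    return out


# ---------------------------------------------------------------------------
# STDP pairing protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STDPProtocolSpec:
    """Pre/post pairing protocol on the calcium model.

    ``dt_grid`` holds signed pre->post lags in ms; positive lags are causal
    (presynaptic spike precedes the postsynaptic burst). Postsynaptic spikes
    are evoked directly (forced threshold crossings), singlet or doublet."""

    pairing_hz: float = 5.0
    n_pairings: int = 85
    post_mode: str = "doublet"        # singlet | doublet
    doublet_isi: float = 10.0         # ms between the two doublet spikes
    dt_grid: tuple = tuple(np.arange(-100.0, 101.0, 10.0))
    rho: float = 40.0                 # membrane noise during the protocol
    w0: float = 1.0                   # initial weight of the probed synapse
    variant: str = "calcium"

    def __post_init__(self):
        if self.post_mode not in ("singlet", "doublet"):
            raise ValueError("post_mode must be 'singlet' or 'doublet'")
        period = 1000.0 / self.pairing_hz
        if max(abs(float(d)) for d in self.dt_grid) >= period:
            raise ValueError("|dt| must be smaller than the pairing period")


@dataclass
class STDPCurve:
    dt_ms: np.ndarray
    change_pct: np.ndarray           # relative weight change per lag, %
    smooth: np.ndarray               # polynomial interpolation on dt_ms
    spec: STDPProtocolSpec


def _stdp_single_lag(spec: STDPProtocolSpec, dt_lag: float, seed: int,
                     neuron: NeuronConfig) -> float:
    sim_dt = 0.1
    period = 1000.0 / spec.pairing_hz
    settle = 500.0
    duration = settle + spec.n_pairings * period + 500.0
    n_steps = int(round(duration / sim_dt))

    pre_times, post_times = [], []
    for k in range(spec.n_pairings):
        t0 = settle + k * period
        pre = t0 + max(0.0, -dt_lag)
        post = t0 + max(0.0, dt_lag)
        pre_times.append(pre)
        post_times.append(post)
        if spec.post_mode == "doublet":
            post_times.append(post + spec.doublet_isi)
    ev_step = np.round(np.array(pre_times) / sim_dt).astype(np.int64)
    order = np.argsort(ev_step)
    ev_step = ev_step[order]
    ev_unit = np.zeros(len(ev_step), dtype=np.int64)
    forced = np.unique(np.round(np.array(post_times) / sim_dt).astype(np.int64))

    p = pack_params(neuron, sim_dt)
    noise_rng = rng.substream(seed, "noise", int(round(dt_lag * 10)) & 0x7FFFFFFF)
    noise = (spec.rho / np.sqrt(sim_dt) * noise_rng.standard_normal(n_steps)
             if spec.rho > 0 else np.empty(0))
    out = K.run_single_neuron(
        p, VARIANTS[neuron.variant], n_steps, ev_step, ev_unit,
        np.array([spec.w0]), np.array([1.0]), np.zeros(1, dtype=bool),
        forced, noise, 5, 1, 0, 0, False, 1.0)
    if out[0] != K.OK:
        raise FloatingPointError(f"STDP simulation diverged at dt={dt_lag}")
    w_end = out[2][0]
    return 100.0 * (w_end - spec.w0) / spec.w0


def run_stdp_protocol(spec: STDPProtocolSpec, seed: int = 0,
                      neuron: NeuronConfig | None = None) -> STDPCurve:
    """Relative weight change (%) versus pre->post lag.

    A single plastic excitatory afferent synapses onto an otherwise
    unstimulated calcium-model neuron; postsynaptic spikes are forced at the
    scheduled times. Membrane noise ``rho`` provides the basal fluctuations
    of the calcium excitability signal."""
    if neuron is None:
        neuron = default_neuron_config(spec.variant)
        neuron = replace(neuron,
                         dendrite=replace(neuron.dendrite, rho=spec.rho))
    dts = np.asarray(spec.dt_grid, dtype=np.float64)
    changes = np.array([
        _stdp_single_lag(spec, float(d), seed, neuron) for d in dts])
    deg = min(6, len(dts) - 1)
    smooth = np.polyval(np.polyfit(dts, changes, deg), dts) if deg >= 1 else changes
    return STDPCurve(dts, changes, smooth, spec)
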