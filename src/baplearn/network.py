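"""Recurrent network with pre-configured cell assemblies.

A population of two-compartment spike-trace neurons (400 excitatory + 100
inhibitory by default) receives the same all-to-all afferent pattern stream
as the single-neuron experiments. Excitatory units are partially organized
into disjoint assemblies (sizes ~ Gaussian(18, 3)) whose internal synapses
are either strong (Gaussian mean 3.0) or weak (positive half-Gaussian
around 0). Recurrent connectivity between cell classes is sparse with
lognormal weights; excitatory-to-inhibitory coupling is relatively strong
so inhibition is recruited reliably and runaway excitation is prevented.
All afferent and recurrent synapses are plastic under the same
self-supervised rule, with per-unit homeostatic rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import metrics, rng, spikegen
from .simulation import NeuronConfig, TrialConfig, pack_params
from .plasticity import PlasticityParams

__all__ = [
    "NetworkSpec", "Network", "NetworkResult", "build_network",
    "run_network_trial", "tuned_assembly_analysis", "pairwise_correlation_matrix",
    "NetworkRunawayError",
]


class NetworkRunawayError(RuntimeError):
    """Population-wide runaway excitation exceeded the configured rate cap."""


@dataclass(frozen=True)
class NetworkSpec:
    n_exc: int = 400
    n_inh: int = 100
    n_assemblies: int = 20
    assembly_mu: float = 18.0
    assembly_sigma: float = 3.0
    #: connection probabilities per (pre class -> post class)
    p_ee: float = 0.10
    p_ei: float = 0.50   # E -> I, relatively dense/strong to recruit inhibition
    p_ie: float = 0.50
    p_ii: float = 0.50
    #: lognormal recurrent weight law (underlying normal mu/sigma) and
    #: per-class-pair multipliers
    lognormal_mu: float = -0.7
    lognormal_sigma: float = 0.8
    scale_ee: float = 1.0
    scale_ei: float = 2.5
    scale_ie: float = 2.0
    scale_ii: float = 1.5
    #: within-assembly E->E law: Gaussian(mu, sigma), positive-truncated
    assembly_w_mu: float = 3.0      # 3.0 = strong condition, 0.0 = weak
    assembly_w_sigma: float = 1.0
    #: afferent weights: half-Gaussian magnitudes, all-to-all, signed by class
    afferent_sigma: float = 1.0
    afferent_scale: float = 0.55
    #: inhibitory units are electrotonically more compact -> higher rates
    inh_capacitance_factor: float = 0.6
    rate_cap_hz: float = 100.0      # population-mean cap over 500 ms windows

    def __post_init__(self):
        for name in ("p_ee", "p_ei", "p_ie", "p_ii"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_assemblies * self.assembly_mu > self.n_exc * 1.2:
            raise ValueError("assemblies do not fit in the excitatory population")


@dataclass
class Network:
    spec: NetworkSpec
    assemblies: list[np.ndarray]         # index arrays into the E population
    w_aff: np.ndarray                    # (n_units, n_aff), signed
    w_rec: np.ndarray                    # (n_units, n_units), signed, 0 = absent
    mask_rec: np.ndarray                 # bool, existing recurrent synapses
    is_exc: np.ndarray                   # bool per network unit

    @property
    def n_units(self) -> int:
        return self.w_rec.shape[0]


@dataclass
class NetworkResult:
    network: Network
    spike_units: np.ndarray
    spike_times: np.ndarray              # ms
    schedule: spikegen.PresentationSchedule
    communities: dict[str, np.ndarray]
    duration: float
    w_aff0: np.ndarray
    w_rec0: np.ndarray
    w_aff: np.ndarray
    w_rec: np.ndarray
    kappa: np.ndarray
    kappa_min: float
    #: per assembly: spike count within each pattern epoch (any pattern)
    assembly_counts: np.ndarray          # (n_assemblies, n_presentations)
    presentation_labels: np.ndarray

    def unit_spikes(self, unit: int) -> np.ndarray:
        return self.spike_times[self.spike_units == unit]


def _truncated_gaussian(mu, sigma, size, rng_):
    """Positive-truncated Gaussian via resampling."""
    out = rng_.normal(mu, sigma, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng_.normal(mu, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def build_network(spec: NetworkSpec, build_rng: np.random.Generator,
                  n_aff_exc: int = 1000, n_aff_inh: int = 1000) -> Network:
    """Wire assemblies, recurrent connectivity and afferent weights."""
    n = spec.n_exc + spec.n_inh
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:spec.n_exc] = True

    # disjoint assemblies over the E population; sizes resampled until >= 2
    sizes = []
    for _ in range(spec.n_assemblies):
        s = 0
        while s < 2:
            s = int(round(build_rng.normal(spec.assembly_mu, spec.assembly_sigma)))
        sizes.append(s)
    if sum(sizes) > spec.n_exc:
        raise ValueError("assembly sizes exceed the excitatory population")
    perm = build_rng.permutation(spec.n_exc)
    assemblies, pos = [], 0
    for s in sizes:
        assemblies.append(np.sort(perm[pos:pos + s]))
        pos += s

    # sparse recurrent connectivity, lognormal weights, Dale signs by pre class
    w_rec = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    probs = {(True, True): spec.p_ee, (True, False): spec.p_ei,
             (False, True): spec.p_ie, (False, False): spec.p_ii}
    scales = {(True, True): spec.scale_ee, (True, False): spec.scale_ei,
              (False, True): spec.scale_ie, (False, False): spec.scale_ii}
    for pre_exc in (True, False):
        for post_exc in (True, False):
            pre_idx = np.where(is_exc == pre_exc)[0]
            post_idx = np.where(is_exc == post_exc)[0]
            block = build_rng.random((len(post_idx), len(pre_idx))) < probs[(pre_exc, post_exc)]
            wts = build_rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma,
                                      size=block.shape) * scales[(pre_exc, post_exc)]
            if not pre_exc:
                wts = -wts
            sub = np.zeros(block.shape)
            sub[block] = wts[block]
            w_rec[np.ix_(post_idx, pre_idx)] = sub
            mask[np.ix_(post_idx, pre_idx)] = block
    np.fill_diagonal(w_rec, 0.0)
    np.fill_diagonal(mask, False)

    # within-assembly E->E synapses: all-to-all, positive-truncated Gaussian
    for members in assemblies:
        blk = np.ix_(members, members)
        w = _truncated_gaussian(spec.assembly_w_mu, spec.assembly_w_sigma,
                                (len(members), len(members)), build_rng)
        w_rec[blk] = w
        mask[blk] = True
        w_rec[members, members] = 0.0
        mask[members, members] = False

    # all-to-all afferent weights: half-Gaussian magnitudes, signed by class
    n_aff = n_aff_exc + n_aff_inh
    mags = np.abs(build_rng.normal(0.0, spec.afferent_sigma, size=(n, n_aff)))
    sign_aff = np.where(np.arange(n_aff) < n_aff_exc, 1.0, -1.0)
    w_aff = spec.afferent_scale * mags * sign_aff[None, :]

    return Network(spec, assemblies, w_aff, w_rec, mask, is_exc)


def run_network_trial(network: Network, config: TrialConfig,
                      stream: spikegen.InputStream | None = None,
                      plast_stride: int = 10, zeta_stride: int = 10
                      ) -> NetworkResult:
    """Simulate the network on one afferent stream with all synapses plastic.

    ``config`` supplies the afferent scheme, seed and the (spike-trace)
    neuron parameters shared by all units; per-class capacitances follow the
    network spec. Aborts with :class:`NetworkRunawayError` if the population
    mean rate exceeds the configured cap in any 500 ms window."""
    spec = config.input
    dt = spec.dt
    if stream is None:
        stream, _ = spikegen.build_input_stream(
            spec, rng=rng.stream(config.seed, "input"),
            failure_rng=rng.stream(config.seed, "failure"))
    n_steps = int(round(stream.duration / dt))
    steps = np.round(stream.times / dt).astype(np.int64)
    order = np.lexsort((stream.units, steps))
    ev_step, ev_unit = steps[order], stream.units[order].astype(np.int64)

    p = pack_params(config.neuron, dt)
    nspec = network.spec
    c_s = np.full(network.n_units, config.neuron.soma.c_s)
    c_d = np.full(network.n_units, config.neuron.dendrite.c_d)
    c_s[~network.is_exc] *= nspec.inh_capacitance_factor
    c_d[~network.is_exc] *= nspec.inh_capacitance_factor
    sign_aff = np.where(np.arange(spec.n_units) < spec.n_exc, 1.0, -1.0)

    w_aff0 = network.w_aff.copy()
    w_rec0 = network.w_rec.copy()
    (status, out_unit, out_step, w_aff, w_rec, kappa, kappa_min) = K.run_network(
        p, n_steps, c_s, c_d, network.is_exc, ev_step, ev_unit, sign_aff,
        network.w_aff.copy(), network.w_rec.copy(), network.mask_rec,
        plast_stride, zeta_stride, nspec.rate_cap_hz)
    if status == K.RUNAWAY:
        raise NetworkRunawayError(
            f"population rate exceeded {nspec.rate_cap_hz} Hz "
            f"(seed={config.seed}); consider stronger inhibition")

    spike_times = out_step.astype(np.float64) * dt
    schedule = stream.schedule
    pat = schedule.label != spikegen.NOISE_LABEL
    starts, ends = schedule.start[pat], schedule.end[pat]
    labels = schedule.label[pat]
    counts = np.zeros((len(network.assemblies), len(starts)), dtype=np.int64)
    for j, (s, e) in enumerate(zip(starts, ends)):
        sel = (spike_times >= s) & (spike_times < e)
        units_in = out_unit[sel]
        for a, members in enumerate(network.assemblies):
            counts[a, j] = int(np.isin(units_in, members).sum())

    return NetworkResult(
        network=network, spike_units=out_unit, spike_times=spike_times,
        schedule=schedule, communities=stream.communities,
        duration=stream.duration, w_aff0=w_aff0, w_rec0=w_rec0,
        w_aff=w_aff, w_rec=w_rec, kappa=kappa, kappa_min=kappa_min,
        assembly_counts=counts, presentation_labels=labels,
    )


def tuned_assembly_analysis(result: NetworkResult, n_top: int = 6) -> dict:
    """Normalized spike counts of the strongest-responding assemblies.

    Picks the ``n_top`` assemblies with the highest total in-pattern spike
    count, keeps those whose size-normalized count at the last presentation
    exceeds 1 (an assembly-sized volley), and returns counts normalized by
    assembly size per presentation."""
    if result.assembly_counts.shape[1] == 0:
        raise ValueError("trial contains no pattern presentation")
    sizes = np.array([len(m) for m in result.network.assemblies], dtype=float)
    norm = result.assembly_counts / sizes[:, None]
    total = result.assembly_counts.sum(axis=1)
    top = np.argsort(total)[::-1][:n_top]
    keep = [a for a in top if norm[a, -1] > 1.0]
    return {
        "assemblies": keep,
        "normalized_counts": norm[keep],
        "all_normalized_counts": norm,
        "top": top,
    }


def pairwise_correlation_matrix(result: NetworkResult, bin_width: float = 25.0
                                ) -> dict:
    """Pearson correlations of binned spike counts for all unit pairs.

    Silent units produce undefined (NaN) rows/columns, mirrored in the
    ``silent`` mask. The summary reports the mean within-assembly and
    between-assembly correlation over defined, distinct pairs."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n = result.network.n_units
    edges = np.arange(0.0, result.duration + bin_width, bin_width)
    binned = np.zeros((n, len(edges) - 1))
    for u in range(n):
        binned[u], _ = np.histogram(result.unit_spikes(u), bins=edges)
    sd = binned.std(axis=1)
    silent = sd == 0
    if silent.any():
        warnings.warn(f"{int(silent.sum())} silent units yield undefined correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(binned)
    corr[silent, :] = np.nan
    corr[:, silent] = np.nan

    in_assembly = np.full(n, -1)
    for a, members in enumerate(result.network.assemblies):
        in_assembly[members] = a
    i, j = np.triu_indices(n, k=1)
    valid = ~np.isnan(corr[i, j])
    same = (in_assembly[i] >= 0) & (in_assembly[i] == in_assembly[j])
    both = (in_assembly[i] >= 0) & (in_assembly[j] >= 0)
    within = corr[i, j][valid & same]
    between = corr[i, j][valid & both & ~same]
    return {
        "matrix": corr,
        "silent": silent,
        "within_mean": float(np.mean(within)) if len(within) else np.nan,
        "between_mean": float(np.mean(between)) if len(between) else np.nan,
        "n_within_pairs": int(len(within)),
        "n_between_pairs": int(len(between)),
    }
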