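"""Afferent input construction.

The stimulus is a continuous stream from a population of homogeneous Poisson
units (nominally 1000 excitatory + 1000 inhibitory at 5 Hz). A few disjoint
"temporal communities" of units own frozen spike templates of length
``T_pat``; these templates are replayed verbatim at random times, separated
by fresh-noise gaps drawn uniformly from ``[T_pat, 3 T_pat]``. Outside its
replay epochs every unit, community member or not, fires fresh Poisson noise
at the same rate, so nothing distinguishes a pattern except the repeated
temporal arrangement of its spikes.

Spikes live on a regular ``dt`` grid: each step fires independently with
probability ``rate * dt`` (the discrete Bernoulli approximation of a Poisson
process, valid for ``rate * dt << 1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatternTemplate",
    "InputStreamSpec",
    "PresentationSchedule",
    "WeightInitSpec",
    "InputStream",
    "generate_poisson_train",
    "build_pattern_template",
    "build_communities",
    "build_input_stream",
    "apply_transmission_failure",
    "apply_jitter",
    "sample_initial_weights",
]

NOISE_LABEL = "noise"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternTemplate:
    """Frozen spike template of one temporal community.

    ``unit_spikes`` maps population unit index -> sorted spike times (ms)
    within ``[0, t_pat)``. The template is identical at every presentation;
    corruption (transmission failure, jitter) is applied downstream.
    """

    pattern_id: str
    t_pat: float
    unit_spikes: dict[int, np.ndarray]
    burst_unit_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        for u, t in self.unit_spikes.items():
            if len(t) and (t.min() < 0 or t.max() >= self.t_pat):
                raise ValueError(f"unit {u}: template spikes outside [0, T_pat)")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"unit {u}: spike times not strictly increasing")

    @property
    def units(self) -> np.ndarray:
        return np.fromiter(self.unit_spikes.keys(), dtype=np.int64)

    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.unit_spikes.values()))


@dataclass(frozen=True)
class InputStreamSpec:
    """Parameters of the afferent stream (rates in Hz, times in ms)."""

    n_exc: int = 1000
    n_inh: int = 1000
    rate: float = 5.0
    t_pat: float = 100.0
    n_patterns: int = 3
    noise_gap_range: tuple[float, float] = (100.0, 300.0)
    p_fail: float = 0.1          # per-spike transmission failure, per presentation
    burst_fraction: float = 0.0  # fraction of community units firing bursts
    burst_len: int = 3           # spikes per burst
    burst_isi: float = 5.0       # intra-burst interval (ms)
    trial_duration: float = 20_000.0
    dt: float = 0.1
    community_size: int | None = None  # default: balanced split, ~500/pattern
    disjoint_communities: bool = True

    def __post_init__(self):
        if self.rate < 0 or self.dt <= 0:
            raise ValueError("rate must be >= 0 and dt > 0")
        if not 0.0 <= self.p_fail < 1.0:
            raise ValueError("p_fail must lie in [0, 1)")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must lie in [0, 1]")
        if self.noise_gap_range[0] < self.t_pat:
            raise ValueError("noise gap lower bound must be >= T_pat")
        if self.trial_duration <= self.t_pat:
            raise ValueError("trial_duration must exceed T_pat")
        p = self.rate * self.dt * 1e-3
        if p > 0.05:
            warnings.warn(f"rate*dt = {p:.3f} is not << 1; Poisson grid approximation degrades")

    @property
    def n_units(self) -> int:
        return self.n_exc + self.n_inh


@dataclass(frozen=True)
class PresentationSchedule:
    """Contiguous partition of the trial into pattern and noise epochs (ms)."""

    start: np.ndarray
    end: np.ndarray
    label: np.ndarray  # str array; NOISE_LABEL or a pattern_id

    def __post_init__(self):
        if not (np.all(self.end > self.start) and np.all(self.start[1:] == self.end[:-1])):
            raise ValueError("epochs must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.start)

    def epochs_of(self, pattern_id: str) -> np.ndarray:
        """(n, 2) start/end array of the epochs carrying ``pattern_id``."""
        m = self.label == pattern_id
        return np.stack([self.start[m], self.end[m]], axis=1)

    def presentation_counts(self) -> dict[str, int]:
        ids, counts = np.unique(self.label[self.label != NOISE_LABEL], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass(frozen=True)
class InputStream:
    """Realized afferent spikes: parallel (unit, time) arrays sorted by time."""

    units: np.ndarray          # int64
    times: np.ndarray          # float64, ms
    n_units: int
    duration: float
    schedule: PresentationSchedule
    communities: dict[str, np.ndarray]  # pattern_id -> member unit indices
    templates: dict[str, "PatternTemplate"] = field(default_factory=dict)

    def spikes_of(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]


@dataclass(frozen=True)
class WeightInitSpec:
    """Initial afferent weight law; excitatory synapses end positive,
    inhibitory negative (magnitudes drawn from the stated law)."""

    distribution: str = "gaussian"  # gaussian | uniform | lognormal
    mu: float = 0.0
    sigma: float = 1.0
    bounds: tuple[float, float] = (-3.0, 3.0)
    # LogNormal defaults matched in variance (~1) to the unit Gaussian
    lognormal_mu: float = -0.3466
    lognormal_sigma: float = 0.8326


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def _poisson_grid_flat(n_cells: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of successes in ``n_cells`` independent Bernoulli(p) trials.

    Uses geometric inter-success gaps, which is exact and O(#spikes) rather
    than O(#cells)."""
    if p <= 0 or n_cells <= 0:
        return np.empty(0, dtype=np.int64)
    out = []
    pos = -1
    # draw in chunks until past the end
    expect = max(16, int(1.3 * n_cells * p) + 8)
    while True:
        gaps = rng.geometric(p, size=expect)
        idx = pos + np.cumsum(gaps)
        if idx[-1] >= n_cells:
            out.append(idx[idx < n_cells])
            break
        out.append(idx)
        pos = idx[-1]
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def generate_poisson_train(
    rate: float, duration: float, dt: float = 0.1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Spike times (ms) of one grid-Bernoulli Poisson unit.

    Each of the ``duration/dt`` steps fires independently with probability
    ``rate*dt`` (rate in Hz, duration/dt in ms)."""
    if rate < 0 or dt <= 0:
        raise ValueError("rate must be >= 0 and dt > 0")
    p = rate * dt * 1e-3
    if p > 0.05:
        warnings.warn(f"rate*dt = {p:.3f} is not << 1")
    if rng is None:
        rng = np.random.default_rng()
    n_steps = int(round(duration / dt))
    steps = _poisson_grid_flat(n_steps, p, rng)
    return steps.astype(np.float64) * dt


def _population_poisson(
    units: np.ndarray, duration: float, rate: float, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fresh Poisson spikes for a set of units over ``[0, duration)``.

    Returns (unit_idx, time_ms). The flat Bernoulli grid spans units x steps,
    so the per-unit marginals are exactly the grid process."""
    n_steps = int(round(duration / dt))
    p = rate * dt * 1e-3
    flat = _poisson_grid_flat(len(units) * n_steps, p, rng)
    u, s = np.divmod(flat, n_steps)
    return units[u], s.astype(np.float64) * dt


# ---------------------------------------------------------------------------
# templates and communities
# ---------------------------------------------------------------------------

def build_communities(spec: InputStreamSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Assign units to per-pattern temporal communities.

    Communities are balanced between the excitatory and inhibitory halves of
    the population and, by default, disjoint; leftover units are permanent
    background noise units."""
    size = spec.community_size
    if size is None:
        size = min(500, spec.n_units // max(spec.n_patterns, 1))
    half = size // 2
    exc_pool = rng.permutation(spec.n_exc)
    inh_pool = spec.n_exc + rng.permutation(spec.n_inh)
    communities: dict[str, np.ndarray] = {}
    for k in range(spec.n_patterns):
        name = f"pattern{k}"
        if spec.disjoint_communities:
            e = exc_pool[k * half:(k + 1) * half]
            i = inh_pool[k * half:(k + 1) * half]
        else:
            e = rng.choice(exc_pool, size=half, replace=False)
            i = rng.choice(inh_pool, size=half, replace=False)
        if len(e) + len(i) < 2:
            raise ValueError("population too small for requested communities")
        communities[name] = np.sort(np.concatenate([e, i]))
    return communities


def build_pattern_template(
    spec: InputStreamSpec,
    community_units: np.ndarray,
    rng: np.random.Generator,
    pattern_id: str = "pattern0",
) -> PatternTemplate:
    """Draw one frozen Poisson template over ``[0, T_pat)`` for a community.

    For a bursting unit every template spike is replaced by a run of
    ``burst_len`` spikes at ``burst_isi`` intervals (clipped to the epoch),
    emulating high-frequency burst firing."""
    community_units = np.asarray(community_units, dtype=np.int64)
    if community_units.size == 0:
        raise ValueError("community must contain at least one unit")
    n_burst = int(round(spec.burst_fraction * len(community_units)))
    burst_units = frozenset(
        rng.choice(community_units, size=n_burst, replace=False).tolist()
    ) if n_burst else frozenset()
    u, t = _population_poisson(community_units, spec.t_pat, spec.rate, spec.dt, rng)
    unit_spikes: dict[int, np.ndarray] = {}
    for unit in community_units:
        ts = np.sort(t[u == unit])
        if unit in burst_units and len(ts):
            offs = np.arange(spec.burst_len) * spec.burst_isi
            ts = (ts[:, None] + offs[None, :]).ravel()
            ts = np.unique(ts[ts < spec.t_pat])
        unit_spikes[int(unit)] = ts
    return PatternTemplate(pattern_id, spec.t_pat, unit_spikes, burst_units)


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def apply_transmission_failure(
    spikes: np.ndarray, p_fail: float, rng: np.random.Generator
) -> np.ndarray:
    """Delete each spike independently with probability ``p_fail``."""
    if not 0.0 <= p_fail < 1.0:
        raise ValueError("p_fail must lie in [0, 1)")
    if p_fail == 0.0 or len(spikes) == 0:
        return np.asarray(spikes, dtype=np.float64)
    keep = rng.random(len(spikes)) >= p_fail
    return np.asarray(spikes, dtype=np.float64)[keep]


def apply_jitter(
    spikes: np.ndarray,
    mean_jitter: float,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    """Displace each spike by Uniform(-2m, +2m) so the mean |displacement|
    equals ``mean_jitter``; clip to ``[lo, hi)`` and re-sort."""
    if mean_jitter < 0:
        raise ValueError("mean_jitter must be >= 0")
    spikes = np.asarray(spikes, dtype=np.float64)
    if mean_jitter == 0.0 or len(spikes) == 0:
        return spikes.copy()
    shift = rng.uniform(-2.0 * mean_jitter, 2.0 * mean_jitter, size=len(spikes))
    out = np.clip(spikes + shift, lo, np.nextafter(hi, lo) if np.isfinite(hi) else hi)
    return np.sort(out)


# ---------------------------------------------------------------------------
# stream assembly
# ---------------------------------------------------------------------------

def build_schedule(spec: InputStreamSpec, rng: np.random.Generator) -> PresentationSchedule:
    """Alternate noise gaps and uniformly chosen pattern epochs over the trial."""
    starts, ends, labels = [], [], []
    t = 0.0
    dur = spec.trial_duration
    while t < dur:
        gap = rng.uniform(*spec.noise_gap_range)
        gap_end = min(t + gap, dur)
        starts.append(t); ends.append(gap_end); labels.append(NOISE_LABEL)
        t = gap_end
        if t >= dur:
            break
        if t + spec.t_pat <= dur:
            k = rng.integers(spec.n_patterns)
            starts.append(t); ends.append(t + spec.t_pat); labels.append(f"pattern{k}")
            t += spec.t_pat
        else:
            # not enough room for a full pattern: pad with noise to the end
            starts.append(t); ends.append(dur); labels.append(NOISE_LABEL)
            t = dur
    return PresentationSchedule(
        np.asarray(starts), np.asarray(ends), np.asarray(labels, dtype=object)
    )


def build_input_stream(
    spec: InputStreamSpec,
    templates: dict[str, PatternTemplate] | None = None,
    rng: np.random.Generator | None = None,
    failure_rng: np.random.Generator | None = None,
    communities: dict[str, np.ndarray] | None = None,
) -> tuple[InputStream, PresentationSchedule]:
    """Realize the full afferent stream for one trial.

    During a pattern epoch the owning community replays its frozen template
    while every other unit fires fresh Poisson noise; during noise epochs the
    whole population fires fresh noise. Transmission failure deletes every
    spike — template or noise — independently with ``p_fail``, so the
    received train differs from the sent train at every presentation without
    biasing pattern epochs against noise.
    """
    if rng is None:
        rng = np.random.default_rng()
    if failure_rng is None:
        failure_rng = rng
    if communities is None:
        communities = build_communities(spec, rng)
    if templates is None:
        templates = {
            pid: build_pattern_template(spec, members, rng, pid)
            for pid, members in communities.items()
        }
    if not templates:
        raise ValueError("at least one pattern template is required")
    schedule = build_schedule(spec, rng)

    all_units = np.arange(spec.n_units)
    unit_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    for s, e, lab in zip(schedule.start, schedule.end, schedule.label):
        if lab == NOISE_LABEL:
            u, t = _population_poisson(all_units, e - s, spec.rate, spec.dt, rng)
            unit_chunks.append(u); time_chunks.append(t + s)
        else:
            tpl = templates[lab]
            members = communities[lab]
            background = np.setdiff1d(all_units, members, assume_unique=False)
            u, t = _population_poisson(background, e - s, spec.rate, spec.dt, rng)
            unit_chunks.append(u); time_chunks.append(t + s)
            for unit, ts in tpl.unit_spikes.items():
                if len(ts):
                    unit_chunks.append(np.full(len(ts), unit, dtype=np.int64))
                    time_chunks.append(ts + s)
    units = np.concatenate(unit_chunks)
    times = np.concatenate(time_chunks)
    if spec.p_fail > 0.0:
        keep = failure_rng.random(len(times)) >= spec.p_fail
        units, times = units[keep], times[keep]
    order = np.lexsort((units, times))
    stream_obj = InputStream(
        units=units[order],
        times=times[order],
        n_units=spec.n_units,
        duration=spec.trial_duration,
        schedule=schedule,
        communities=dict(communities),
        templates=dict(templates),
    )
    return stream_obj, schedule


# ---------------------------------------------------------------------------
# initial weights
# ---------------------------------------------------------------------------

def sample_initial_weights(
    spec: WeightInitSpec, n_exc: int, n_inh: int, rng: np.random.Generator
) -> np.ndarray:
    """Initial weight vector of length ``n_exc + n_inh``.

    Magnitudes are drawn from the requested law; the Dale sign convention is
    then applied (first ``n_exc`` entries positive, rest negative)."""
    n = n_exc + n_inh
    name = spec.distribution.lower()
    if name == "gaussian":
        mags = np.abs(rng.normal(spec.mu, spec.sigma, size=n))
    elif name == "uniform":
        mags = np.abs(rng.uniform(spec.bounds[0], spec.bounds[1], size=n))
    elif name == "lognormal":
        mags = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=n)
    else:
        raise ValueError(f"unknown weight distribution {spec.distribution!r}")
    sign = np.ones(n)
    sign[n_exc:] = -1.0
    return sign * mags
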