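"""Trial read-outs: selectivity index, tuning time, SNR, spike-train
correlations and weight-distribution summaries.

The selectivity index of a pattern standardizes the gap between the mean
synaptic weight onto that pattern's community and the mean over all other
afferents, squashed through tanh:

    s.i.(t) = tanh( alpha * (mu_pat - mu_non) / (sigma_non + eps) )

Tuning to a pattern is declared at the first time the index exceeds both a
dynamic threshold and a fixed lower bound (0.15), and keeps doing so for at
least one second.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "selectivity_index", "tuning_time", "presentations_before", "snr",
    "bin_spikes", "output_cross_correlation", "weight_distribution_summary",
]

SI_ALPHA = 0.5
SI_EPS = 1e-6
SI_K = 5.0
SI_LOWER = 0.15
SI_PERSIST_MS = 1000.0


def _pool_groups(weight_snapshots: np.ndarray, members: np.ndarray,
                 n_exc: int | None, pool: str) -> tuple[np.ndarray, np.ndarray]:
    """Split snapshot columns into pattern and non-pattern groups.

    ``pool='exc'`` restricts both groups to excitatory afferents (requires
    ``n_exc``); ``pool='all'`` pools signed weights of both classes."""
    members = np.asarray(members)
    n_syn = weight_snapshots.shape[1]
    if len(members) == 0 or len(members) == n_syn:
        raise ValueError("pattern and non-pattern synapse groups must both be non-empty")
    if pool == "exc":
        if n_exc is None:
            raise ValueError("pool='exc' requires n_exc")
        members = members[members < n_exc]
        non = np.setdiff1d(np.arange(n_exc), members)
    elif pool == "all":
        non = np.setdiff1d(np.arange(n_syn), members)
    else:
        raise ValueError(f"unknown pool {pool!r}")
    if len(members) == 0 or len(non) == 0:
        raise ValueError("pattern and non-pattern synapse groups must both be non-empty")
    return members, non


def selectivity_index(weight_snapshots: np.ndarray, members: np.ndarray,
                      alpha: float = SI_ALPHA, eps: float = SI_EPS,
                      n_exc: int | None = None, pool: str = "all") -> np.ndarray:
    """Per-snapshot selectivity index of one pattern.

    ``weight_snapshots`` is (n_snap, n_syn); ``members`` indexes the
    pattern's community. With ``pool='exc'`` the mean/spread statistics run
    over excitatory afferents only — the pooling used for tuning detection,
    since rival-community inhibitory strengthening otherwise cancels the
    tuned community's signed mean."""
    members, non = _pool_groups(weight_snapshots, members, n_exc, pool)
    w_pat = weight_snapshots[:, members].astype(np.float64)
    w_non = weight_snapshots[:, non].astype(np.float64)
    mu_p = w_pat.mean(axis=1)
    mu_n = w_non.mean(axis=1)
    sd_n = w_non.std(axis=1)
    return np.tanh(alpha * (mu_p - mu_n) / (sd_n + eps))


def _threshold_series(weight_snapshots: np.ndarray, members: np.ndarray,
                      mode: str, k: float = SI_K, n_exc: int | None = None,
                      pool: str = "all") -> tuple[np.ndarray, np.ndarray]:
    """Dynamic threshold T(t) and the quantity compared against it.

    modes:
      ``sem``     T on the weight scale with the non-pattern dispersion taken
                  as the standard error of its mean; compared against the
                  pattern-mean weight (default).
      ``tanh``    T mapped through the same standardize-and-squash transform
                  as the index; compared against s.i. itself.
      ``literal`` T = mu_non + k sigma_non compared against s.i. directly.
    """
    members, non = _pool_groups(weight_snapshots, members, n_exc, pool)
    w_non = weight_snapshots[:, non].astype(np.float64)
    mu_n = w_non.mean(axis=1)
    sd_n = w_non.std(axis=1)
    if mode == "sem":
        thr = mu_n + k * sd_n / np.sqrt(len(non))
        value = weight_snapshots[:, members].astype(np.float64).mean(axis=1)
    elif mode == "tanh":
        thr = np.full(len(mu_n), np.tanh(SI_ALPHA * k))
        value = np.tanh(SI_ALPHA * (
            weight_snapshots[:, members].astype(np.float64).mean(axis=1) - mu_n
        ) / (sd_n + SI_EPS))
    elif mode == "literal":
        thr = mu_n + k * sd_n
        value = np.tanh(SI_ALPHA * (
            weight_snapshots[:, members].astype(np.float64).mean(axis=1) - mu_n
        ) / (sd_n + SI_EPS))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return value, thr


def tuning_time(selectivity: dict[str, np.ndarray], weight_snapshots: np.ndarray,
                snapshot_times: np.ndarray, communities: dict[str, np.ndarray],
                mode: str = "sem", k: float = SI_K, lower: float = SI_LOWER,
                persist_ms: float = SI_PERSIST_MS, n_exc: int | None = None,
                pool: str = "all") -> tuple[float | None, list[str]]:
    """First time (s) the tuning criterion holds and persists >= 1 s.

    Returns ``(time_s | None, qualifying pattern ids)``; more than one id
    means mixed tuning ('Others'), an empty list means no tuning. The
    criterion per pattern: s.i. > ``lower`` and the threshold comparison of
    the chosen mode, jointly maintained for ``persist_ms``."""
    if len(snapshot_times) < 2:
        return None, []
    dt_snap = snapshot_times[1] - snapshot_times[0]
    need = max(1, int(round(persist_ms / dt_snap)))
    tuned: dict[str, float] = {}
    for pid, si in selectivity.items():
        value, thr = _threshold_series(weight_snapshots, communities[pid], mode, k,
                                       n_exc=n_exc, pool=pool)
        ok = (si > lower) & (value > thr)
        # first run of `need` consecutive satisfied snapshots
        run = 0
        for j, flag in enumerate(ok):
            run = run + 1 if flag else 0
            if run >= need:
                tuned[pid] = snapshot_times[j - need + 1] * 1e-3
                break
    ids = sorted(tuned, key=tuned.get)
    return (tuned[ids[0]] if ids else None), ids


def presentations_before(schedule, pattern_id: str, t_ms: float) -> int:
    """Number of ``pattern_id`` presentations whose onset precedes ``t_ms``."""
    ep = schedule.epochs_of(pattern_id)
    return int(np.sum(ep[:, 0] < t_ms))


def snr(spike_times: np.ndarray, schedule, pattern_id: str) -> float:
    """Spike-count signal-to-noise: spikes inside the tuned pattern's epochs
    over spikes elsewhere; returns +inf when no spike falls outside."""
    spike_times = np.asarray(spike_times)
    ep = schedule.epochs_of(pattern_id)
    inside = np.zeros(len(spike_times), dtype=bool)
    for s, e in ep:
        inside |= (spike_times >= s) & (spike_times < e)
    n_in = int(inside.sum())
    n_out = int(len(spike_times) - n_in)
    if n_out == 0:
        return np.inf
    return n_in / n_out


def bin_spikes(spike_times: np.ndarray, t_start: float, t_end: float,
               bin_width: float = 25.0) -> np.ndarray:
    """Spike counts on a regular grid (times in ms)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(t_start, t_end + bin_width, bin_width)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts


def output_cross_correlation(spikes_a: np.ndarray, spikes_b: np.ndarray,
                             t_start: float, t_end: float,
                             bin_width: float = 25.0) -> float:
    """Pearson correlation of binned spike counts over a common window.

    Returns NaN (with a warning) if either train has zero variance."""
    ca = bin_spikes(spikes_a, t_start, t_end, bin_width).astype(np.float64)
    cb = bin_spikes(spikes_b, t_start, t_end, bin_width).astype(np.float64)
    if ca.std() == 0.0 or cb.std() == 0.0:
        warnings.warn("zero-variance spike train; correlation undefined")
        return np.nan
    return float(np.corrcoef(ca, cb)[0, 1])


def weight_distribution_summary(weights: np.ndarray,
                                grouping: dict[str, np.ndarray] | None = None,
                                grid_size: int = 256) -> dict[str, dict]:
    """Per-group KDE and a two-component bimodality assessment.

    A group is flagged bimodal when a two-Gaussian mixture is preferred by
    BIC over a single Gaussian and the component means are separated by more
    than the pooled component scale."""
    from sklearn.mixture import GaussianMixture

    weights = np.asarray(weights, dtype=np.float64)
    if grouping is None:
        grouping = {"all": np.arange(len(weights))}
    out: dict[str, dict] = {}
    for name, idx in grouping.items():
        vals = weights[np.asarray(idx)]
        if len(vals) < 3:
            raise ValueError(f"group {name!r} too small for a density summary")
        grid = np.linspace(vals.min() - 1.0, vals.max() + 1.0, grid_size)
        if np.std(vals) > 0:
            kde = stats.gaussian_kde(vals)(grid)
        else:
            kde = np.zeros_like(grid)
        x = vals.reshape(-1, 1)
        g1 = GaussianMixture(1, random_state=0).fit(x)
        g2 = GaussianMixture(2, random_state=0).fit(x)
        mu = g2.means_.ravel()
        sd = np.sqrt(g2.covariances_.ravel())
        separated = abs(mu[0] - mu[1]) > np.sqrt(0.5 * (sd[0] ** 2 + sd[1] ** 2))
        bimodal = bool(g2.bic(x) < g1.bic(x) and separated)
        out[name] = {
            "grid": grid, "kde": kde, "bimodal": bimodal,
            "skewness": float(stats.skew(vals)),
            "mean": float(vals.mean()), "std": float(vals.std()),
        }
    return out
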