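"""Miniature deterministic datasets for fast tests.

All fixtures are generated programmatically from a seed; nothing is stored
on disk. ``toy_stream``/``toy_template`` shrink the Fig-1-style input to 40
units and 2 patterns over 2 s; ``toy_network`` is a 20E/5I network with two
small assemblies driven by a 40-unit afferent layer.
"""

from __future__ import annotations

import numpy as np

from . import rng, spikegen
from .network import NetworkSpec, build_network
from .simulation import NeuronConfig, TrialConfig, default_neuron_config

__all__ = ["make_fixture", "toy_input_spec"]


def toy_input_spec(duration_ms: float = 2000.0) -> spikegen.InputStreamSpec:
    return spikegen.InputStreamSpec(
        n_exc=20, n_inh=20, rate=20.0, t_pat=100.0, n_patterns=2,
        community_size=16, trial_duration=duration_ms, p_fail=0.1,
    )


def make_fixture(kind: str, seed: int = 0):
    """Return a small deterministic dataset: ``toy_stream``, ``toy_template``
    or ``toy_network``."""
    if kind == "toy_stream":
        spec = toy_input_spec()
        stream, schedule = spikegen.build_input_stream(
            spec, rng=rng.stream(seed, "input"),
            failure_rng=rng.stream(seed, "failure"))
        return stream, schedule
    if kind == "toy_template":
        spec = toy_input_spec()
        r = rng.stream(seed, "input")
        comms = spikegen.build_communities(spec, r)
        return spikegen.build_pattern_template(spec, comms["pattern0"], r)
    if kind == "toy_network":
        nspec = NetworkSpec(n_exc=20, n_inh=5, n_assemblies=2, assembly_mu=4.0,
                            assembly_sigma=1.0, afferent_scale=1.6)
        net = build_network(nspec, rng.stream(seed, "network"),
                            n_aff_exc=20, n_aff_inh=20)
        cfg = TrialConfig(seed=seed, input=toy_input_spec(),
                          neuron=default_neuron_config("spike_trace"))
        return net, cfg
    raise ValueError(f"unknown fixture kind {kind!r}")
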