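"""Simulate delay-aware signaling and count unique network states.

Builds a seeded random geometric network, stimulates one node with a single
pulse, and compares the richness of the dynamics (distinct binary network
states) against a uniform-delay lattice control with the same wiring.
"""

from tseqnet import (
    SignalingParams,
    cumulative_unique_states,
    firing_raster,
    lattice_variant,
    run_simulation,
)
from tseqnet import fixtures as fx

params = SignalingParams(
    conduction_velocity=1.0, refractory_period=4.0, dt=1.0, n_steps=250
)
fixture = fx.make_random_geometric(
    n=35, p=0.09, seed=1, n_steps=250, inhibitory_fraction=0.1, params=params
)
log = run_simulation(fixture.network, fixture.delays, params, fixture.stimuli)
geo_states = cumulative_unique_states(firing_raster(log))[-1]

lattice, ldelays, lparams = lattice_variant(fixture.network, n_steps=250)
lat_log = run_simulation(lattice, ldelays, lparams, fixture.stimuli)
lat_states = cumulative_unique_states(firing_raster(lat_log))[-1]

print(f"events (geometric): {len(log.events)}")
print(f"unique states, geometric delays: {geo_states}")
print(f"unique states, uniform delays:   {lat_states}")
print(
    "-> heterogeneous conduction delays multiply the number of distinct "
    f"activity patterns ({geo_states / lat_states:.1f}x here): geometry, "
    "not just wiring, shapes the dynamics."
)
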