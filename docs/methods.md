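# Methods

## Signaling model

The simulator implements the simplest node model consistent with discrete,
delay-aware signaling on a geometric graph.

- **Graph.** A directed graph `G = (V, E)` with no self-loops and no
  duplicate edges. Each node carries a 3-D soma position (µm), a polarity
  (excitatory `E` or inhibitory `I`) and an optional class label. Only
  chemical (directed) connections are modeled; electrical gap junctions
  are out of scope.
- **Delays.** Edge delay in steps is
  `max(1, round(‖p_i − p_j‖ / v / dt))` with half-away-from-zero rounding.
  Straight-line soma distance stands in for axon path length. The clamp to
  one step prevents zero-delay edges, which would break causal ordering
  for co-located somata. Doubling the conduction velocity exactly halves
  every unclamped delay.
- **Activation.** Threshold is one incoming signal. Arrivals are grouped
  per (node, step). A node whose last activation is at least
  `refractory_steps` ago activates on any arrival; while refractory,
  arrivals are discarded outright (they do not accumulate). An activation
  triggered only by excitatory arrivals emits one signal per outgoing
  edge, carrying the *emitting node's* polarity; an activation with any
  inhibitory arrival in the same step is non-emitting (the node still
  activates and becomes refractory, but sends nothing). This
  inhibition-dominates tie-break is the deterministic, conservative choice
  for simultaneous mixed arrivals.
- **Events.** Every activation is logged with causal parent links to all
  same-step triggering arrivals. Multi-parent events are what make walk
  extraction faithful: a node fired by two simultaneous signals continues
  *both* walks. Stimulus-driven root events have no parents. Signals still
  in flight when the run ends are dropped.
- **Defaults.** Conduction velocity 80 mm/s (theoretically plausible for
  an organism of this scale), refractory period 4 ms, and a 0.15 s window
  discretized into 6000 steps (dt = 25 µs). All four are configurable.

Determinism: the engine iterates arrivals in sorted node order, so
identical inputs yield identical event logs regardless of insertion order.

## State and activity summaries

The raster `y ∈ {0,1}^{N×T}` marks emitting activations only; inhibited
(non-emitting) activations are excluded from the state vector, since the
state is read as signal output. The flag is retained in the log so the
alternative reading is recomputable. Unique-state counting is a cumulative
distinct-column count, with the all-zero quiescent state counted. Class
histograms bin emitting events per class label with a default bin of 250
steps. Raster rows and file exports index nodes by sorted name so outputs
are platform-stable.

## Temporal sequences

A temporal sequence is a causal walk from the stimulated start node to an
end-node event, obtained by depth-first traversal of the event log's
child links. Every visit to an end-node event along a path records one
sequence, so walks continuing through an end node yield additional longer
sequences. Inhibited activations can terminate but never continue a walk
(they emit nothing). Two walks tracing the same labels at different times
are distinct by default; `dedupe_labels=True` collapses them, since the
preferable counting granularity depends on the question asked. Path
enumeration is exponential in the worst case; a hard cap (default 10^6)
fails loudly rather than silently truncating.

The extraction is cross-checked, on every toy fixture and 100 fuzzed
random networks, against an independent oracle that recurses backward
over parent links from every end event.

## Similarity measure

`pairwise_match_fraction(x, y)` scans `y` once, left to right: for each
successive label of `x`, the cursor advances to that label's first
occurrence at or after the cursor and past it, counting a match. The
fraction is matches/|x| — asymmetric, with `x` the reference. The
aggregate statistic `c_α` counts reference walks whose best fraction over
the comparison set reaches α; iteration stops early once met.

Two properties worth knowing:

- The greedy scan is *not* the maximal in-order match; an LCS variant is
  provided as an off-by-default diagnostic. Greedy ≤ LCS always holds.
- The greedy fraction is **not monotone under suffix extension of `y`**:
  for `x = (B,A,A)` and `y = (A,A)` the fraction is 2/3, but appending
  `B` to `y` drops it to 1/3, because the late `B` match advances the
  cursor past both `A`s. Intuition suggesting monotonicity here is wrong;
  the property tests assert the corrected invariant (the fraction is
  unchanged when the suffix shares no labels with `x`).

## Basis decomposition

`canonicalize` collapses maximal tandem repeats (k ≥ 2 contiguous copies
of a block) scanning left to right, preferring the smallest block period,
into `(primitive block, k)` units. The stored units come from the first
pass, so re-expansion with the stored counts reproduces the input label
sequence exactly. The canonical form iterates the collapse to a fixed
point, which resolves nested repeats (`AABAAB → ABAB → AB`). For such
nested cases the fixed-point canonical is not expandable from the flat
units — grouping uses the fixed point, round-trip uses the units; walks
arising from simulated cycle traversals are one-level tandem repeats, for
which the two coincide.

`decompose_basis` groups walks by canonical label sequence (times
ignored, since repetition is defined over node sub-sequences). Groups
with ≥ 2 members are Repeating — they differ only in lap counts of a
realized cycle — and singletons are One-Time. A single self-repeating
walk whose canonical form matches no other walk is One-Time, since
"repeating" is defined relative to another member. The decomposition is a
partition, asserted in tests.

## Null models

- **Gilbert**: each ordered pair (i, j), i ≠ j, independently becomes an
  edge with `p = e/(N(N−1))`; the diagonal is excluded, consistent with
  that denominator. Expected edge count equals the original's; positions,
  polarities and labels are untouched, and delays are recomputed from
  positions afterwards.
- **Edge swap**: per iteration, |E| attempts; each draws two distinct
  edges with four pairwise-distinct endpoints and exchanges targets iff
  neither new edge exists. Weak connectivity is checked after each swap
  and the swap reverted on failure, making preservation of edge count,
  both degree sequences and weak connectedness unconditional. Weak (not
  strong) connectivity is used because even real connectomes are not
  strongly connected. Default 10 iterations.
- **Embedded substitution**: edges with both endpoints inside the member
  set are replaced by the randomized subnetwork's edges; every edge
  touching an outside node is preserved. (A literal row/column
  replacement would also erase member-to-outside edges; the
  block-substitution reading is adopted because outside connectivity is
  explicitly preserved in the construction's intent.)

All randomness flows through a single seeded generator recorded in the
`RandomizationReport`.

## Synthetic fixtures

The fixture generators produce the study's toy conditions with ground
truth derived from the construction itself, never stored as opaque
constants: chains (firing times = delay prefix sums), a diamond (one
merged event with two parents ⇒ exactly two walks), a tapped two-node
oscillator (walk count = laps completing inside the window), seeded
random geometric graphs placed uniformly in an elongated 50×1000×50 µm
box (worm-like aspect, so delays are heterogeneous), and a two-population
fixture whose source alternately drives a "V" and a "D" group with
cross-coupling — a toy analogue of ventral/dorsal motorneuron read-out.

What the fixtures do *not* emulate: realistic degree distributions,
distance-dependent wiring probabilities, synaptic weights, or the actual
connectome's community structure. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not biological
fidelity of any particular prediction.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic
networks of 10–50 nodes and windows of 13–300 steps, sizes at which the
causal walk space is exhaustively enumerable and every computation can be
cross-checked against a brute-force oracle. The acceptance study uses a
35-node geometric network (edge probability 0.09, delays 1–5 steps,
refractory 4 steps — recovery comparable to conduction, as in the
physiological regime) and selects the longest analysis window, from 250
steps downward, whose full walk set stays under 3000 paths: walk counts
grow exponentially with window length on recurrent graphs, and the walk
set is defined over a time interval of interest, so the window is part of
the study conditions and is reported alongside each quantity. The lattice
control realizes one arbitrary time unit as 10 steps so the 0.9
refraction ratio (delay 10, refractory 9) is exact in integers.

Applying the pipeline to the real 277-neuron connectome requires external
wiring/position/GABA compilations which ship with no accession; the
loaders (`load_network_bundle`), the position-drop rule in
`build_network`, and the counting-granularity switches are all in place
for users who supply those files.

## Known limitations

- No membrane-potential accumulation, synaptic weights, noise, or signal
  attenuation; the threshold is fixed at one signal.
- Straight-line distances understate true neurite path lengths.
- Discretization: delays round to whole steps (half away from zero), so
  two distinct geometries can yield identical delay assignments at coarse
  dt.
- Walk enumeration is exponential on recurrent graphs; the cap makes this
  explicit rather than silently sampling.
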