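# Methods

## Geometry and coordinate frame

The mock-up platform is a 7 × 20 m rectangle. The package fixes a frame the
measurements never state explicitly: origin at the platform centre, long
axis x ∈ [−10, 10] with the 3 m entrance staircase centred at x = +10,
cross axis y ∈ [−3.5, 3.5] with the train-arrival side mapped to y < 0.
Safety lines run parallel to the long edges at 0.8 m; the band between a
safety line and the edge is the hazard zone. Points exactly on the line
count as legal — the boundary is a zero-measure set and waiting behind the
line, not on it, is what the protocol distinguishes. Only the long
(track-facing) edges carry hazard bands; the short sides hold the entrance
and the back wall. Obstacles (narrow 0.6 × 3.6 m, wide 3 × 3.6 m) sit at
the centre with their 3.6 m extent across the platform, so they visually
separate the track sides; both footprints lie strictly between the safety
lines.

## Voronoi densities and tile profiles

Per frame, pedestrian *i*'s cell is the region of the walkable polygon
(rectangle minus obstacle) closer to them than to anyone else, and carries
the constant density 1/|A<sub>i</sub>|. Cells are closed by construction:
each point is mirrored across the four rectangle edges before the
tessellation, which makes the rectangle edge the bisector between a point
and its mirror; a final polygon intersection removes the obstacle. Cell
areas therefore sum to the walkable area to machine precision — asserted at
1 ppm in the tests.

The profile parcels the platform into 0.2 m square tiles and averages, per
tile and over the window frames, ∑<sub>i</sub>|A<sub>i</sub> ∩ tile| /
|A<sub>i</sub>| divided by |tile ∩ walkable|. Using the intersected area
(not the full tile area) in the denominator for boundary-straddling tiles
makes the profile integrate exactly to the mean person count; the choice
only affects boundary tiles. Marginal curves collapse the profile along one
axis per track side: the mean over accessible tiles of each row/column
slice, with the deviation from the curve's overall mean.

Degenerate inputs: one agent owns the whole walkable polygon; coincident
points (< 1 µm) are rejected as tracking errors; exactly collinear sets are
rescued by a deterministic sub-nanometre jitter whose effect is far below
every reported tolerance.

Profiles sub-sample frames (default stride 10, i.e. 5 fps from the native
50 fps) — waiting crowds are quasi-static, so sub-sampling changes profiles
far less than the 1 % conservation tolerance. The standard analysis size
used in the tests and the acceptance script is a 100-agent, 2-minute run at
5 fps.

## Delaunay distances

Interpersonal distances are the unique edge lengths of the scipy Delaunay
triangulation per frame, pooled over the waiting window. Convex-hull edges
are kept by default: distances of 1.6–2.5 m are meaningful (slow walkers),
so no silent cut-off is applied. Co-circular configurations (the unit
square) admit either diagonal; tests compare edge sets up to that tie.
For fewer than three or collinear agents the triangulation is degenerate
and the operation raises; callers may fall back to pairwise distances.

**Boundary artifacts.** The Delaunay edge set of a crowd that fills a
rectangle necessarily contains a small population of multi-metre hull
edges: points lined up along a wall are nearly collinear, so the convex
hull skips the slightly recessed ones and bridges distant people. These
are tessellation artifacts, not interpersonal distances — even a perfectly
even lattice crowd acquires them as soon as positions are perturbed by a
few centimetres, inflating the raw pooled mean by ≈ 0.2 m and the s.d. by
an order of magnitude. The spacing-recovery statistics (tests and
acceptance script) therefore exclude edges above 3 m, beyond any distance
the analysis treats as a real neighbour relation; the raw uncut mean is
reported alongside. The `max_length` option of `delaunay_edges` exposes the
same cut-off to users; it defaults to off.

Two theoretical helpers mirror the back-of-envelope numbers used when
interpreting the measurements: `grid_spacing(A, n) = √(A/n)` (1.87 m for 40
and 1.18 m for 100 persons on the full 140 m², deliberately ignoring
obstacles) and `grid_density(s) = 1/s²` (≈ 0.69 m⁻² at 1.2 m spacing, the
interior square-lattice Voronoi cell). A hexagonal-lattice variant
(ρ = 2/(√3·s²)) would give ≈ 0.80 m⁻² at the same spacing; only the
square-lattice relation is implemented.

## Floor field

Five components on the analysis grid, each with a continuous evaluator:

* **D, entrance proximity** — implemented as the normalised cubic
  D(x) = ((x − x_far)/(x_ent − x_far))³: 1 at the entrance short side, 0 at
  the far end, decaying as the cube of the normalised distance from the far
  end. A raw shifted cubic (x + x_min)³ cannot be maximal at the entrance
  for any consistent sign convention, so the normalised form — which
  satisfies both defining properties (maximal at the entrance, cubic decay
  toward the far end) — is used.
* **T, arrival side** — logistic (1 + e^(−a·s))⁻¹ in the signed
  cross-coordinate s, positive toward the arrival side; 0.5 on the midline.
  Default a = 2 m⁻¹ (saturates within ~2 m of the midline).
* **E, edge safety** — logistic of the signed safety-line distance B
  (negative inside the hazard band): exactly 0.5 on a safety line, → 1
  mid-platform. Default b = 3 m⁻¹ (the edge effect is confined to ~1 m
  around the line).
* **F, flow avoidance** — negative Gaussian of depth c centred on the
  entrance; defaults c = 1, d = e = 3 m matching the 3 m entrance width.
* **O, obstacle** — f · s · exp(−(x−x₁)(x−x₂)/g² − (y−y₁)(y−y₂)/h²) with s
  the signed cross-offset from the obstacle midline oriented toward the
  arrival side: attractive in front (line of sight to the train), repulsive
  behind, antisymmetric about the midline, decaying to neutral. Defaults
  f = 1, g/h = obstacle half-extent + 1 m (influence dies within ~2 m).
  Zero (with a log notice) on obstacle-free geometry.

The constants a–h are free modelling parameters, not measured values; every
default is overridable.

**Normalisation before superposition.** The raw components live on
incommensurate scales, so weights of order 1–3 are only meaningful after
each component is rescaled to unit maximum absolute value over walkable
cells; `superpose` does this by default. The illustrative weight set
(w₁…w₅) = (1, 2, 3, 1, 0) — w₅ = 3 with an obstacle — produces the expected
qualitative pattern: the hot zone on the arrival side of the
entrance-proximal half, and a cold shadow directly behind the obstacle.
These patterns are asserted as region membership and inequalities, not as
pixel values.

## Synthetic runs

The generator reproduces the protocol's statistical structure, not the
psychology of real passengers:

* **Entry** — agents enter at the entrance centre at intervals uniform in
  [3, 5] s and walk at 1 m s⁻¹ along a corner-waypoint path around the
  obstacle (0.3 m inflation; no social-force model).
* **Waiting-place choice** — one-shot: a cell's score is the floor-field
  value minus κ·∑ exp(−(r/r_pref)²) over occupants; cells whose jittered
  candidate point would come within the hard-core radius (0.6 m, plus the
  clipped-sway headroom of both heads) of an occupant are excluded, and a
  cell is drawn with probability ∝ exp(score/temperature), temperature
  0.05. Chosen places are never revised — relocation is rare in waiting
  crowds and is out of scope.
* **Crowd-repulsion amplitude κ = 0.1** — calibrated once against the
  field's own scales: the arrival-side advantage after normalisation is
  w₂·ΔT ≈ 1.9, so κ must keep the accumulated repulsion of a packed
  arrival-side crowd (≈ 2 per agent-ring at ~1.1 m spacing) below that
  advantage until the side genuinely jams; larger values make agents
  maximise isolation and spread over the full platform, which contradicts
  the observed arrival-side clustering. With κ = 0.1 a 100-agent crowd
  fills the arrival side first, overflows past the midline when it jams,
  and recovers a pooled neighbour distance close to r_pref.
* **Edge standoff** — each agent draws a personal comfort clearance from
  the platform boundary, uniform in [0, 0.5] m (with a graded fallback
  when crowded out). Real crowds line up against edges at individually
  varying distances; without this the simulated boundary rows are
  razor-straight, which no tracking data shows.
* **Standing** — head sway is an AR(1) low-pass-filtered Gaussian
  (φ = 0.95, stationary s.d. 0.03 m), clipped at 3σ so the placement
  margins are hard guarantees. The hazard band is a hard constraint: the
  experiments recorded zero waiting positions inside it, and a soft field
  penalty alone cannot guarantee zero.
* **Walkers** — under waits of ≥ 4 min, a fraction p_walk = 0.15 abandons
  its spot after a random time and wanders at 0.5 m s⁻¹ between random
  waypoints on the non-arrival side. This is a labelled stand-in: the real
  walkers' wave-like paths are not modelled quantitatively.
* **Randomness** — one seed; per-agent substreams are spawned in entry
  order, so adding an agent never perturbs earlier agents' draws, and equal
  seeds give bit-identical trajectory files.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the experiments — sequential
entry, field-guided arrival-side clustering, hazard-band avoidance,
hard-core spacing with a preferred interpersonal distance, entry-order
determinism — so pipeline tests on it validate the measurement chain and
the directional effects (the long-distance fraction falls as the crowd
grows from 40 to 100; zero hazard-band occupancy). It does not contain
social groups, luggage, visual-preference heterogeneity beyond the edge
standoff, repositioning dynamics, or boarding; the experimentally reported
density band (0.6–1.3 m⁻²) and distance fractions (30 %/15 %) depend on
human behaviour and are bracketed qualitatively, not reproduced.

## Numerical choices

* Grid resolution 0.2 m everywhere (profiles and fields are directly
  comparable); grids cover the full rectangle, cells without walkable
  overlap are masked.
* Tessellation conservation asserted at 10⁻⁶ relative; profile integrals at
  1 %; tile values cross-checked against dense Monte-Carlo point sampling
  of the cell-density field at 1 % on small fixtures; Delaunay edges
  cross-checked against a brute-force empty-circumcircle construction for
  n ≤ 8.
* Profiles from several runs are computed per run; cross-run averaging is
  cell-wise with equal weights and off by default.
* Sample skewness of an all-equal distance set is undefined and reported
  as 0 with a `degenerate` flag.
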