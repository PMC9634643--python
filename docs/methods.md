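# Methods

## The accessibility model

Ga2SFCA is a two-step floating catchment area method in which both the
facility-side and the population-side sums are weighted by a truncated
Gaussian distance-decay kernel. Its behavioural assumptions are: (i)
every resident of a cell is a potential park user and residents
interact with all parks within a mode-specific travel budget; (ii)
willingness to travel decays smoothly with distance, slowly near home
and near the budget edge and fastest in between (the s-shape of the
Gaussian), reaching exactly zero at the catchment radius; (iii) a
park's capacity is proportional to its area (hm²), ignoring facility
quality. The resulting index `A_i` has units hm² of park per person
and satisfies the exact bookkeeping identity Σ_i P_i·A_i = Σ_j S_j
whenever every supply point has some decay-weighted population in
range — the main correctness oracle of the test suite, together with
an independently coded brute-force double loop.

Distances are planar Euclidean meters inflated by a per-mode detour
factor (defaults: walking and cycling 1.3, driving 1.4 — typical
network-to-crow-flight ratios for dense urban road networks). A routed
origin–destination matrix can be supplied instead as a CSV
(`supply_id, cell_id, distance_m`); missing pairs are treated as
unreachable. Same-cell supply/demand pairs use the OD value when
present, else the straight-line distance (zero when coincident).

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| hexagon side | 500 | m | fine-grained demand unit; equidistant centroid-to-edge in six directions limits shape-induced bias |
| time thresholds | 15, 30 | min | a comfort budget and a limit budget |
| mode speeds | 5 / 15 / 30 | km/h | walking and cycling at the upper edge of their classification bands; driving 30 km/h, an urban average consistent with a 7.5 km radius in 15 min |
| speed bands | 0–5 / 5–15 / 15–60 | km/h | average trip speed; half-open `[lo, hi)`, driving closed at 60, faster trips excluded |
| large-park threshold | 100 | hm² | parks at/above it are entered through entrance points; area split equally over entrances so supply is conserved |
| residence screen | > 10 distinct days | — | strict reading of an "over 10 days" rule; configurable |
| night window | 21:00–08:00 | — | residence = longest cumulative dwell in this window; ties to the lower cell id |
| visit rule | ≥ 30 min in 08:00–21:00 | — | contiguous same-cell event runs in a green-space cell |
| grading | 5 classes, ratio 2 | — | geometric-interval breaks `(r^m−1)/(r^k−1)`; break values fall in the upper class |
| deviation bands | 0.8 / 1.2 | — | closed into "balanced" on both edges |

Resolved ambiguities (package design choices): the residence-day
screen is strict (`>`, not `≥`); per-mode accessibility enters the
overlay raw (unnormalized), with min–max normalization applied only
before grading; the deviation index uses the 1–5 accessibility grade
as the supply level by default (`level_source="comprehensive"`
switches to raw C_i); the supply denominator of the deviation index
sums the levels of all graded cells, including visitor-free ones;
mode classification uses door-to-door average speed; visitor counts
deduplicate users over the full analysis window.

## The synthetic city

The generator emulates the statistical structure of a month of
single-operator signaling data for a mid-sized city:

* **Extent and grid** — 27 × 18 km (486 km²) at 500 m hexagon side
  (777 cells, the same order as the 827-cell study grid it emulates).
* **Parks** — 30 convex polygons with lognormal areas (median ≈ 20
  hm²), 15 % forced ≥ 100 hm² with 2–6 boundary entrances; placement
  is rejection sampling without overlap, raising a placement error
  when the extent cannot host them.
* **Population** — 100,000 persons multinomially allocated to cells
  from a two-center Gaussian-mixture density, so totals are exact and
  a mirror-symmetric configuration yields statistically symmetric
  counts.
* **Users and events** — 20,000 users with residence drawn ∝ cell
  population; every user dwells at home 21:30–07:30 each of 31 nights
  (clean residence recovery); Poisson(3) park visits per user, each a
  daytime dwell in a green-space cell of a park chosen ∝ area ×
  Gaussian decay of distance (scale 15 km); 90 % of visits dwell
  35–120 min (detectable), the rest 10–25 min.
* **Trips** — the mode is drawn first from the target shares
  (9.06 / 18.41 / 72.53 % walk/cycle/drive), then the speed uniform
  inside that mode's band, so speed-band classification inverts the
  assignment with zero error by construction; empirical shares match
  the target within binomial sampling error (±0.01 at ≥ 50,000 trips).

The generator stores every latent assignment in `truth`, making
detector recovery an exact, first-class test: with all visits long,
detected residences and per-cell visitor counts equal truth.

What it does **not** emulate: base-station positioning noise and
ping-pong oscillation, operator market share (penetration scaling),
road networks (detour factors stand in for routing), dwell-duration
and trip-frequency distributions estimated from real data, and
non-convex park shapes. Passing recovery tests therefore demonstrates
the correctness of the detection and catchment logic under clean dwell
structure, not robustness to noisy real-world signaling.

## Numerical choices

* The decay kernel is evaluated in closed form; values beyond the
  radius are exactly 0 and the kernel is exactly 1 at distance 0, so
  catchment membership `d ≤ d0` and the weight's support coincide.
* Supply points with an empty catchment get R_j = 0 with a logged
  warning instead of being dropped, keeping the conservation identity
  auditable (their S_j is knowingly excluded from the identity).
* Hexagon vertices are tabulated offsets from the cell center rather
  than per-cell trigonometry, so shared vertices of neighboring cells
  are bitwise identical and the tessellation is exact; points on
  shared edges locate to the lower cell id.
* Min–max normalization maps a constant surface to all-zero scores;
  geometric-interval grading then puts every cell in grade 1.
* All randomness flows from one `numpy` Generator seeded by the
  configuration, and every artifact is written with fixed float
  formats: a fixed configuration reproduces byte-identical outputs.

## Problem sizes

The default demo configuration (777 cells, 30 parks, 20,000 users,
~680,000 events, ~60,000 trips) runs the full pipeline in well under a
minute on one CPU; the test suite's statistical checks use 50 random
catchment instances up to 50 × 500 and Monte-Carlo population checks
pooled over 20 seeds.

## Known limitations

Accessibility uses straight-line-with-detour distances unless a routed
OD matrix is provided; park capacity is area only (no quality or
congestion); demand is total population without subgroup weighting;
the deviation index inherits the ambiguity of "accessibility level"
(grade vs raw index — both offered, grade default); hexagons are not
clipped to irregular administrative boundaries (cells are retained by
centroid-in-extent).
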