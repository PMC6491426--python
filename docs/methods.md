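# Model and methods

`lhonsim` simulates the spread of a superoxide insult through a
two-dimensional optic-nerve cross-section, asking why Leber hereditary
optic neuropathy (LHON) preferentially destroys small temporal axons.
This note records the model as implemented, the defaults and why they
hold their values, the numerical choices, and what the synthetic data
do and do not establish.

## Nerve geometry

The nerve is a disk of radius `s · 750 µm` at radius-scale `s`
(the human optic nerve is ~1.5 mm across), holding
`round(s² · 1,200,000)` axons so that axon density matches the human
nerve at every scale.  At the default 10% scale this is 12,000 axons on
a 1500×1500 pixel grid (10 px/µm; one pixel = 0.1 µm).

Axons are non-overlapping disks placed by random sequential adsorption:
a uniform position inside the nerve, a radius drawn from the local size
profile, acceptance iff every previously placed axon is at least
`clearance` away edge-to-edge.  The clearance (default 0.05 µm)
reserves extracellular corridors standing in for myelin and glia while
keeping the packing feasible at human axon density; per-axon retries
are capped at 200 and the global attempt budget at 50 per target axon,
with an explicit packing-failure error below 95% of target.  Note that
rejection is radius-dependent: in regions whose nominal profile is
dominated by large calibers the packer accepts fewer candidates, so the
realized density and caliber distribution deviate from the nominal
mixture exactly as crowding dictates.

Rasterization classifies each pixel center (outside / extra-axonal /
axon id).  An axon's *perimeter pixels* are those with at least one von
Neumann neighbor carrying a different label; perimeter counts scale
linearly with radius, which is what ties production to circumference.

## Regional size profiles

Each quadrant (temporal, superior, inferior, nasal) carries a
three-component sum of Gaussians over radius,
`f(r) = Σ a_k exp(−((r−µ_k)/σ_k)²)`; intermediate angles interpolate
the two adjacent quadrant profiles linearly in the nine coefficients
(a blockwise per-quadrant mode is available).  Profiles can also be
fitted to radius histograms by bounded nonlinear least squares with
ten random restarts, reporting adjusted R².

The shipped default profiles place a *bulge* of small calibers
(components at 0.26 and 0.27 µm) identically in every quadrant and
carry all regional contrast in the third, large-caliber component
(0.52–0.58 µm), whose population share rises from ~19% temporally to
~80% nasally.  Three considerations fixed this shape:

* small- and medium-tertile axons then share one spatial distribution,
  so their degeneration fractions track each other, as observed;
* the large tertile is dominated by the distinct large-caliber
  component concentrated nasally/inferiorly, producing the reported
  relative sparing of large axons and of the nasal sector;
* packing at human density is geometrically feasible (mean caliber
  ~0.3 µm temporally, ~0.36 µm nasally, within reported optic-nerve
  ranges).

Size classes are *empirical tertiles* of each generated population
(ties at a cut go to the lower class), so the initial small/medium/
large proportions are equal on every instance by construction.
Sampled radii are truncated to 0.1–3.0 µm.

## Superoxide dynamics

Every in-nerve grid element updates synchronously from the previous
field:

    C'[i,j] = ( C[i,j] + P[i,j] + Σ_n D_pair · (C[n] − C[i,j]) ) · (1 − S[i,j])

* **Diffusion** uses the four von Neumann neighbors; the pair constant
  is the mean of the two elements' location constants (intra- vs
  extra-axonal) and pairs crossing the nerve border contribute nothing
  (no-flux).  Stability requires each constant ≤ 0.25; both defaults
  sit at 0.25, i.e. membranes impose no extra resistance — the model
  deliberately omits membrane, glial and microvascular diffusion
  heterogeneity.
* **Production** adds `P_coeff` (default 0.06 µmol/iteration) at each
  perimeter pixel of each alive axon, making per-axon production
  proportional to circumference in the slice (the Na⁺/K⁺-ATPase
  argument: conduction scales with membrane area).
* **Scavenging** is first order: each element retains the fraction
  `1 − S` of its content per iteration, `S_intra` inside alive axons
  and `S_extra` elsewhere (both default 0.005/iteration).  First-order
  kinetics is the standard dismutase assumption and the only reading
  under which the working range of the constants (10⁻⁶–0.05) is
  self-consistent with release constants of 10³–3·10⁴ µmol; a
  zeroth-order subtractive variant remains available behind
  `scavenging="subtractive"`.

**Degeneration.** After each update, any alive axon whose mean
intra-pixel concentration reaches the toxic threshold `threshold_T`
degenerates: `release_R` µmol (default 20,000) is spread uniformly over
its pixels and those pixels immediately become extra-axonal for
production, scavenging and diffusion.  The mean aggregator is the
substantive choice (a max-pixel variant exists): dividing the same
influx over a larger cross-section is precisely how large axons resist,
since without membrane resistance their interior otherwise tracks the
ambient field.

**Injury.** The insult is `injury_amount` µmol (default 5·10⁵) spread
uniformly over a disk of radius 5% of the nerve radius at a named
anatomical site.

**Steady state.** The run ends when no element's concentration changes
by more than `ss_epsilon = 0.01` µmol per iteration, with no new
deaths, for 10 consecutive iterations (`ss_metric="element"`).  A
variant tracking the change of the *total* superoxide instead is
available (`ss_metric="total"`); it declares steady state two-to-three
thousand iterations later on identical degeneration outcomes, because
the summed field keeps draining long after every element is locally
quiescent.  Runs hitting `max_iterations` return flagged
`converged=False` rather than raising.

## Calibration

Most constants have no published values, so the model is anchored the
way its outcomes were originally benchmarked: steady-state survival of
a mid-temporal injury on the 10%-scale nerve must land in 35–40%, the
range estimated from LHON histopathology.  `calibrate()` bisects one
free parameter (by default the toxic threshold, survival being
monotone in it) until the benchmark holds, in at most 12 evaluations;
parameters already in band are returned unchanged.  The shipped
`threshold_T = 16.74` is the result of that procedure; with it the
mean mid-temporal outcome is ~60% degeneration (survival ~40%) with
within-class fractions of roughly 68/67/45% for small/medium/large.

## Dynamics of the cascade

With these constants the simulation operates as a threshold-limited
excitation wave.  Each degenerating axon's release creates a local
concentration spike far above threshold; neighbors within roughly a
micron integrate enough of it to cross threshold within a few
iterations, so the wave hops axon-to-axon through regions rich in
small, tightly packed calibers.  Where the large-caliber component
dominates (nasal, and increasingly toward the inferior route), each
potential victim needs `threshold × area` micromoles — several times
more — while contributing the same fixed release, and the chain
reaction starves.  The front therefore races through the temporal
half, partially penetrates the superotemporal/inferotemporal wedges,
and stops against the nasal sector; zone-level damage grades from ~100%
temporally to a few percent nasally.  Large axons inside the swept
region are also partially spared: the pool around a passing front
decays with time constant 1/S = 200 iterations, which is comparable to
the `r²/D` interior-equilibration time of the largest calibers.

## Parameters at a glance

| parameter | default | units | role |
|---|---|---|---|
| scale | 0.1 | – | nerve radius as fraction of human |
| resolution | 10 | px/µm | raster resolution |
| clearance | 0.05 | µm | minimum axon separation |
| D_intra, D_extra | 0.25, 0.25 | – | pair diffusion constants |
| P_coeff | 0.06 | µmol/iter | production per perimeter pixel |
| S_intra, S_extra | 0.005, 0.005 | 1/iter | first-order scavenging |
| threshold_T | 16.74 | µmol | toxic mean concentration |
| release_R | 20,000 | µmol | release per degenerating axon |
| injury_amount | 5·10⁵ | µmol | initial bolus |
| injury_footprint | 0.05 | nerve radii | bolus disk radius |
| ss_epsilon | 0.01 | µmol | steady-state tolerance |

Concentration units are internally consistent but arbitrary; the
anchors are the scavenging fractions, the release-constant range, and
the survival benchmark.

## Zones and visual fields

The nerve is sectorized into the seven Garway-Heath zones by angle:
nasal 110°, then 40° sectors (inferonasal, inferotemporal on one side;
superotemporal, superonasal on the other) and an 89°-wide temporal
sector split at its bisector into 6.1 (superior half) and 6.2.  Zone
ids run nasal → temporal with 2–3 assigned along the inferior route and
4–5 along the superior route; since the published sector map does not
number zones, this assignment (and the whole map) is configurable.
The 76 Humphrey 30-2 test locations are assigned to zones through a
documented geometric approximation of the nerve-fiber-bundle map
(field inversion through the nodal point, entry angle at the disc);
the table ships as editable data and reproduces the topology of the
published map, not its patient-derived boundaries.

The 20-site validation lattice places injuries on the four anatomical
axes at radius fractions 0.15/0.3/0.5/0.7/0.85 (sites 1–5 nasal, 6–10
superior, 11–15 temporal, 16–20 inferior).

## What the synthetic data show — and what they do not

No external data are required anywhere: radius histograms, visual
fields and toy diffusion cases are generated programmatically with the
statistical structure the model assumes (regional caliber skew,
temporal visual-field depression).  Passing tests therefore establish
internal consistency — that the implemented mechanism produces the
size- and location-selective degeneration pattern under realistic
anatomy — not agreement with any particular patient's histology.  The
regional mixture coefficients are design choices constrained by
qualitative anatomy (caliber gradients, packing feasibility) rather
than fits to published histograms, and the visual-field machinery is
exercised against synthetic fields only.

## Numerical choices

* Synchronous (Jacobi) update from the previous field only: element
  order cannot influence results, which also defines correctness for
  any parallel execution.
* The production constant is quantized to single precision so that all
  three update implementations (vectorized fast path for uniform
  constants, table-lookup general path, pure-numpy reference) agree to
  float64 rounding; the reference implementation is the oracle in the
  test suite.
* With production and scavenging off, total superoxide is conserved to
  ~10⁻¹⁶ relative per step (pair terms cancel exactly).
* Ties: an axon exactly at threshold dies (≥ comparison); a radius
  exactly at a tertile cut joins the lower class; an angle exactly on
  a sector boundary belongs to the sector starting there.
* Degenerate inputs raise typed errors: infeasible packing, footprints
  outside the nerve, non-finite fields, unbracketable calibration
  targets, incomplete visual fields.
* Reproducibility: one integer seed determines the nerve, the injury
  and hence (the dynamics being deterministic) the entire degeneration
  history bit-for-bit on a given platform.

## Problem sizes

Most development and testing runs use the 10%-scale nerve, matching
the reference configuration.  The shipped studies default to desk-scale
sizes: six-seed repetition studies, two-seed sensitivity sweeps, and
single-seed 20%-scale checks; 50%-scale runs (≈304,000 axons on a
7500² grid) are supported but guarded by an explicit memory budget.
A 10%-scale steady-state run takes on the order of half a minute on
one core; 20%-scale runs several minutes.

## Known limitations

* Two-dimensional: no longitudinal diffusion along axons.
* No glia, microvasculature, myelin thickness or membrane resistance;
  a single toxin with no interconversion among reactive oxygen species.
* The within-class contrast between small/medium and large axons
  (~23 percentage points at the calibrated operating point) is somewhat
  smaller than the steepest reported contrasts; in this geometry the
  spared fraction is dominated by where the wave stops rather than by
  in-place selection, and the superotemporal sector and the temporal
  sub-zones die slightly more completely than reported (see the zone
  discussion above).
* The scavenging budget is extracellular-dominated: axon pixels cover
  only ~30% of the nerve at the maximum packable density, so with equal
  per-element constants most removal happens outside axons.  Halving
  the intra-axonal constant therefore deepens the cascade to ~70%
  rather than near-totality, and eliminating extracellular scavenging
  collapses the nasal wall entirely.  An intra-dominated removal budget
  would require axon area fractions beyond what non-overlapping disks
  with clearance can pack at human axon density.
* Iteration counts are not calibrated to wall-clock disease time; only
  their ordering (temporal injuries take longer to reach steady state
  than nasal ones) is meaningful.
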