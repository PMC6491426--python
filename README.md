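# lhonsim

A Monte Carlo simulator of superoxide-mediated axonal degeneration in
optic-nerve cross-sections, built to study why Leber hereditary optic
neuropathy (LHON) preferentially destroys the small-caliber temporal
axons of the papillomacular bundle.

The package is for computational neuroscientists and vision researchers
who want a mechanistic, reproducible sandbox for the spatial spread of
an axonal toxin: it generates anatomically structured synthetic nerves,
propagates an initial superoxide insult by reaction–diffusion, and
summarizes the resulting degeneration by axon size class and
Garway-Heath sector.

## The model

A nerve at radius-scale *s* is a disk of packed, non-overlapping
circular axons (≈ *s*²·1.2·10⁶ of them, the human count scaled by
area) rasterized onto a pixel grid at 10 px/µm.  Axon calibers follow
regional three-component Gaussian profiles — small axons temporal,
large axons nasal — and size classes are population tertiles.
Superoxide evolves on the grid by a synchronous von Neumann update

    C'ᵢⱼ = ( Cᵢⱼ + Pᵢⱼ + Σₙ D·(Cₙ − Cᵢⱼ) ) · (1 − Sᵢⱼ)

with production P on the perimeter pixels of alive axons (∝
circumference), first-order scavenging S per element, and no-flux
boundaries.  An axon whose mean internal concentration reaches a toxic
threshold degenerates and releases a fixed superoxide bolus over its
footprint, feeding the cascade.  A run ends at steady state (no element
changes by more than 0.01 µmol per iteration, no new deaths).  The
toxic threshold is calibrated so that 35–40% of axons survive a
mid-temporal injury, the range suggested by LHON histopathology.

See `docs/methods.md` for the full model description, parameter table
and limitations.

## A worked example

```python
from lhonsim import InjurySpec, SimulationParams, build_nerve, run_to_steady_state

model = build_nerve(scale=0.1, rng_seed=0)          # ~12,000 axons, 1500x1500 px
result = run_to_steady_state(model, InjurySpec(preset="mid_temporal"),
                             SimulationParams())

print(f"{100*result.overall_dead_fraction:.1f}% degenerated "
      f"(steady at iteration {result.steady_iteration})")
wc = 100 * result.class_dead_fractions("class")
print(f"within-class small/medium/large: {wc[0]:.1f} / {wc[1]:.1f} / {wc[2]:.1f} %")
```

prints, for this seed:

```
60.1% degenerated (steady at iteration 5067)
within-class small/medium/large: 67.7 / 67.7 / 45.0 %
```

About three fifths of the nerve degenerates: the insult ignites a
degeneration wave that consumes the small/medium-caliber temporal and
central regions and stalls against the large-caliber nasal sector, so
small and medium axons die at equal, high rates while almost half the
large axons — mostly nasal — survive.  The same run with a
`"mid_nasal"` preset ends near 0.6% degeneration.

More narrative scripts live in `examples/` (nerve anatomy, injury
location, zone summaries vs. synthetic visual fields, sensitivity
sweeps).  A thin CLI wraps the same calls:
`lhonsim run --config run.yaml`, `lhonsim sweep S_intra 0.0025 0.05`,
`lhonsim repeat`, `lhonsim zones`, `lhonsim fixtures`, …

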