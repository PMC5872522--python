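# Methods

## Model

`melnest` implements a volume-exclusion process on a 3D square lattice:
each site holds at most one agent, and all dynamics are per-agent
Bernoulli events resolved by a random sequential update. Two species are
modelled. *Skin* agents (keratinocytes and fibroblasts, treated as one
population) are motile and proliferative. *Melanoma* agents are motile,
proliferative and mutually adhesive: a melanoma agent that has passed
its motility gate moves only with probability (1 − q)^a, where a is the
count of melanoma agents among its 26 Moore neighbours at its current
site, evaluated before the move. Skin agents never experience adhesion,
reflecting the mesenchymal, individually migrating character of
fibroblasts. There is no cell death, no chemotaxis, no nutrient field
and no explicit gravity; downward invasion emerges from diffusion into
the vacant bulk.

Each step of duration τ runs a motility phase then a proliferation
phase. A phase performs exactly N selections with replacement, where N
and the selectable list are frozen at phase start; daughters born
mid-phase join the registry immediately but are not selectable until the
next step. This keeps the expected event count at N·P per phase and
makes results independent of registry ordering. Movement targets are
drawn uniformly from the six von Neumann directions; a draw whose target
is occupied or vertically out of domain is an *aborted event*, not a
re-draw — re-drawing would inflate effective motility near boundaries
and break the diffusivity relation below. Daughters are placed uniformly
among the *vacant* in-domain von Neumann sites, aborting only when none
is vacant. The stricter convention (draw one of six directions, abort
if the drawn site is occupied) was considered and not implemented: it
couples the birth rate to local crowding more strongly than the
abort-only-when-surrounded rule the model is defined with, and carrying
a second convention as a switch would double the surface to validate.

Boundaries: lateral faces are periodic (the lattice represents the
central region of a larger tissue, so agents leaving one side re-enter
the other); the top (k = 0, the seeding surface) and bottom layers are
no-flux. The Moore count and the nest labelling wrap laterally for
consistency with movement.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| Δ | lattice spacing ≈ cell diameter | 20 | μm |
| τ | time-step duration | 0.01 | h |
| P_m^(m), P_m^(s) | motility probability per selection | 0.075, 0.3 | – |
| P_p^(m), P_p^(s) | proliferation probability per selection | 0.0004, 0.00025 | – |
| q | melanoma–melanoma adhesion strength | 0.7 | – |

The defaults describe an SK-MEL-28 melanoma line co-cultured with
primary human skin cells, taken from prior cell-scale estimates rather
than fitted to nest data: they correspond to proliferation rates
λ = P_p/τ of 0.04 /h (melanoma) and 0.025 /h (skin) and diffusivities
D = P_m Δ²/(6τ) of 500 and 2000 μm²/h. Both conversions are exact
arithmetic and are exposed in both directions (`derive_rates`,
`probs_from_rates`); note x·f/f round-trips only to ~1 ulp in binary
floating point unless f is a power of two.

Initial conditions match the wet-lab seeding protocol: cells are
pipetted inside a 3 mm-radius disc, the lattice surface is a 3 mm
square, so the density-matched agent count is n·side²/(π r²), rounded
half away from zero. The experimental 30 000 skin and 1250/5000/8500
melanoma cells give 9549 skin and 398/1592/2706 melanoma agents. Runs
last four days (9600 steps), matching the culture period.

## Simulated data generation

`seed_surface` *is* the study's data generator: it places the two
populations uniformly at random, without replacement, on the k = 0
layer, and the engine evolves them. All randomness — placement, agent
selection, gates, directions, daughter sites — flows from one seeded
`numpy.random.Generator` in a documented order, so every run is
bit-reproducible from its seed. `fixtures.make_fixture` additionally
provides hand-placed deterministic configurations (two separated
blocks, a diagonal pair, 3- and 4-agent clusters, a fully enclosed
agent, a mixed melanoma/skin neighbourhood) used to pin the
neighbourhood, filter and labelling conventions.

What the generator does **not** emulate: donor-to-donor variability,
the keratinocyte/fibroblast distinction, cell size heterogeneity,
off-lattice positions, and the optical properties of stained tissue
photographs. Passing tests therefore validate the stochastic model and
its quantification pipeline, not the image-analysis chain used on real
tissue.

## Nest quantification

A nest is a connected component of melanoma agents. Components are
found with `scipy.ndimage.label` (default 26-connectivity, mirroring
the adhesion neighbourhood; 6 available) plus a union–find merge across
the periodic lateral seam, which `ndimage` does not handle natively.
Clusters of fewer than `min_agents = 4` agents are excluded as
unobservably small. Area is `n_agents · Δ²` (400 μm² per agent); a
`projected` convention (distinct occupied columns × Δ²,
the top-down footprint of a photograph) is available. Summaries are
boxplot-style: linearly interpolated quartiles, 1.5·IQR fences,
whiskers at the most extreme observations inside the fences. Labelling
is deterministic and permutation-invariant, and is property-tested
against a brute-force flood fill. Centroids of seam-spanning nests are
naive index means (not wrap-corrected).

`split_touching_nests` offers a second, image-like quantification: the
melanoma *height map* (agents stacked per column — the darkness of a
top-down rendering) is segmented by watershed from local maxima at
least 3 columns (60 μm) apart, chosen below the ~100 μm scale of
observed nests; each occupied column joins one basin and a basin's size
is its total agent count. This is a deterministic automation of the
manual step common in image-based nest measurement, where touching
nests are separated by eye before region areas are read off. It does
not wrap laterally (a photographed field of view does not either).

## Scenario experiments

Four named conditions: `baseline`; `no_melanoma_proliferation`
(P_p^(m) = 0, the in-silico analogue of gamma-irradiated melanoma
cells); `half_proliferation` (P_p^(m) = 0.0002); `half_adhesion`
(q = 0.35). Replicate batteries default to five seeds per condition on
a 75 × 75 × 60 lattice with initial counts scaled by lateral area so
the surface density equals the full 150 × 150 × 100 reference; local
dynamics depend only on density, and this quarter-area window keeps a
full battery within minutes on one CPU. Conditions are compared by the
ratio of pooled median nest areas with a seeded percentile bootstrap.

## Known limitations

- **Percolation defeats component-based medians at high seeding
  density.** At the 2706-agent-equivalent density (12% initial surface
  coverage), four days of growth produce one connected cluster holding
  ~95% of melanoma mass (under 6- or 26-connectivity alike, so this is
  face-to-face contact, not a diagonal artifact). The component-size
  median then reflects the residual dust, and condition comparisons
  invert: the acceptance battery measures baseline/half-proliferation
  median fold ≈ 0.2 and baseline/half-adhesion ≈ 1.5, where mound-scale
  intuition (and image-based measurements that separate touching nests)
  would put both near 10. The watershed quantification, run on the same
  states by `scripts/acceptance.py`, restores mound-scale behaviour —
  baseline medians ~45 000 μm², suppressed-proliferation fold ≈ 10,
  half-proliferation fold ≈ 3 — but still cannot reproduce a large
  half-adhesion effect, because halving adhesion *increases* the
  melanoma count (~50% more agents escape crowding-aborted
  proliferation) while dispersing it; only a measurement that discounts
  dispersed, low-density agents (as thresholded photographs of stained
  tissue do) can register that as "smaller nests". Both quantifications
  are reported side by side; neither is silently preferred.
- The ≥4-agent filter floors both tails of a comparison, compressing
  median fold changes whenever typical nests are within an order of
  magnitude of the threshold.
- The adhesion modifier is isotropic and pairwise-multiplicative;
  no bond energies, no skin–skin or skin–melanoma adhesion.
- Nests cannot bulge above the seeding surface (k = 0 is no-flux), so
  growth that would be vertical in vivo is redirected laterally,
  promoting merging.
- Single-CPU design; a full-geometry four-day baseline run takes a few
  minutes, and replicates are embarrassingly parallel at the process
  level.
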