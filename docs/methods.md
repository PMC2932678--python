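# Methods

## Model overview

`callussim` implements a bioregulatory (mechanics-free) continuum model
of secondary fracture healing.  Twelve non-dimensional fields —
mesenchymal stem cells (MSC) `c_m`, fibroblasts `c_f`, chondrocytes
`c_c`, osteoblasts `c_b`, endothelial cells `c_v`; fibrous `m_f`,
cartilage `m_c`, bone `m_b` and vascular `m_v` matrix; chondrogenic
`g_c`, osteogenic `g_b` and vascular `g_v` growth-factor families — are
coupled through taxis–diffusion–reaction dynamics.  MSCs, fibroblasts
and endothelial cells migrate (random motility plus chemo-/haptotaxis);
chondrocytes and osteoblasts differentiate in place; matrices and
growth factors do not migrate (growth factors diffuse).

Non-dimensional scales: cell densities against 10^6 cells/ml, matrix
densities against dense tissue (≈0.1 g/ml), growth-factor
concentrations against ≈100 ng/ml; lengths in mm, time in days.  The
carrying capacity is `X = 1`: the total tissue density
`m = m_f + m_c + m_b + m_v` shuts down proliferation and matrix
deposition through the crowding factor `free = (1 − m/X)⁺`.

### Kinetics

With `H(u; K) = u/(K+u)` (a small guard `ε = 1e-9` is added to every
saturation denominator) and `roomᵢ = (1 − cᵢ)⁺`:

* proliferation: `pᵢ cᵢ · cᵢ/(K_allee + cᵢ) · (1 − cᵢ) · free`.  The
  second factor is an Allee-type low-density limitation — trace
  populations lack mutual paracrine support and do not expand on their
  own.  It is what makes the `1e-5` boundary ablation qualitatively
  different from a mere delay: without it, any seeded trace regrows
  exponentially and every "non-union" eventually heals.
* endothelial proliferation and vascular-matrix deposition carry the
  angiogenic drive `β_v + (1−β_v) H(g_v; K_gvv)`: mostly
  stimulus-driven, with a small stimulus-independent background `β_v`
  that produces the slow vascular creep observed without cartilage.
* differentiation (source loss at the full signalled rate, influx into
  the target limited by `room`; the surplus is cleared):
  * MSC → osteoblast: `d_mb (H(g_b;K_gb) + α_bv H(m_v;K_vE)) c_m` — an
    osteogenic growth-factor route plus a vascular-niche route;
  * MSC → chondrocyte: `(d_mc H(g_c;K_gc) + d_mc_av (1 − H(m_v;K_vE))) c_m`
    — a chondrogenic growth-factor route plus a slow avascular default;
  * MSC → fibroblast: constant slow rate `d_mf`;
  * endochondral ossification (chondrocyte → osteoblast):
    `d_cb H(g_b;K_gb) H(m_v;K_vE) c_c` — strictly gated by the vascular
    matrix, exactly zero at `m_v = 0`.
* matrices: each deposited by its cell type at `P_*s c free`; fibrous
  matrix is degraded by invading chondrocytes/osteoblasts
  (`(Q_fc c_c + Q_fb c_b) m_f`) and turned over by the resident cells
  (`d_fm m_f Σc` — cell-gated, so acellular granulation persists);
  cartilage is resorbed during endochondral ossification
  (`Q_cd H(m_v;K_vE) c_b m_c`); vascular matrix deposition is capped at
  the volume fraction vessels can occupy (`mv_max`).
* growth factors: chondrocytes are the only `g_c` source; hypertrophic
  chondrocytes (dense cartilage, `H(m_c;K_hyp)`) produce `g_v`;
  osteoblasts produce `g_b` only in vascularized tissue
  (`H(m_v;K_gbv)`); first-order decay throughout.  Fibroblasts produce
  no vascular growth factor, and there is no de-novo vessel formation
  (angiogenesis only): vascularity can only spread from the endothelial
  boundary supply.

### Migration

Random motility is `D_i Φ(m) h(m_v)` with the crawling factor
`Φ(m) = 2 K_hm m/(K_hm² + m²) · 1/(1 + (m/K_dense)⁴)` — zero without a
substrate, maximal in loose granulation tissue (`m ≈ 0.1`), and nearly
arrested in mature fibrous matrix (`m ≳ 0.4`) — and the vascular
hindrance `h = (1 − m_v/X)⁺`.  Taxis velocities are
`Σ_k χ_k ∇a_k · h(m_v)`, modulated by the same `Φ` at the flux level.
The steric arrest is the mechanism behind carrier-delivered cells
differentiating before they reach the callus centre, and it keeps the
double-insult non-union from healing via long-range migration.

## Geometry and scenarios

The domain is a planar quarter-section of the osteotomized tibia
(symmetry at the fracture plane and the marrow axis): periosteal callus
(1.5 mm) above the cortical wall (0.5 mm), the half intercortical gap
(0.5 mm of the 1 mm osteotomy) and the endosteal half-canal (1 mm),
with a default axial callus length of 3 mm.  Only the 1 mm gap is fixed
by the animal model; the remaining outline dimensions are reconstructed
defaults and free configuration parameters.  The non-union variant
extends the domain distally by the stripping/reaming distance (default
4 mm, one tibial diameter): the marrow canal continues and a thin
(0.75 mm) periosteal flank runs along the cortex; the distal end faces
meet undisturbed tissue and keep healing-strength cell sources.

Boundary schedule (healing): MSC Dirichlet (value 1.0, days 0–14) on
the periosteal surface, the endosteal lining and the distal
marrow/periosteal faces; fibroblasts (0.5, days 0–14) on the outer
soft-tissue surface; endothelial supply (0.5, whole run) on the
periosteal and endosteal segments; growth-factor pulses (days 0–7) on
the cortex interface (`g_b`) and periosteal/endosteal surfaces (`g_c`),
at 0.1 × the base estimates — the tenfold reduction applied to both
healing and non-union configurations.  Initial state: granulation
tissue `m_f = 0.1` plus the fracture-induction release `g_c = 1.0`,
`g_b = g_v = 0.1`.  Non-union scenarios multiply the MSC Dirichlet
values on stripped/reamed segments by `1e-5` and change nothing else.

Treatments are `TreatmentEvent`s at POW 3 by default.  Direct
injections book `volume × concentration` cells (1 ml × 10^6 cells/ml)
exactly in a dimensional ledger, convert them to areal density through
a reference section thickness (5 mm, config-exposed) over a disc
footprint (default radius 0.25 mm), and cap the resulting MSC density
at the carrying density — the excess is reported as ledger overflow
rather than forced into the field, since 1 ml is far larger than the
callus itself.  Placements: central = mid-gap; excentral = displaced to
the periosteal side of the gap, adjacent to the cortex end (no
canonical coordinates exist; both placements are configuration options
logged with every run).  Carrier delivery is a 7-day Dirichlet source (value 1.0) on
the outer soft-tissue segment.

## Numerics

Space: cell-centered finite volumes on a uniform rasterized grid
(staircase boundaries; default `dx = 0.25 mm`).  Diffusion uses central
differences with arithmetically face-averaged coefficients; taxis uses
MUSCL upwinding with the van Leer limiter (first-order fallback at
boundary-adjacent faces), which keeps advected profiles free of new
extrema.  Dirichlet values are imposed through ghost values at the
face, so all fluxes remain conservative; with closed boundaries and no
reactions, species mass is conserved to rounding error.

Time: SciPy's variable-order BDF on the flattened in-domain unknowns
(`rtol 1e-6`, `atol 1e-9` non-dimensional by default) with a
nearest-neighbour all-field Jacobian sparsity pattern.  Integration
restarts at every boundary-window edge, snapshot and treatment time, so
the right-hand side is time-smooth within each interval and runs are
bitwise reproducible.  Reaction and transport coefficients are
evaluated on the state clipped at zero; snapshot values in
`(−1e-10, 0)` are clamped to zero and counted in the solver log, values
below that tolerance are logged as positivity violations (none occur in
the verification or scenario suites).  The verification battery
establishes second-order convergence against the analytic heat kernel,
closed-box mass conservation below `1e-10` relative per week, and
agreement of the zero-dimensional proliferation limit with the implicit
closed form `F(c) − F(c₀) = p t`, `F(c) = (K+1) ln(c/(1−c)) − K/c`, to
better than `1e-6` relative.

Default problem sizes: 124 cells (healing) / 236 cells (non-union
variant) at `dx = 0.25 mm`, 112 simulated days with weekly snapshots —
chosen so a full scenario integrates in a few seconds and the complete
experiment battery in minutes; `dx = 0.1 mm` runs (≈1900 cells) are
available through the configuration for finer spatial readouts.

## Parameter provenance and calibration

The original supplementary parameter table for this model family is
not distributed with the package, so every rate constant in
`default_parameters()` is a reconstruction, marked
`source="reconstructed"` in the registry.  Magnitudes were chosen at
literature-plausible scales (cell motility 0.1–0.35 mm²/day, GF
diffusion 0.3 mm²/day, proliferation 0.15–1.0 /day, GF decay 0.5 /day)
and then calibrated, as a package-level design step, against the
published qualitative phenomenology of the healing and non-union
experiments: cartilage peaking in the first weeks and replaced by bone
by week 8; fibrous dominance with only small amounts of bone and
cartilage in the double-insult non-union; delayed but complete healing
under either single insult; the five-week vascularization lag; the
proliferation-index crossover; slower ossification at `P_cs, P_bs / 10`;
and the three transplant responses.  The acceptance suite asserts
exactly these orderings and trends — not absolute bar heights, which no
published record fixes.  Users substituting their own parameter values
can audit every symbol via `callus-sim params dump`.

## Known limitations

* Bone remodelling, vasculogenesis, cortical-bone changes (bone-end
  rounding, marrow-canal capping) and time-varying callus size are
  outside the model's scope; mechanical loading is not represented
  (the bioregulatory variant assumes adequate stabilization).
* Osteoblasts never mature into osteocytes, so the osteogenic
  growth-factor level plateaus instead of declining after week 3.
* The vascularized-tissue percentage needs a cutoff that the continuum
  representation does not define; the convention here (half the healing
  run's end-state median `m_v`, area-counted) is config-exposed, and no
  claim of canonicity is made.  Whether tissue fractions should be
  normalized by `X` or by the instantaneous total matrix is likewise a
  convention; normalization by `X` is used so that the non-union's
  lower fibrous density remains visible.
* The quarter-section symmetry folds the two cortices of a real
  cross-section onto one; "excentral" injection and its contralateral
  readout are therefore interpreted within one section half
  (periosteal-side injection, endosteal-side lag), at a smaller
  separation than in the animal.
* The kinetic functional forms are reconstructed (see above): absolute
  time courses carry that uncertainty, and conclusions should rest on
  the comparative orderings the test suite pins down, not on absolute
  fraction values.
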