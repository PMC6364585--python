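# Methods

## Model

Each cell is a cloud of point elements moving by overdamped Langevin
dynamics, `gamma dx/dt = F + zeta`, integrated with an explicit
Euler–Maruyama step.  Reduced units fix the drag `gamma = 1` and the Morse
equilibrium separation `re = 1`; all forces (cortical tension `gamma_m`,
adhesion `A_M`) are quoted in these units.

Same-cell element pairs interact through a Morse potential
`V(r) = De (e^{-2a(r-re)} - 2 e^{-a(r-re)} + 1)`, shift-truncated at
2.5 `re`.  The repulsive branch (well depth `De_intra`) sets the element
packing stiffness and the attractive branch (`De_cohesion`) the bulk
cohesion; the two are independently tunable because bulk cohesion acts
as a residual, `beta`-insensitive surface tension on every cell surface
and so competes with the differential-tension signal the model exists
to study.  The default keeps them equal: regime scans showed that
cutting cohesion below the packing scale destabilises cells at low
cortical tension faster than it sharpens the interfacial response.

Pairs in different cells always feel the repulsive branch only (cells
exclude each other without sticking).  Cortex–cortex pairs in different
cells additionally feel the attractive branch of an adhesive Morse
interaction whose well depth follows from the analytic
maximum-attractive-force relation `De_adh = 2 A_M / a_adh`, so the
printed adhesion magnitude `A_M` is exactly the peak attractive force of
one pair.  The adhesive well is deliberately narrow (`a_adh` large): the
interfacial energy per unit area scales like `rho * n * De_adh \propto
A_M / a_adh`, and only a small interfacial binding energy keeps the
adhesion-driven contact patch of a tension-symmetric doublet small while
the peak force stays at `A_M`.

### Cortex

Each cell is divided into 32 equal-solid-angle sectors about its centre
of mass (two polar caps and rings of 6, 9, 9, 6 sectors); every element
whose radius reaches 80% of its sector's maximum radius is cortex, the
rest cytoplasm.  Allocation is recomputed every step (configurable
stride), so escaping cytoplasm becomes cortex and is pulled back.

The cortical surface is triangulated by projecting the cortex elements
radially onto a unit sphere about the centre of mass and taking the
convex hull of the projections (a spherical Delaunay construction valid
for star-shaped clouds).  A plain convex hull of the raw positions looks
equivalent but fails in exactly the situation that matters: the flattened,
slightly concave contact face of an adhering cell falls inside the hull
and its elements silently lose their tension edges.  The projected
construction keeps every cortex element a vertex of a closed surface
(V − E + F = 2, every edge on two facets).

Cortex elements sharing a triangulation edge pull on one another with a
constant-magnitude force `gamma_m` (an actomyosin-like contractility that
does not depend on separation).  Cortex elements holding an adhesive
contact with another cell are labelled by the partner cell's relative
type; an edge whose two endpoints share a label is interfacial and its
tension is scaled by the corresponding factor of the symmetric 2×2
`beta` matrix (ties at triple contacts resolve toward the smaller beta).
Scalar `beta` in the configuration means the type-1/type-1 factor, with
all other factors 1, which is the convention used for the sorting phase
diagrams.

Adhesion is normalised by local element density: each mesh vertex owns
one third of its incident facet areas, and its adhesive forces are scaled
by that share divided by the cell mean, so adhesion per unit area is
independent of local element crowding.

### Contact gates: force, labelling, measurement

At desk scale a cell is only a few `re` across, so one interaction
radius cannot serve the three distinct roles adhesive "contact" plays.
The package separates them explicitly:

- **Force**: the adhesive Morse branch acts out to its own cutoff.
- **Labelling** (which elements count as interfacial for tension
  scaling): moderately local in distance, permissive in angle (partner
  anywhere in the front hemisphere of the element's outward normal), so
  the contact rim can recruit new elements and the interface can grow.
- **Measurement** (which contacts count toward interface area): close to
  the equilibrium sheet gap and facing (partner near the outward
  normal), so elements just outside the rim — nearly coplanar with the
  contact line — do not inflate the measured area.

Elements whose pairwise `A_M` is zero share no adhesive interaction and
are never labelled or measured as interfacial; a doublet with zero
adhesion therefore reports a zero interface even while the cells touch.

### Interface area estimator

The cell–cell interface area is measured on the triangulated surface:
each facet contributes its area times the fraction (0, 1/3, 2/3, 1) of
its vertices currently in facing adhesive contact.  The interface
proportion `I_P` is the summed interfacial area of both cells over their
summed total surface area.  The estimator was calibrated on synthetic
truncated-sphere doublets posed at known contact angles (where the true
value is `(1-beta)/(3-beta)` by construction): the vertex-weighted form
tracks the analytic value to within ~0.03 across the full range of
contact angles, whereas the all-or-nothing facet rule (counting only
facets with all three vertices in contact) loses most of a rim ring and
under-reads deep interfaces by up to a factor of two at these element
counts.

### Noise

`zeta` is i.i.d. Gaussian per component with standard deviation
`noise_amplitude`.  The amplitude is not a cosmetic jitter: the
effective temperature of the discretised dynamics is
`kT = noise_amplitude^2 dt / 2`, and contact-line motion proceeds by
single-element detachment events with barriers of order the adhesive
bond energy.  With near-zero noise every doublet stays pinned in its
post-division contact and the interfacial tension factor has no visible
effect; the default amplitude is chosen so those barriers are crossable
within a relaxation run while all structural energies (bulk bonds,
cortical tension work per edge) remain several times `kT`.

## Experiments

### Doublets

A doublet is made the way the growth model makes them: one relaxed cell
of twice the per-cell element count divides through a random plane and
the two daughters relax without growth.  Relaxation runs in windows,
sampling `I_P` every few steps; it stops when the windowed mean changes
by less than 1% (with a small absolute floor) between windows, and the
reported value is the final-window mean.  Zero adhesion legitimately
yields separated cells and `I_P = 0`.

The analytic benchmark is the linear force balance model of the doublet
contact vertex: `beta = cos(theta/2)` and `I_P = (1-beta)/(3-beta)`,
exact in the high-tension limit where adhesion is negligible.

### Growth and sorting

Aggregates grow from 10 to 30 cells.  Cells insert cytoplasm elements
near their centre of mass at per-step probability `n ln2 dt / tau_C`
(element count doubles over one cycle time) and divide through a
uniformly random plane on reaching their target element count; under
asymmetric division each event has a 50% chance of producing two
parent-type daughters and 50% of one daughter of each type.  The
founder aggregate is grown from a single cell under neutral mechanics
(`beta = 1`), and the two types are assigned at random (default 1:1) at
the 10-cell stage.

Sorting is quantified by the radius, neighbour and surface measures and
their permutation-null indices `S = orientation (X - E(X)) / (3 sigma)`.
The radius measure carries orientation −1 (a sorted aggregate has a
*small* type-1 radius), the other two +1, which makes "near 1 = sorted"
hold for all three.  The null reassigns type labels uniformly at random
with fixed counts; the production default is 10^4 reassignments and the
test preset 10^3.  On a 30-cell aggregate the null of each measure is
approximately Gaussian (|skew| < 0.15, |excess kurtosis| < 0.4), though
an omnibus normality test at 10^4 samples can still resolve the slight
platykurtosis of the finite label population.

## Parameter defaults

(reduced units; see `scemsort.runio.make_model_params`)

| parameter | default | meaning |
|---|---|---|
| `De_intra` | 0.05 | repulsive-branch well depth (packing stiffness) |
| `De_cohesion` | 0.05 | attractive-branch well depth (bulk cohesion) |
| `a` | 4.0 | bulk inverse range |
| `cutoff` | 2.5 | bulk truncation |
| `a_adh` | 14.0 | adhesive inverse range (cutoff 1.6) |
| `dt` | 0.01 | Euler–Maruyama step |
| `noise_amplitude` | 1.0 | Gaussian force noise, per component |
| labelling gate | r ≤ 1.6, facing cos > 0 | interfacial-tension labels |
| measurement gate | r ≤ 1.2, facing cos > 0.2 | interface-area contacts |
| elements/cell | 32 (aggregates), 64 (doublets), 128 (production) | resolution |
| `tau_C` | 40 | cell-cycle time |
| shuffles | 10^3 (test), 10^4 (production) | permutation null size |

The bulk and adhesive shapes were fixed by requiring one parameter set
to reproduce three regimes at once: doublet interfaces that track the
force-balance prediction at high tension, an interface that saturates
near the two-hemisphere limit at low tension and high adhesion, and a
small contact patch when the two cells' tensions are symmetric.  The
last requirement binds hardest: a tension-symmetric doublet keeps a
metastable adhesion patch (interface proportion ~0.1 at these element
counts) that no accessible noise level removes, so the measured
high-tension offset grows toward small `1 - beta` rather than staying
constant.  Doublet experiments therefore run at 64 elements per cell --
at 32-40 elements the rim discretisation flattens the beta response
altogether -- while growth runs keep 32-element cells for speed.

## Scale and what desk runs show

Test-preset cells carry a few dozen elements, so the interface of a
doublet is resolved by ~5–20 facets and single-element discreteness is
visible in every measured quantity; repeats over seeds are averaged
wherever a number is reported.  Desk-scale runs demonstrate the
mechanisms — interfacial-tension-controlled contact, adhesion thresholds,
permutation-null sorting indices — not converged continuum values; the
production preset sharpens the same quantities but does not change the
code paths.  The synthetic fixture generator used by the sorting tests
emulates packed-sphere aggregates with plausible contact graphs and free
areas, not the mechanics of deformable cells; what passing those tests
shows is that the measures and indices are computed correctly, not that
a simulated aggregate would sort.

## Aggregate sorting at desk scale

The sorting machinery (growth, division, measures, null, indices) is
fully exercised by the test suite, but the *magnitude* of
tension-driven sorting at desk scale is limited by the doublet physics
above: the difference in interface proportion between like-type doublets
at `beta = 0.5` and `beta = 1.0` is ~0.05-0.07 here, several times
smaller than at production resolution, and the final sorting index of a
single 30-cell aggregate fluctuates with standard deviation ~0.4 across
seeds.  Repeat studies across cell-cycle times (15-80), resolutions
(32/64 elements) and both division modes show the desk-scale
differential-tension drive sits at or below that noise floor, so
aggregate-level comparisons between mechanical conditions are reported
as means over seeds and should be read as direction checks, not effect
sizes.  Symmetric division is additionally confounded for this purpose:
daughters stay adjacent, so clonal patches mimic sorting against a
label-permutation null regardless of mechanics, which is why the
sorting comparisons use asymmetric division (as the phase-diagram
protocol does).

## Known limitations

- Convexity: the spherical-projection surface assumes star-shaped cells;
  strongly non-convex shapes (late engulfment) are outside the model.
- The 32-sector cortex rule is resolution-limited: sectors that straddle
  a contact line can briefly misallocate rim elements.
- The interface estimator's rim bias, though calibrated, remains the
  dominant systematic at test scale (~±0.03 on `I_P`).
- No hydrodynamics, inertia, cell–substrate mechanics, apoptosis, or
  mechanics-dependent division timing.
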