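# Methods

`osteosim` simulates regeneration of a plate-stabilized 3-mm mid-diaphyseal
femoral defect in the rat over twelve weeks, in a healthy and a
type-2-diabetic (T2DM) parameter regime, by coupling a quasi-static finite
element (FE) model of the callus mechanics with an agent-based model (ABM) of
the cell populations, once per simulated day.  This note documents the model,
its assumptions, the parameters that matter, and what the package's synthetic
study conditions do and do not establish about real healing.

## Model overview

Each simulated day:

1. the axial compression and bending moment for that day are interpolated
   linearly between the printed initial and final loads of the group (healthy
   17.42→24.07 N and 31.07→42.93 N mm; diabetic 21.60→24.89 N and
   38.52→44.40 N mm over 84 days), reflecting body-weight growth;
2. every element's isotropic stiffness is assembled by a volume-fraction rule
   of mixtures over its tissue content, averaged over the last ten coupling
   iterations to represent the lag of matrix maturation behind cellular
   activity;
3. the small-strain elastic equilibrium is solved and each element's
   octahedral shear strain becomes the mechanoregulation stimulus at the cell
   lattice sites it contains;
4. the cellular processes run (migration, mechano-regulated differentiation,
   proliferation, apoptosis, osteoblast embedding);
5. fibroblasts, chondrocytes and osteoblasts deposit fibrous matrix,
   cartilage and woven bone in their elements, closing the loop.

The primary outcome is BV/TV: the volume fraction of the intercortical
footprint (the annulus between endosteal and periosteal radii extended across
the gap) occupied by elements whose mineralized fraction reaches 0.5, after
84 days.  Bridging is a 6-connected path of bone-classified elements joining
the two cortical ends within one hemi-callus.

## Geometry and discretization

The femur is an idealized hollow cortical cylinder (30 mm) filled with
marrow; the defect is transverse at mid-height; the callus is an elliptic
bulge (outer radius 3.2 mm, axial half-extent 4.6 mm).  Femur radii are not
part of the published parameter set; the package ships a nominal fixture
(periosteal radius 2.0 mm; endosteal radius 1.30 mm healthy / 1.315 mm
diabetic).  The diabetic cortical deficit is therefore carried mostly by the
printed lower cortical modulus (6610 vs 8660 MPa) and the heavier loads
rather than by geometric thinning.

The plate (titanium, E = 110 GPa, 1.6 × 2.0 mm section, spanning z = 10–20
mm laterally) rests on a 0.2-mm soft interposition layer and is anchored by
four screw patches.  Screws are homogenized into columns with an effective
modulus of 2.5 GPa, which lumps the bending and shear compliance of slender
screw shafts into a solid block; this constant sets the translational
(axial-closure) compliance of the construct and was chosen, together with the
plate section, so the day-0 intercortical strain averages reproduce the
reported values (see Calibration).

The mesh is a tensor-product voxel grid of trilinear hexahedra whose axial
planes are aligned with every feature boundary; curved in-plane boundaries
enter each element as sub-sampled material area fractions.  Elements
containing plate metal are layered composites and blend in series (Reuss), so
the thin compliant contact layer is not averaged away; all other constituents
blend in parallel (Voigt).  The cell lattice covers the healing domain
(callus + gap + medullary region near the defect) and maps every site to its
element.  Two resolution presets are used throughout: *desk* (mesh scale 4,
i.e. 0.8 mm callus voxels, 100 µm lattice, ≈ 30 s per 84-day run) and *micro*
(scale 6, 150 µm, ≈ 6 s), with the full-fidelity configuration (0.2 mm /
10 µm) available but not exercised by the tests.

## Cellular processes

Five phenotypes occupy lattice sites exclusively: MSCs, fibroblasts,
chondrocytes, immature and mature osteoblasts.  30 % of the periosteal and
marrow-side surface sites are seeded with MSCs post-surgery (19.5 % in the
diabetic model).  MSCs and fibroblasts random-walk (hourly sub-steps,
uniformly chosen free neighbors, random conflict resolution); cells divide
with probability rate × dt into a free neighbor (contact inhibition
otherwise); each phenotype dies with its apoptosis probability.  Rates
convert to probabilities as p = rate × dt, sub-divided only when p would
exceed 1; this preserves the daily branching mean exactly (a population with
division rate r grows by 1 + r dt per day while space lasts).

MSC differentiation is mechano-regulated.  The stimulus windows (octahedral
shear strain) are: quiescent below 0.1075 %, osteogenic to 0.35 %,
chondrogenic to 1.05 %, fibrous above.  The diabetic set keeps the same
window frame but adds a lazy zone (no differentiation) at 0.1275–0.1875 %,
moving the effective onset of mechano-driven differentiation to higher
stimulus levels, as reported for diabetic mechanosensitivity.  Because only
the window *edges* differ while both groups' gap strains lie comfortably
inside the osteogenic/chondrogenic range, the simulated outcomes are nearly
insensitive to the mechanosensitivity factor — consistent with its null
effect in the published screening.

**Osteoblast embedding.**  Immature osteoblasts mature with rate 0.4/day
(mean active period 2.5 days).  Mature osteoblasts are treated as
matrix-embedded, osteocyte-like cells: they continue to deposit bone but no
longer divide or undergo the apoptosis process; the tabulated osteoblast
proliferation and apoptosis rates drive the immature (active) pool.  This
choice is forced by the parameter set itself: applying the diabetic apoptosis
rate (0.24/day) to all osteoblasts makes every osteoblast lineage net-dying
(proliferation 0.15/day), and no amount of matrix production yields the
observed diabetic bone volume.  Embedding is also the standard fate of
matrix-producing osteoblasts in this model family.

Matrix production converts 0.10 element-volume fractions per day per resident
producing cell at full occupancy (an osteoblast-saturated element ossifies in
ten days), consuming granulation tissue first, then softer formed tissues.
Immature bone matures to mature bone with the same 0.4/day constant used for
cell embedding.

Plate-surface guidance multiplies all rates by 1.10 within 30 µm of the plate
surface in the healthy model and restores the full healthy rate set there in
the diabetic model.  On lattices too coarse to resolve 30 µm the zone is the
first resolvable layer of tissue sites along the plate–bone interface.

## Calibration and what is free

All sixteen cellular rates, the tissue elastic table, the loads, the seeding
densities, the ten-iteration smoothing and the 84-day horizon are fixed
inputs.  Four constants are genuinely free (unpublished) and were calibrated
once against the reported study-level outcomes, then frozen: the matrix
production rate (0.10/day), the embedding rate (0.4/day), the quiescent bound
(0.1075 % shear) and the diabetic lazy zone (0.1275–0.1875 %).  The fixture's
plate/screw constants were likewise calibrated against the day-0 strain
averages.  At the frozen values the desk-scale model yields (five-seed
means): healthy 67, diabetic 20, diabetic + guidance 31 BV/TV %, healthy +
guidance within one point of healthy, and diabetic geometry with healthy
rates within the healthy seed spread — reproducing the reported pattern
(60 / 27 / 32, guidance inert in healthy, mechanostructural alterations
non-explanatory) within the stochastic tolerance of the coarse preset.

Two structural lessons from the calibration are worth recording.  First, the
diabetic MSC balance (0.21 proliferation − 0.0835 apoptosis − 0.15
differentiation drain) is negative wherever differentiation is active, so a
protected low-stimulus reservoir (quiescent + lazy zone) is *required* for
the diabetic model to heal at all.  Second, the healthy and diabetic
endpoints cannot be tuned independently: the quiescent bound couples them
(diabetic window bounds must not drop below healthy ones), which leaves the
healthy endpoint a few points above the reported 60 % at the chosen operating
point.

## Numerical choices

* Linear elastic quasi-static solve (sparse LU) replaces a poroelastic
  formulation; permeability and bulk moduli are carried as data for a
  biphasic stimulus extension.  The decision variable is a strain-derived
  stimulus at daily granularity, for which the elastic constants dominate.
* Loads are applied as area-weighted nodal forces on the proximal face
  (distal face fixed); the end moment is oriented to oppose the rotation
  induced by the plate-offset eccentricity of the axial load, leaving the
  medial side with the larger net compression, as observed.
* Update order within a day: migration → differentiation → proliferation →
  apoptosis → embedding.  All updates are simultaneous vectorized moves with
  random tie-breaking, which removes directional bias without per-cell
  ordering.
* Composition vectors are renormalized to the simplex after production;
  Poisson ratios blend linearly and clamp below 0.5; permeability blends
  log-linearly (it spans four orders of magnitude).
* Bone classification threshold 0.5 (element mineralized fraction) for both
  BV/TV and bridging.  Raising it to 0.6 lowers desk-scale BV/TV by roughly
  five points across scenarios; the ordering of the groups is unaffected.

## Known limitations

* **Resolution sensitivity.**  The voxelized cortex ring and the thin
  plate–bone contact layer re-voxelize across mesh scales, so full-model
  strain averages are tied to the desk mesh scale used for calibration (the
  homogeneous-configuration solver itself converges; see the test suite).
  The desk lattice (100 µm) also makes migration effectively faster per
  unit time than a 10 µm lattice at equal µm/h rates.
* **Race-sensitive endpoints.**  Healing endpoints emerge from a race between
  ossification and strain-shielding shutdown; they respond non-monotonically
  to some parameters (e.g. faster early bone can *reduce* the final diabetic
  BV/TV by shielding the gap sooner).  Seed-to-seed spread at desk scale is
  ±4–5 BV/TV points; reported values are means over ≥ 3 seeds.
* No angiogenesis, inflammation, adipogenesis, glycation, or resorption /
  remodeling of formed bone; the diabetic condition is a fixed parameter set,
  not a dose–response model.
* The synthetic geometry is idealized (cylinder + elliptic callus); real
  cross-sections, screw threads, and contact mechanics at the plate interface
  are not represented.  Passing tests therefore show that the *mechanisms*
  (cell-kinetic impairment dominating over mechanostructural alteration)
  reproduce the reported pattern under idealized conditions — not that the
  model predicts individual animals.
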