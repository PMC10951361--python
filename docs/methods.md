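# Methods

`marrowsim` is a hybrid cellular automaton (HCA) of a trabecular bone-marrow
cross-section: discrete cell agents on a single-occupancy square lattice,
coupled to continuous cytokine fields solved by explicit finite differences,
with a continuous per-site bone-density field in between. This note records
the model, its assumptions, the calibrated parameters, and what the synthetic
study conditions do and do not show.

## Lattice and bone matrix

The domain is a 160 x 150 grid of 10 um sites (1600 x 1500 um^2), periodic on
all sides for both agents and fields. Bone is a per-site mineral density in
[0, 1]; marrow is density 0. Trabecular geometry is procedural: the zero
level-set ridges of a Gaussian-smoothed noise field (strut thickness ~50 um),
confined to the grid center and thresholded to exactly the target area
fraction, 12.9% BA/TA by default (the healthy murine trabecular value the
model is anchored to). A bone mask can be supplied instead, e.g. for test
fixtures. Quiescent bone-lining cells populate every marrow-facing bone
site.

Single occupancy is enforced for all agents; divisions require a free
neighboring marrow site and are deferred under crowding. Distances are
Euclidean between site centers, inclusive at the boundary, with periodic
wrap; the interaction radii (20, 40, 80 um) translate to disks of 13, 49,
and 197 sites.

## Cytokine fields

RANKL (`R_L`) and a bone-derived factor (`T_beta`, TGF-beta as the
representative BDF) obey reaction-diffusion equations

    du/dt = D lap(u) + production - delta u,

integrated with forward-time centered-space (FTCS) stepping and periodic
boundaries; the PDE sub-steps the half-day agent step 4x so the stability
bound `D dt / h^2 <= 1/4` holds (D = 180 um^2/day, dt_pde = 0.125 day;
these are effective grid-scale diffusivities, as usual for explicit
on-lattice solvers). Negative excursions are clipped at zero and counted;
under the default parameterization no clips occur.

Production terms:

- RANKL: alpha_R = 10 conc/day per RANKL-expressing lining cell (only the
  <= 5 cells activated by a remodeling event; expression stops at osteoclast
  fusion or after a 30-day activation window).
- BDF: a basal term alpha_B = 0.0075 conc/day everywhere (homeostatic
  background T* = alpha_B/delta_T = 0.05) plus release tied to active
  resorption, alpha_T = 8 concentration units per unit bone density
  resorbed. The alternative reading of the release term (release
  proportional to standing bone content next to an osteoclast) is available
  behind `FieldParams.bdf_release_mode = "bone_content"`; the default ties
  release to the density actually removed, which makes released BDF exactly
  bookkeepable against resorbed bone.

Decay rates are delta_R = 0.05/day and delta_T = 0.15/day. All BDF
thresholds below are calibrated against the resulting homeostatic plume: a
resorbing osteoclast raises local BDF to a peak of ~1.5-1.9 over the 0.05
baseline, decaying within ~2 weeks of osteoclast death.

## The remodeling cycle (BMU)

Initiation. Remodeling events are scheduled uniformly in time at the
turnover calibration: expected events x (resorption rate x osteoclast
lifespan) = initial bone pool over four years, i.e. the pool turns over in
~4 y. Because a fraction of initiations never assembles enough precursors
(and osteoclast activity is BDF-modulated, below), the engine divides the
closed-form rate by a measured delivery efficiency of 0.55 so that *realized*
turnover matches the calibration. An event activates up to five contiguous
lining cells (RANKL on) and recruits 10 preosteoclasts into the surrounding
marrow within 150 um. Recruitment is local rather than domain-wide: with
grid-stable diffusivities the RANKL gradient cannot span the domain on BMU
timescales, so domain-wide spawning would starve events of precursors.
No event initiates within 80 um of an active event.

Fusion. Preosteoclasts chemotax up the RANKL gradient (steepest ascent,
24 sites/day, random tie-break). When at least five precursors lie within a
40 um cluster near an initiation-phase event, the cluster fuses with
probability 0.5 per step into one osteoclast placed on a bone-abutting
member (one osteoclast per event). Local RANKL must exceed 1.0 conc.

Resorption. The osteoclast removes bone from the adjacent site of highest
density, preferring the site it has already started and surface (perimeter)
bone, so the cavity is a marrow-accessible, full-depth trench; it advances
into excavated sites. Per-osteoclast activity is a saturating function of
local BDF with a floor, rate = 1.0 density/day x (0.15 + 0.85 T/(0.35+T)) --
the resorption arm of the tumor-bone vicious cycle, and the mechanism behind
the biphasic response to BDF depletion (below). Resorption stops at the
14-day lifespan or when the lifetime budget (14 density units) is spent.
Lining cells retract as soon as their site is touched.

Coupling to formation. At fusion, one MSC is placed within 40 um of the
osteoclast (guarded: at most one MSC per neighborhood). MSCs chemotax
slowly up the BDF gradient and divide asymmetrically into preosteoblasts at
up to 1.8/day while local BDF exceeds a floor of 0.06, from a progenitor
pool capped at 16 divisions. Preosteoblasts proliferate (0.02/day) while
BDF is above 0.15, and otherwise differentiate onto an adjacent resorbed
site -- but not next to a living osteoclast (reversal follows resorption)
and not within 80 um of a myeloma cell. The osteoblast inherits lifespan =
90 days x resorbed depth of its site and a formation budget equal to that
depth, deposited at budget/lifespan per day; so a fully excavated site takes
~3 months to rebuild, and formation equals resorption per completed event up
to explicit loss terms (preosteoblast attrition at 0.02/day while waiting).
Idle preosteoblasts home toward the nearest cavity (distance-transform cue).
On completing its site an osteoblast is buried with probability 0.05
(transferring any unbuilt budget to the nearest surviving osteoblast, or
parking it for the next differentiation), otherwise it becomes a quiescent
lining cell or is removed (50/50).

Under these defaults a tumor-free world holds BA/TA within about -10% of
0.129 over four simulated years while remodeling >50% of the initial bone
sites, with coupling |formed - resorbed| of a few percent per completed
event.

### Biphasic response to BDF depletion

Scaling both BDF production terms by `tgfb_scale` reproduces the biphasic
bone response: a moderate reduction (x0.5) *raises* final BA/TA because
osteoclast activity (BDF-stimulated) falls more than formation -- supply of
preosteoblasts is kept scale-independent by the saturating MSC response and
the capped progenitor pool, while reversal shortens. A strong reduction
(x0.05) collapses the plume below the MSC floor, abrogating preosteoblast
supply entirely: resorption continues at the activity floor with no
formation, and bone is lost steadily. The ordering BA/TA(0.5) > BA/TA(1.0)
> BA/TA(0.05) is stable across seeds at matched event schedules.

## Myeloma

A single sensitive cell (clone 0) is seeded within 40 um of the first fused
osteoclast. Per half-day step each cell dies, moves, then divides:

- death: step function of local BDF, 0.004/day below the survival threshold
  0.15, 0.002/day above (the survival advantage near resorbing bone);
- movement: 0.1 moves/day, softmax-biased toward higher BDF;
- division: 0.06/day x (1 + 2 T/(0.2+T)), x1.2 within 20 um of an MSC or
  preosteoblast, x cost_factor (0.9) if resistant; contact-inhibited.

Tumor couplings: MSCs are recruited at 5e-4 per MM cell per day, homing to
the tumor (within 100 um of a myeloma cell, preferentially joining an
existing stromal niche) with a 120-day lifespan, so a compact
tumor-associated stromal compartment tracks tumor size, echoing the stroma
seen around residual disease; three or more myeloma cells adjacent to bone trigger a
new remodeling event, waiting only for nearby *resorption* to finish rather
than the (myeloma-blocked) formation phase -- successive waves of
osteolysis; and preosteoblast differentiation is vetoed within 80 um of any
myeloma cell. Untreated runs show sigmoidal takeover of the marrow on a
~1-1.5 year timescale with BA/TA falling steeply (Spearman rho between
burden and BA/TA ~ -1), MSC share of the marrow rising, osteoblasts
collapsing after tumor establishment, preosteoblasts rising then falling,
and osteoclast numbers rising.

## Treatment, EMDR, and resistance evolution

Treatment starts when tumor burden reaches 10% of the current marrow area
and relapse is declared at 20%; continuous and pulsed (2 weeks on / 1 week
off) schedules are supported. Bortezomib kills exposed sensitive cells at
0.35/day x dose, vetoes preosteoclast fusion attempts with probability
0.85, and boosts osteoblast deposition by 30%. Zoledronate scales
per-osteoclast resorption by (1 - 0.7), which also shrinks BDF release and
hence the BDF arm of EMDR.

EMDR: sensitive cells within 20 um of an MSC/preosteoblast or on BDF above
0.5 have their BTZ kill multiplied by 0.01 (near-complete protection, the
minimal mechanism that makes EMDR runs plateau rather than clear). Resistant
cells never receive the BTZ kill term and EMDR is evaluated for sensitive
cells only. With no resistance available (p_omega = 0), high-dose BTZ
eradicates the tumor without EMDR and leaves a stable sub-diagnosis plateau
with EMDR.

Resistance: after treatment has started, each division of a sensitive cell
makes the daughter resistant with probability p_omega (a new clone id and
lineage record per event, tagged with its origin context: near-stroma takes
precedence over BDF-high). Resistance is heritable, irreversible, and
carries a proliferation cost (x0.9), so resistant cells are out-competed by
sensitive cells off treatment (the competition assay reproduces the decline
of a 50% resistant seed; a cost of 1 drifts neutrally).

## Numerical and design choices

- Agent step 0.5 day, fixed operator order (initiations, PDE sub-steps,
  then PRE_OC, OC, MSC, PRE_OB, OB, MM in randomized within-kind order,
  then treatment bookkeeping, then recording). A self-convergence test
  checks that halving the step moves 1-year ensemble BA/TA by <5%.
- Movement speeds are sites/day resolved as micro-moves within a step, so
  per-step probabilities stay small.
- One seed determines everything: world generation, the event schedule, and
  the per-replicate stream are spawned from a single `SeedSequence`.
- Treatment arms that differ only after the trigger (EMDR on/off, p_omega)
  can be forked from a shared pre-treatment trajectory with re-seeded
  streams -- a matched-seed design that removes pre-treatment variance from
  arm contrasts; replicates whose tumor dies before the trigger are
  recorded as failed takes and excluded from treated-cohort statistics.
- Degenerate inputs are rejected loudly (empty bone masks, off-target mask
  fractions, unstable PDE configurations, inverted treatment triggers).

## Study conditions and desk-scale sizes

The acceptance script and test suite regenerate the in-silico cohorts at
sizes chosen for a single CPU: homeostasis and its turnover on the full
160 x 150 grid over 4 years (3-5 replicates); BDF perturbation at scales
{1.0, 0.5, 0.05} on a 120 x 112 grid over 4 years; untreated progression on
a 100 x 94 grid over 500 days; treatment cohorts on the full grid with a
730-day post-treatment censoring horizon and 7-8 treated replicates per arm
(the printed cohorts used n = 125/25 replicates and a longer censor; the
relapse *proportions* are binomial, so smaller n widens their standard
errors accordingly). Percent-style outputs are reported on a 0-100 scale.

## What the generator does not emulate

Two spatial dimensions (no cortical bone, no 3D connectivity), no
vasculature, adiposity, extracellular matrix, or immune compartment; no
pharmacokinetics (dose is a dimensionless kill scale); resistance is a
binary heritable flag acquired only after treatment initiation (no standing
variation, no graded mechanisms); cytokine diffusivities are grid-limited
rather than molecular. Passing tests therefore demonstrate internal
consistency of the model's couplings and reproduction of the qualitative
and cohort-level quantitative behaviors above, not predictions for any
particular patient or mouse.
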