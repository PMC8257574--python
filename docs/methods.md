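# Methods

## Scope and modelling stance

`corflow` studies how outlet-flow boundary conditions shape simulated FFR
and wall shear stress. The boundary-condition estimation (territory
allocation, allometric scaling, Murray splitting, plus the Windkessel and
frame-count comparators) is the scientific core; the hemodynamic solver is a
deliberately reduced 1-D model. A full 3-D Navier–Stokes simulation of a
meshed lumen resolves secondary flows and circumferential WSS variation that
the 1-D model cannot, but it does not change the structure of the mapping
from boundary conditions to trans-lesional pressure ratio, which is what
this package is built to probe at desk scale.

## Geometry and units

Coronary trees are rooted collections of centerline polylines with
per-point lumen radii (mm, world frame). Radii are interpolated linearly
between samples; centerlines can be resampled to a fixed arc-length step.
A stenosis is an arc-length interval with a percent-diameter-reduction
severity; the cosine profile
`r(s) → r(s)·(1 − (sev/100)·w(s))`, `w = ½(1 − cos 2πu)`, is C0-continuous
and peaks mid-lesion, so severity is exactly the midpoint diameter
reduction. Interfaces use mmHg and ml/min; the solver works in SI with
1 mmHg = 133.322 Pa.

## Territory allocation

Each occupied myocardium voxel is labelled with the artery owning the
nearest resampled centerline point (Euclidean distance in mm, default
resampling step 0.5 mm). Distances target the centerline rather than the
lumen surface: at the 1–2.5 mm radius of coronary lumens versus the
centimetre scale of territory geometry, the difference is below the voxel
size, and the centerline is the representation all inputs share. Exact ties
are broken by the fixed precedence LAD < LCx < RCA, making allocation
deterministic. Side branches contribute distance targets under their tree's
main-artery label, since flow is allocated to the three main territories as
wholes. Myocardial mass defaults to occupied volume × 1.05 g/ml (standard
myocardial tissue density); a measured mass on the patient record bypasses
the mask.

The implementation queries one k-d tree per artery and takes the
precedence-respecting argmin across arteries; the test suite checks it
against an exhaustive all-pairs scan.

## Flow estimation

**Territory-based.** `Q_total = a·M^b` with defaults `a = 0.64`,
`b = 0.75` (rest-state calibration of the allometric law); per-artery flow
is `Q_total` times the territory fraction; within a tree, flow splits at
every bifurcation in proportion to daughter radius cubed (exponent
configurable; 7/3 is also seen in the literature). The daughter radius used
is the radius at the child's first centerline point — deterministic and
local to the bifurcation. Where a child attaches at an interior point of
its parent, the parent's continuation competes in the split with its own
local radius; flow is therefore conserved at every node by construction.

**Windkessel-based.** Per-artery hyperemic resistance is the rest
resistance times TCRI (default 0.24, the commonly cited hyperemic/rest
ratio); flow is `(ABP − P_v)/R_h`. Relative allocation is thus inversely
proportional to rest resistance and independent of TCRI. The shipped
default resistances are placeholders in a plausible range — real analyses
must supply their own rest-state values, and every test does.

**Frame-count-based.** Velocity is 3-D vessel length divided by the
contrast transit time `n_frames/fps` (cine acquisition at 15 frames/s);
mass flow is `ρ·v·A`. The 3-D length is an input; correcting 2-D
projection foreshortening by image registration is out of scope.

**Hyperemia.** FFR is defined under maximal hyperemia while the allometric
constants are rest-calibrated. The solver takes an optional hyperemia flow
multiplier (default 1.0, i.e. the allometric estimate unscaled); the
synthetic cohort runner defaults it to 1/TCRI ≈ 4.17, the same rest→
hyperemic conversion the Windkessel route uses, so that cohort FFR values
span the clinical decision range.

## Reduced-order solver

Pressure integrates the Poiseuille gradient `dP/ds = 8μQ/(πr⁴)` along each
branch by the composite trapezoid rule on a grid of default step 0.25 mm
that always includes lesion endpoints, lesion midpoints, the distal
sampling station and child attachment points. At each lesion exit an
irreversible Borda–Carnot loss `K_e(ρ/2)(Q/A_s − Q/A_d)²` is applied as a
pressure jump, with `A_s` the minimum lumen area inside the lesion, `A_d`
the area at the station 5 mm past the lesion end, and `K_e = 1` by default.
A zero-severity lesion is treated as a strict no-op (no narrowing, no
expansion term), so it cannot introduce a spurious loss on a tapered
baseline lumen. Children inherit the parent pressure interpolated at their
attachment. Defaults: μ = 0.003 Pa·s (0.03 poise), ρ = 1060 kg/m³, rigid
walls, steady incompressible flow.

`FFR = P(s_end + 5 mm)/P_a` with `P_a` the tree inlet pressure
(`ABP = SBP/3 + 2·DBP/3`); when a branch ends within 5 mm of the lesion the
pressure is sampled at the branch end and a warning is recorded on the
result. WSS is the Poiseuille wall value `4μQ/(πr³)` — circumferentially
uniform in 1-D, so the circumferential average is the value itself —
and `WSS_prox` is the arc-length mean over the proximal third of the
lesion interval.

Numerical behaviour: for lesion-free, piecewise-constant-radius branches the
trapezoid rule is exact and matches the closed form to machine precision;
with cosine lesions, halving the step from 0.25 mm changes pressures by
well under 0.05 mmHg on the test geometries. At extreme severities
(≳ 93% on typical phantom vessels) the model's pressure drop can exceed the
perfusion pressure and the reported FFR goes below zero; this regime is
outside the index's physiological meaning but preserves monotonicity, so
severity sweeps remain well ordered.

## Synthetic phantom

The LV is a truncated ellipsoid shell (outer 30×30×40 mm, inner
22×22×32 mm semi-axes, basal cut 20 mm above centre, 2 mm voxels), giving
≈ 70–90 g of myocardium — small-adult scale, chosen so the whole pipeline
runs in seconds. Trees grow on a 2%-inflated copy of the outer surface,
each artery in its own azimuthal sector (LAD anterior, LCx lateral, RCA
inferior), which keeps centerlines outside the cavity by construction and
makes territory fractions controllable. Daughter radii at every generated
bifurcation satisfy `r_p³ = r_d1³ + r_d2³` with a split fraction drawn from
(0.35, 0.65); root radius defaults to 1.5 mm, within the 1.5–5 mm diameter
range of real coronaries. One stenosis per artery is placed on the root
branch with severity drawn from (30, 85)% — straddling the FFR = 0.80
crossover, which sits near 82–86% severity under hyperemic flow in this
model — positioned so the +5 mm distal station stays on the same branch.
SBP ∈ (100, 140), DBP ∈ (60, 90) mmHg put the mean aortic pressure in the
low 90s, typical of rest measurements.

The cohort runner pairs each model FFR with a "measured" value equal to the
model FFR plus zero-mean Gaussian noise (SD 0.05, an intermediate scale
between catheter repeatability and reported CT-vs-catheter disagreement),
clipped to (0, 1]. This emulates measurement error only; it is **not** an
independent physical model of the vessel, so cohort agreement statistics
exercise the evaluation machinery rather than validate the solver against
an external truth. What passing cohort tests show is that the pipeline is
deterministic under seed, that severity ordering propagates to FFR and
WSS_prox ordering, and that the evaluation statistics behave; they say
nothing about accuracy on real CCTA anatomy, real lesion morphology, or
inter-modality timing effects.

## Evaluation conventions

Positivity is `FFR ≤ 0.80` (inclusive). Metrics with zero denominators are
reported as undefined, never as zero. ROC AUC uses higher-score-is-more-
positive orientation (rank by `−FFR_s`) with ties counting ½. Bland–Altman
limits are mean ± 1.96 × sample SD (ddof = 1) of `FFR_s − FFR_m`; the paired
comparison is a two-sided paired t-test — an assumption, as agreement
analyses do not always name their test.

## Known limitations

Steady flow, rigid walls, Newtonian rheology; no pulsatility, no
fluid–structure interaction, no cardiac motion. The 1-D WSS is a
circumferential mean and will understate focal WSS at eccentric plaques.
The allometric law is known to bias flow estimates for unusually small
myocardial masses. Territory allocation treats voxels as all-or-none, with
no partial-volume weighting at the mask edge, and assumes homogeneous
per-gram metabolic demand.
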