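# Methods

## The measurement chain

A study is a co-registered CT/SPECT pair per limb (affected and
unaffected), on one voxel grid with millimetre spacing; the proximal end
of the limb sits at index 0 of the limb axis. Resampling between
mismatched grids is out of scope — inputs must arrive co-registered, as
hybrid-scanner exports are.

**Limb segmentation** grows the connected component of voxels above a
soft-tissue HU floor (default −400 HU) from a user- or auto-placed seed;
seeds in air are refused. Optional crop fractions stand in for the
anatomical end landmarks (groin-to-ankle, axilla-to-wrist); phantoms use
the full axis. **Bone** is thresholded at ≥ 150 HU and morphologically
closed; **muscle** is the 20–100 HU window inside the limb, closed,
hole-filled, and cleaned of sub-27-voxel speckle. The **subcutaneous (SC)
compartment is defined, not segmented**: `SC = limb ∧ ¬(bone ∨ muscle)`,
and the mask container enforces that identity exactly. The commercial
workstations used clinically publish none of their thresholds, so all of
these are configuration, validated against phantom ground truth rather
than against any external tool.

**Honeycomb pattern (HP).** Fibrotic/fluid trabeculation inside the SC
fat raises voxels out of the fat range toward water; HP is
operationalized as SC voxels with −60 ≤ HU ≤ 10, both bounds inclusive
(the inclusive reading is asserted by tests; the window is config). The
HP volume ratio is V_HP / V_SC of the affected limb. Regional HP
presence uses a threshold on the regional HP ratio, τ_HP = 0.05 by
default — pure fat plus noise measures ≈ 0.006, genuine trabeculation
starts an order of magnitude higher, so the cut sits in a wide gap.

**CT volumetry.** Volumes are voxel counts × voxel volume (reported in
cm³). The severity grade maps the volumetric difference percent through
half-open bands: Grade 0 < 10, 1 = [10, 20), 2 = [20, 30), 3 = [30, 40),
4 ≥ 40 — every percent has exactly one grade and each printed boundary
(10/20/30/40) belongs to the higher grade. A negative difference
(affected smaller) is clinically anomalous; it grades 0 and warns.

**Dermal backflow (DBF).** The VOI is grown by 3-D iso-contouring: from
each seed, the connected component of voxels at or above
`iso_fraction × (connected maximum)`, iterating threshold and maximum to
a fixed point. `iso_fraction` defaults to 0.10; the clinical tool's value
is unpublished, so it is config and echoed in output. The VOI is
restricted to the SC compartment (dermal backflow is, by definition,
skin-level) and non-dermal hotspots — injection depot, lymph nodes,
ducts — are removed from the growth domain *before* the maximum is
taken, because the depot is orders of magnitude brighter and would
otherwise own the threshold. Auto-seeding takes the brightest SC voxel
per region on a 3³-mean-filtered image (a single hot Poisson voxel
cannot seed), requiring 5× the background, where background is the 25th
percentile of SC activity — a low quantile stays a background estimate
even when DBF occupies most of the SC shell, where the median does not
(this failure mode is real: extensive bilateral-region DBF pushed the
median to rim level). DBF presence per region, and any VOI component,
must reach 1 cm³; smaller hits are noise speckle. Extent is
none/proximal/distal/entire from the per-region presence flags. The
proximal/distal split plane defaults to 0.5 of the limb axis (the
elbow/knee position is never specified in clinical descriptions of the
regions; it is config with landmark override).

## Staging and classification

**TLS rule engine.** The rule table is data, not code. The default:
a limb is in the *partial* obstruction group iff a proximal or
intermediate lymph node is visualized, otherwise *total*; within
partial, DBF extent none/single-region/entire maps to P-1/P-2/P-3;
within total, entire/single-region/none maps to T-4/T-5/T-6. L-0
(normal drainage) requires no DBF **plus** duct visibility **plus both**
node stations — a no-DBF limb with an incomplete node picture stays
P-1, which is the reading seen in practice for mild partial
obstruction. The authoritative stage definitions live in the staging
system's original publication; any divergence is isolated to one
swappable table, and a variant table (e.g. one where any DBF under
total obstruction reads T-4) is a one-liner.

**Staging comparison.** Paired stage calls (planar-only vs
planar+SPECT/CT) cross-tabulate with combined-reading rows ×
planar-reading columns. Contamination-flagged subjects are excluded
from both the table and the modification rate (off-diagonal count /
evaluable N); the off-diagonal is decomposed into within-partial,
within-total, partial→total and total→partial movements. Subjects
conserve: diagonal + off-diagonal + excluded = input count.

**Hybrid classes.** Each region's (DBF, HP) flags form one of four
patterns; the ordered (proximal, distal) pair classifies as: Class 1 —
both regions DBF−/HP−; Class 2 — DBF+/HP− present, no DBF+/HP+ or
DBF−/HP+ anywhere; Class 3 — DBF+/HP+ present, no DBF−/HP+; Class 4 —
DBF+/HP+ and DBF−/HP+ coexist; Class 5 — both regions DBF−/HP+. Twelve
of the 16 ordered pairs are covered; the four mixed pairs without a
DBF+/HP+ anchor ({+−,−+} in either order, and −+ paired with −−) are
not. The default policy refuses them with an explicit error — silently
guessing would fabricate a class. The opt-in `nearest` policy assigns
the class of the closest covered pair by per-region flag (Hamming)
distance, ties resolving to the milder class, and tags the output
imputed; cohort-level analyses use it so a noisy recovery still yields
an ordinal value.

## The phantom

The generator emulates the study conditions the pipeline must survive,
not gamma-camera physics. Geometry: a tapered cylinder (lower-limb
defaults 44 → 28 mm radius over a 192 mm axis at 2 mm isotropic spacing
on a 96³ grid — a scaled-down limb that keeps compartment proportions),
bone and muscle at 0.18 and 0.55 of the local radius. Severity enters
by scaling the outer radius by √(1 + d/100), which inflates exactly the
SC compartment and raises total volume by exactly d percent — as in
disease, where excess volume is subcutaneous.

CT: per-tissue Gaussian HU texture (bone 700±100, muscle 50±10, fat
−100±15, air −1000±20 — conventional radiology values, config-exposed)
plus additive acquisition noise (default sd 5 HU). HP texture is a
Gaussian-smoothed random field (4 mm correlation length) thresholded
per region at the exact quantile that hits the target SC fraction —
connected strands, like real trabeculation, not i.i.d. salt; region
growing and windowing behave differently on connected structure. On a
noiseless image the measured in-window fraction equals the target to
±0.01 by construction; under default noise the window loses slightly
more HP (uniform draws near the window edges diffuse out) than it gains
from fat, so recovered ratios sit ~0.02 low — within the ±0.03 recovery
tolerance the tests assert.

SPECT: tissue background 4, dermal rims at activity 200 painted on the
outer 12 mm of the SC shell in flagged regions over the central 76 % of
the region's axial span (clinical reads treat the regions as clearly
separate; the standoff also keeps PSF smear from crossing the split
plane), node spheres deep to the SC, a thin duct tube in the inner SC,
and an injection depot (activity 3000) at the distal tip. The PSF is an
isotropic Gaussian of 8 mm FWHM — typical LEHR system resolution at
clinical distances — applied before Poisson sampling. Truth DBF masks
are the pre-smoothing rims; exclusion zones are the hotspots enlarged
analytically (12 mm; 15 mm for the depot) to cover their smear.

Cohorts couple everything to the hybrid class: per-class DBF/HP
layouts (Class 1: nothing; 2: one-region DBF; 3: DBF+HP both regions;
4: one region DBF+HP, the other HP only; 5: HP only, both regions),
volumetric-difference draws from per-class uniform bands (1: 1–8 %,
2: 5–14, 3: 12–26, 4: 24–42, 5: 30–48 — monotone with overlap; Class 1
stays below the Grade-1 edge by construction), duration bands rising
with class, and node/duct visibility making the truth stages P-1, P-2,
P-3, T-5, T-6 for classes 1–5 under the default rule table. A planar
reading model degrades the truth findings with small miss
probabilities (DBF 0.10, proximal node 0.05, intermediate node 0.08)
and a 0.05 contamination probability (spurious intermediate node,
flagged) — the mechanisms that make planar-vs-combined comparisons
interesting. All couplings are arguments, not constants.

What the phantom does **not** model: scatter, attenuation, partial
volume at tissue interfaces (voxels are drawn per compartment), real
anatomy (no vessels, no skin layer, elliptical-only cross-sections),
upper-limb cohort geometry (single-phantom upper limbs are supported by
radius parameters; default cohorts are lower-limb), and human reader
variability beyond the miss-probability model. Passing recovery tests
therefore demonstrates internal consistency of the chain under
realistic noise, resolution and class structure — not clinical accuracy
on patient images.

## Statistics

scipy/statsmodels provide Kruskal–Wallis, Mann–Whitney (mid-ranks,
two-sided), Spearman, Shapiro–Wilk and the 2×2 McNemar (exact binomial
when discordant pairs < 25, unless overridden — the switch is explicit,
never silent). Implemented here because no installed routine matches
the needed convention: the McNemar–Bowker generalization with
zero-count symmetric pairs skipped and df reduced accordingly;
Dunn–Bonferroni post-hoc z-tests on pooled mid-ranks with the tie
correction and adjusted p = min(1, m·p); the linear-by-linear trend
statistic M² = (N−1)·r² with integer default scores; weighted κ = 1 −
Σw·O / Σw·E with linear (default) or quadratic weights, cross-checked
in tests against scikit-learn's independent implementation. κ bands
follow the conventional cuts with half-open edges at the printed
two-decimal boundaries (≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80
substantial, above almost perfect); negative κ reads poor. Numeric
summaries always retain both forms; the Shapiro–Wilk gate at α = 0.05
only chooses the displayed one, with n < 3 and constant vectors flagged
instead of gated.

Test calibration is asserted empirically: each test's statistic equals
a direct-formula/enumeration oracle on small instances to 1e-9, and
each test's type-I error under its null lies in [0.035, 0.065] over
1000 seeded simulations at sample sizes where the asymptotics are
adequate (the McNemar null simulation uses the uncorrected chi-squared
form, whose size is nominal at ~30 discordant pairs, where the
continuity-corrected form is conservative).

## Problem sizes and determinism

Recovery tests run on the default 96³ grid: 40-phantom cohorts for the
acceptance checks, single phantoms shared across module tests via
session fixtures, 64³ grids where only behaviour (not accuracy) is at
stake. Every random draw flows from one `numpy` Generator seeded by the
spec or function argument; the same seed reproduces volumes
bit-identically, and cohort generation derives child seeds from its own
generator so studies are independent but jointly reproducible.
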