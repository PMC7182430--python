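# Methods

## Scope and data model

The pipeline starts at the feature-table level — one row per detected ion
with m/z, retention time and replicate intensities — i.e. after peak
picking, and ends at identified, quantified molecular events plus the
membrane-geometry estimates. Raw spectra, CID fragmentation, and membrane
positioning itself are out of scope: identification is accurate-mass only,
and structures must arrive membrane-positioned (OPM convention) or with
leaflet planes supplied.

## Theoretical library

Lipids are modeled at class + X:Y resolution (total acyl carbons : total
double bonds), the resolution a single-stage accurate-mass experiment
supports. Formulas come from per-class construction rules anchored on the
diacyl-PA backbone C(c+3)H(2c−2d+5)O₈P; DAG is the dephosphorylated
backbone, cardiolipin the tetra-acyl double backbone, and IPC is modeled as
a tetra-hydroxylated ceramide phosphoinositol C(c+6)H(2c+12)NO₁₃P (MIPC
adds one hexose). The IPC/MIPC backbone hydroxylation state is an
inference from the measured masses — only m/z is available for these
species — and is therefore confined to a single constructor that can be
revised if fragment-level evidence ever contradicts it. Monoisotopic
element masses are pinned in code (NIST values) so the library is a pure
function of its configuration; an independent mass calculator (pyteomics)
cross-checks the table in the test suite.

Detection adducts per class follow the chromatography (ammonium-formate
mobile phases, negative mode for all lipids except ergosterol): [M+HCOO]⁻
for the zwitterionic/neutral PC and DAG, [M−H]⁻ for the anionic classes,
[M+H]⁺ for ergosterol. The default library additionally enumerates PC and
DAG under [M−H]⁻: after adduct collapse the deprotonated form is the
canonical event representative, so the annotator must be able to match it.
All ions are treated as singly charged.

Default enumeration ranges: 26–44 carbons × 0–6 double bonds for the
diacyl classes, 52–88 × 0–6 for cardiolipin, saturated 40–46-carbon
backbones for IPC/MIPC, a single ergosterol entry.

### A note on isobars

Some class assignments are not decidable by accurate mass: PC(c,d) and
PE(c+3,d) share a molecular formula, and the PC(c,d) formate ion is
element-for-element identical to the PS(c+3,d−1) [M−H]⁻ ion. These tie at
exactly 0 ppm. The annotator reports such events as `ambiguous` with the
full candidate list, choosing the displayed assignment by descending
class-abundance priority (PC > PE > PS > PI > PG > PA > CL > DAG > IPC >
MIPC). Resolving them requires fragment spectra or standards, which the
pipeline deliberately does not model.

## Filter cascade

Stages run in a fixed order, each reporting kept + removed = input:

1. **Enrichment** — keep a feature iff mean(sample) / (mean(control) + 1)
   ≥ 10. The threshold is inclusive; the pseudo-count of one intensity unit
   handles blank controls. Replicate means (not per-replicate minima) carry
   the decision.
2. **Censoring** (250–1600 m/z) — a feature is solvent/salt-like if its
   fractional mass is below 0.00045 per Da of m/z, or if it is a rung of a
   ladder of ≥ 3 features spaced by a salt-cluster unit (sodium formate,
   67.98742 Da). The fractional-mass rule is applied only below m/z 1200:
   above ~1.25 kDa the cumulative mass defect of CH₂-rich lipids wraps past
   a full Dalton (cardiolipins around m/z 1394 have fractional mass ≈ 0.01)
   and a naive lower bound would censor genuine lipids; ladder detection
   covers the full window. Ladders are found by union-find over integer
   multiples of the cluster unit, counting distinct rungs, so overlapping
   ladders that share grid positions cannot mask each other.
3. **Isotope collapse** — B merges into A when B sits one ¹³C–¹²C spacing
   (1.0033548 Da) above any current member of A within 5 ppm, co-elutes
   within 0.1 min, and is no brighter than 0.6× the member it stacks on
   (M+2 chains through M+1). Merging is greedy by descending mean sample
   intensity with ties broken by lower m/z then id, which makes the result
   independent of input order; a brute-force all-pairs reference
   implementation in the tests checks equivalence on small instances.
4. **Adduct/dimer collapse** — co-eluting events whose m/z differ by a
   registered neutral delta (formic acid, 46.00548 Da) are one molecule,
   with the lower-m/z deprotonated form as representative; an event at
   2·m + 1.00728 of *any member form* of a surviving molecule at the same
   retention time is its [2M−H]⁻ dimer and is absorbed. Checking all member
   forms matters: the dimer of a PC molecule forms from its formate ion,
   which after adduct collapse is no longer the representative.

The isotope ceiling of 0.6 is a deliberate simplification: the first-order
M+1 fraction is ≈ 0.0108 × nC, which exceeds 0.6 for molecules with more
than ~55 carbons (cardiolipins, some MIPC). Their M+1 ions therefore
survive as spurious singleton events — the main residual artifact class,
a few percent of events in the synthetic experiments.

## Synthetic experiments

The generator emulates the study conditions: three sample replicates
against three polymer-only controls, a 20-minute reversed-phase gradient,
multiplicative log-normal replicate noise at 10% CV, and true lipid ions
enriched ≥ 50-fold over control before noise (drawn log-uniform up to
100× that floor). The default class composition follows the yeast plasma
membrane (PC 38, PI 19, PE 17, PS 15, ergosterol 4, PA/PG/CL 1 each,
IPC/MIPC 2 each, mol%); acyl chain lengths are drawn from a discrete
normal centered at 32 carbons (σ 3; cardiolipin 68, ceramide backbones 44)
with double bonds centered at 1, matching the chain-length range of
identified plasma-membrane species rather than a uniform sweep of the
library grid. Retention times are linear in carbons (+0.25 min/C) and
double bonds (−0.6 min/bond) with class offsets — a fixed, arbitrary but
reversed-phase-shaped model.

Planted artifacts: M+1 isotopes at the binomial first-order fraction, one
co-eluting alternate adduct per species (0.3× intensity), [2M−H]⁻ dimers
for the brightest intensity decile (0.1×), sodium-formate ladders of 4–7
rungs (rendered *enriched*, so the censor stage rather than the enrichment
filter must remove them), and solvent ions present in both channels at
ratios within [0.7, 1.4]. Everything is a deterministic function of
(seed, config).

What the generator does **not** model — chromatographic peak shapes, ion
suppression, mass-accuracy drift, co-elution interference, missing values —
bounds what the recovery tests show: they validate the decision logic of
the cascade under the stated noise model, not instrument-level robustness.

## Quantification

External curves are ordinary least squares of area on concentration, not
forced through the origin (blanks may carry background); R² < 0.98 is
flagged. Standard addition estimates the endogenous concentration as the
magnitude of the x-intercept, intercept/slope, with a first-order
propagated SE including the slope–intercept covariance (−x̄·var(slope));
the estimator is scale-invariant in the areas and unbiased to well under
2% at 1% noise. Where both calibrations exist for an analyte, the ratio of
the standard-addition estimate to the external-curve estimate of the same
sample defines a per-analyte conversion factor correcting matrix effects.

Sphingolipids have no synthetic standards and are reported strictly as
peak-area ratios to ergosterol, never as molar amounts. Domain comparisons
use per-replicate ratios, group means ± SEM, fold change of group means,
and a two-tailed pooled-variance Student's t-test (Welch available via
flag); significance labels: * p < 0.05, ** p < 0.005. Degenerate
zero-variance groups return p = 1 when means agree. Lipids-per-SMALP is
total lipid pmol / protein pmol, assuming one protein per disc, rounded to
an integer; protein input normalization defaults to 1 µM.

## Membrane geometry

SMALP capacity: the polymer belt (1 nm) reduces the 9 ± 1 nm disc radius;
the remaining bilayer annulus minus a 20 nm² protein cross-section, doubled
for two leaflets, at 0.471 nm² per lipid, gives 78 lipids — inside the
predicted 1:60–120 protein:lipid envelope. (A stated disc area of ~50 nm²
is inconsistent with the 9 nm − 1 nm rim arithmetic, which gives 38.5 nm²;
the formulaic value is used.)

Leaflet cross-sections use polar wedge integration: atoms within ±2 Å of
the leaflet plane form the slab, the fan center is the slab's x/y centroid,
each of 80 wedges (θ = 4.5°) takes the largest in-plane atom distance as
its radius, and the area is Σ rᵢ²·tan(θ/2). For a circular footprint this
overestimates πr² by exactly (n/π)·tan(π/n) − 1 = 0.0514% at n = 80 and
converges as n → ∞. Atom centers are used without van-der-Waals inflation.
Lipid counts inside a 35 Å circle are round((π·35² − area)/47.1), floored
at 0; conformational displacement is the per-leaflet count difference
between two conformations computed with identical parameters.

The slab half-width (2 Å), centroid-based center, and the choice of
slab atoms over a whole-protein projection are config-exposed decisions;
the defaults were fixed before analysis and are the package's own.
Because no experimental transporter coordinates ship with the package,
`synthetic_transporter_conformers()` provides a clearly-labelled synthetic
stand-in at the scale of a 12-helix amino-acid permease (leaflet footprints
1500–1850 Ų) whose outward state widens the extracellular face and narrows
the cytoplasmic face; real OPM-positioned structures can be analyzed
directly via `read_membrane_pdb` / `perilipid geometry --pdb`.

## Problem sizes and determinism

The recovery suites use 25-seed batches of 50-species experiments and
1000-draw Monte-Carlo loops for calibration bias — sizes at which the
binomial uncertainty of the reported rates is well below the asserted
margins. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical (seed, config) pairs produce
byte-identical outputs, including CSV/JSON artifacts.

## Known limitations

- Accurate-mass-only identification cannot resolve exact isobars (see
  above) or sn-position/acyl-isomer structure; X:Y sums are the ceiling.
- The mass-defect censor is heuristic above ~1.2 kDa and relies entirely on
  ladder detection there.
- Very carbon-rich species (> ~55 C) shed M+1 singleton artifacts past the
  0.6 isotope ceiling.
- Standard addition assumes response linearity across the spike range and
  a non-negative intercept; negative intercepts report 0 with a warning.
- The filter thresholds (10-fold enrichment, 5 ppm, 0.1 min, 0.6) are
  defaults of the emulated protocol, not universal constants; all are
  config-exposed.
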