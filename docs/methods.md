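# Methods

This note documents the models, numerical choices and limitations behind
`lipidquant`, in the order the pipeline applies them.

## Lipid chemistry and the species database

Species are represented at sum-composition resolution — class, total
side-chain carbons, total double bonds, sn-1 linkage. Formulas derive from
a per-class rule table (`data/class_rules.yaml`): a backbone composition at
zero chain carbons plus CH₂ per carbon and −H₂ per double bond. Ether
(alkyl, `[O]`) species replace the sn-1 ester by an ether bond (−O +2H
versus the diacyl class). Plasmenyl (vinyl-ether) species are stored on
the alkyl rule with the vinyl-ether double bond counted in `double_bonds`
(P-n:m ≡ O-n:m+1); mass spectrometry cannot distinguish the two
sub-types — only the acid-hydrolysis assay does — so a single formula rule
keeps the database unambiguous. The rule table was validated against
published exact compositions of reference lipids (di-14:0 PC = C36H72NO8P,
di-14:0 PE = C33H66NO8P, tri-14:0 TG = C45H86O6, and so on; see
`tests/test_chem.py`).

Element monoisotopic masses and isotope abundances (IUPAC/CODATA values)
ship as a versioned data file so results do not depend on the runtime
environment. Isotopologue distributions are computed per element by exact
multinomial enumeration of heavy-isotope counts up to the shift cutoff,
then convolved across elements; each nominal-shift bin carries its
abundance-weighted exact mass excess. The default truncation is M+3: for
every formula in the default database the retained mass fraction exceeds
99.5%, and the M+4 abundance is below 1%. The full (untruncated)
distribution sums to 1 within 1e−9 up to C100 (property-tested), and the
truncated distributions agree with an independent atom-by-atom
polynomial-expansion oracle to 1e−9.

The default database enumerates the classes covered by the
internal-standard panel, their ether variants, the ether neutral lipids
and PS[O] — roughly 270 entries with one adduct per class ([M+H]⁺ for
cholines and sphingolipids, [M+NH₄]⁺ for neutral lipids, [M−H]⁻ for acidic
phospholipids). Which adducts the original acquisition actually quantified
per class is not recoverable from a method description, so these defaults
are a documented choice and fully user-overridable. Two deliberate
details: BMP (a PG structural isomer with identical formula) is assigned
the ammoniated positive-mode ion so the two classes remain
mass-distinguishable without retention-time modeling; and the CE class
ships without an internal standard, exercising the protein-scaled-only
unit path (its deuterated standard would need elements outside the bundled
table). Standard species use short/saturated chains lying outside the
endogenous carbon grids.

## Resolution model and overlap groups

Peak width follows FT-analyzer scaling: resolving power referenced at m/z
200 (default 280,000) falling as 1/√(m/z), hence FWHM ∝ (m/z)^1.5. Two
theoretical peaks closer than `merge_multiple` × FWHM (default 1.0, a
Rayleigh-type criterion) are treated as unresolvable and merge into one
observed feature whose m/z is the intensity-weighted centroid. At 280,000
the classic double-bond-ladder interference (M+2 of a more-unsaturated
species vs. the 2H-heavier neighbour's monoisotopic peak, 8.94 mDa apart)
is resolved below m/z ≈ 700 and merges above; interleaved cross-class
near-isobars (e.g. PI vs. PS ladders around m/z 805–812) merge as well.

Overlap groups are connected components over species sharing observed
features. Species membership and isotopologue-to-feature assignment use
two gates: the ppm-tolerance annotation (3 ppm default), and — because a
merged cluster's centroid can legitimately sit several ppm from each
member peak — an *envelope* gate of twice the merge threshold at that m/z
(twice, because single-linkage merge chains can span beyond one threshold
from the centroid). Identification reporting remains strictly
ppm-gated; the envelope only decides what enters the deconvolution
system. Species absent from a sample enter as zero columns and solve to
zero.

## Deconvolution

Each group × sample is solved by non-negative least squares (design
entries are isotopologue fractions of the species total, so the solution
is directly the total species intensity; the monoisotopic-equivalent is
the solution × M0 fraction). NNLS was chosen over sequential subtraction
because noise can push a peel-off negative; on strictly triangular chains
the two agree to 1e−9 (tested), and on noise-free synthetic studies the
closed loop through annotation and deconvolution recovers the generated
amounts to machine precision, including at a coarsened resolving power
(100,000) where dozens of multi-species groups form. Rank-deficient
systems (exact isobars mapping to identical features) are flagged
unresolved and reported as missing, never silently zeroed. Missing
features enter as zero intensity by default, matching the low/absent
semantics used for patients-only species; NA propagation is available.

## Normalization and class totals

For classes with a spiked standard: value = species intensity / standard
intensity × spiked nmol / protein mg. Ether classes are normalized on
their diacyl class standard, since no ether-specific standards are
spiked. Protein scaling and IS normalization commute under this formula,
so their order is immaterial. A zero/missing standard intensity flags the
class invalid for that sample (NaN) rather than guessing. Class totals
assume equal response of member species to the class standard; totals are
therefore comparable between sample groups within a class but never
across classes, and the output metadata says so.

## Statistics

The t-test defaults to pooled variance (Welch optional); ANOVA runs
across the fine-grained group labels; Bonferroni multiplies by the number
of species tested in the run (the family, configurable). Zero-variance
equal-mean rows get p = 1 with a `degenerate` flag. Dunnett's
many-to-one adjusted p is estimated by Monte Carlo (default 100,000
draws): group means and the pooled variance are drawn from their joint
null, which reproduces the Dunnett correlation structure exactly; the
adjusted p is clamped to at least the raw p. Monte-Carlo error at 1e5
draws is below ±0.005, verified against both `scipy.stats.dunnett` and a
data-level brute-force simulation.

PLS-DA is fitted by NIPALS on autoscaled (centered, unit-variance)
predictors against centered one-hot group indicators — autoscaling being
the metabolomics default; center-only and Pareto are available. The fit
is deterministic (no randomness). VIP weights each component by its
explained response sum of squares, the standard definition; mean squared
VIP is identically 1, which the suite asserts on every fitted model. The
default 2 components suffice for a two-condition contrast. Heat-map
matrices take the top-k (default 30) species by VIP, log-transform with a
pseudo-count of half the smallest nonzero value, and center per species,
so color encodes abundance relative to each metabolite's own mean.

## Plasmalogen discrimination and enzyme activity

Paired acid-hydrolysis measurements are summarized per ether species as
fraction remaining = treated/untreated; below 0.5 → plasmenyl
(plasmalogen), at/above → plasmanyl, indeterminate below a detection
floor. The 0.5 threshold sits halfway between the ideal outcomes (0 and
1) and tolerates large noise; the categorical truth configuration
(PC-ethers plasmanyl, PE-ethers plasmenyl) is recovered perfectly at full
hydrolysis efficiency and ≥95% at 10% CV noise.

Enzyme activity uses stable-isotope dilution: the product/IS area ratio
times the spiked IS amount (87 pmol) is inverted through an unweighted
OLS calibration line (with intercept; through-origin available) and
divided by assayed protein (40 µg) and incubation time (1 h), giving
pmol·h⁻¹·mg⁻¹ — units chosen to match the assay scale, as none are
dictated by the procedure itself. A supplied blank record's amount is
subtracted before scaling. A zero-slope calibration is rejected.

## Synthetic-data generator

The generator emulates the target study design: 3 control and 2 patient
fibroblast lines, quadruplicate injections, ~1 mg protein per extraction
(SD 0.1), the internal-standard panel at its stated amounts (2.0 nmol
PC(14:0)₂, 0.5 nmol PE(14:0)₂, 5.0 nmol PS(14:0)₂, ...), 1 ppm (SD) mass
error, and resolution-limited peak merging at 280,000. Class baselines
are fibroblast-plausible totals (e.g. PC 40, PE 20 nmol/mg) distributed
over member species with log-normal weights (σ = 0.5). Patient effects
are class-level multipliers; the defaults (×4 for the ether/neutral
accumulations, ×0.5–0.6 for the depleted classes, a patients-only PS[O]
class) encode the reported effect *directions* with synthetic magnitudes —
the source study prints fold differences only graphically, so recovery
tests target generator truth, not published values.

Intensity noise is multiplicative log-normal with 15% total CV,
decomposed into a per-sample shared injection/extraction factor (12%) and
a per-species independent residual (9%). The decomposition matters: the
shared component is precisely what internal-standard normalization
cancels, and modeling it as independent would misrepresent how IS-based
pipelines behave. Plasma mode reuses the generator with a matrix tag and
volume-interpreted scaling. Hydrolysis pairs share the untreated table's
features and noise so that efficiency 0 is an exact identity; plasmenyl
species survive with fraction 1 − efficiency. Enzyme-assay simulation
applies the shared injection factor jointly to product and IS areas
(residual detector noise one tenth of it), which is what lets the
isotope-dilution ratio recover activities within 2% at 5% area noise.

What the generator does *not* emulate: chromatographic peak shapes and
retention-time drift, adduct multiplicity per species, in-source
fragmentation, detector saturation, and heteroscedastic (intensity
dependent) noise. Passing tests therefore demonstrate correctness of the
computational chain under the stated statistical structure, not
robustness to every artifact of real acquisitions.

## Problem sizes

Test and acceptance runs use the study scale the design targets (20
samples, ~270 database entries, ~1000 features), 2000 simulated species
for null calibration, 100 random systems for the solver oracle, 200
random formulas for the isotope oracle and 10 seeds for recall
estimates — sizes at which every check runs in seconds on one core.

## Known limitations

- Annotation is m/z-only by default; retention-time windows exist but no
  RT prediction or standard-anchored RT correction is applied.
- One adduct per class: cross-adduct deconvolution is out of scope.
- Exact isobars in the same polarity (without distinct isotopologue
  placement) are reported unresolved rather than split.
- The Dunnett null is simulated, not integrated; rerunning with another
  Monte-Carlo seed moves adjusted p-values by up to ~0.005 at the default
  draw count.
- MS/MS-level structure confirmation (fragment spectra) is not modeled;
  the plasmanyl/plasmenyl call rests entirely on the hydrolysis contrast.
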