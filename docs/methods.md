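# Methods

## Estimator chain

The qSIP estimator treats the ultracentrifuge tube as the independent
experimental unit. Within each (site, temperature-treatment) group, every
taxon's per-tube weighted average density (WAD) is the copy-weighted mean
of fraction buoyant densities, where copies are the fraction's qPCR total
(16S copies per g dry mass) multiplied by the taxon's relative read
abundance in that fraction. Only fractions with density inside
[1.65, 1.74] g/ml — the window that is actually sequenced on these
gradients — enter any per-taxon computation; fractions outside are flagged
and logged.

The light-tube WAD anchors the taxon's GC content through the linear
density–GC calibration (intercept 1.646057 g/ml, slope 0.083506 g/ml per
unit GC) and hence its unlabeled molecular weight (0.496·GC + 307.691
g/mol). The labeled molecular weight scales the unlabeled one by the
relative WAD shift, and full ¹⁸O substitution adds 12.07747 g/mol. Excess
atom fraction (EAF) is the achieved fraction of that span, corrected for
the natural ¹⁸O abundance 0.002000429. These constants are module-level
values in `qsipgrowth.qsip` and can be swapped for alternate calibrations.

Assumptions worth keeping in mind:

* populations are at steady state (births ≈ deaths); turnover during the
  incubation biases RGR low and is not modeled;
* GC estimated from light-tube density is a calibration, not a sequence
  measurement; noisy light WADs can push GC outside [0, 1], in which case
  it is clamped with a logged warning rather than rejected;
* negative EAF values (labeled WAD below the light mean) are retained for
  estimation — truncating at zero would bias recovery and the null
  calibration.

## Filtering and significance

A taxon enters a group's analysis only if, for each isotope treatment
separately, it has nonzero reads in at least `min_fractions` (default 4)
fractions of at least `min_replicates` (default 2) tubes. The bootstrap
resamples tubes with replacement within isotope treatment (1000
iterations by default), recomputes mean light and heavy WADs and then
EAF per iteration, and reports the median with 2.5/97.5 percentile
limits. "Significant grower" is strict: the lower limit must exceed
zero; a CI touching zero is not significant. Tube-level resampling was
chosen because the tube is the unit that captures between-replicate
biological and gradient variability; resampling fractions would treat
within-tube density bins as exchangeable, which they are not.

## Growth rates and aggregates

RGR = EAF / (E × 0.6 × days) with E the soil-water ¹⁸O atom fraction from
the two-pool mixing model (mass-weighted mean of ambient water at natural
abundance and added tracer at 0.98). E is computed per heavy tube from its
water-addition record and averaged within the group; with equal ambient
and added masses E = 0.4910002145. The factor 0.6 is the fraction of DNA
oxygen derived from water and 28 days is the default incubation length;
both are fields of `EnrichmentModel`.

Per-taxon gene copies for cumulative growth are reconstructed at
replicate level — per-tube total 16S copies (summed over in-window
fractions) times the taxon's per-tube relative read abundance, averaged
over the group's tubes — then multiplied by the taxon's RGR and summed.
Phylum proportions divide each phylum's summed growth by the total; taxa
without a phylum rank pool into "Unclassified". Proportions are undefined
(and reported as such) when total growth is not positive, which happens
legitimately for unlabeled communities.

The family warming test subtracts, per bootstrap iteration, the family's
mean control RGR from its mean warmed RGR at the same site, using the
unweighted mean over the family's ASVs present in each treatment
(abundance weighting is a deliberate non-default: the choice of weights
is not obvious and unweighted is reproducible from the output tables).
Families estimable in only one treatment are excluded and logged. The
output convention is stated in the run manifest: positive differences
mean growth increased with warming, and significance again requires the
95 % interval to stay above zero. The test is exactly antisymmetric under
swapping the treatment labels.

## Chamber fluxes

Dry CO₂ is C/(1 − W/1000). The first 20 s after closure (deadband) are
discarded; the OLS slope is taken over the following 70 s using recorded
timestamps (robust to logger gaps). W₀ is the water vapor mole fraction
at the first retained sample. The flux equation multiplies the slope by
10·V·P·(1 − W₀/1000)/(A·R·T) with V in cm³ (5.7 l chamber plus collar
height × 660.5 cm² footprint), P in kPa, T in K and R = 8.31 J K⁻¹ mol⁻¹;
the leading 10 reconciles the mixed units (cm³, kPa, cm², µmol/mol) to
µmol m⁻² s⁻¹, verified by a zero-noise inversion test rather than
re-derived symbolically. Signs follow the atmospheric perspective:
chamber accumulation is positive, negative NEE is a carbon sink, and
GEP = −NEE + ER exactly on every output row (missing pair members leave
GEP missing, never imputed).

## Synthetic data

The simulator emulates the tracer-study design: per group, 5 replicate
plots × {light, heavy} tubes, 23 fractions spanning 1.65–1.74 g/ml. Each
taxon's light-tube target WAD follows from its GC content; the heavy-tube
target is obtained by inverting the exact estimator chain at the taxon's
true EAF, so zero-noise recovery is exact by construction and estimator
bugs appear as recovery failures. DNA mass spreads over the fraction grid
with a Gaussian density kernel (default dispersion 0.004 g/ml — enough
multi-fraction occupancy that the ≥4-fraction presence filter is
passable, as on real gradients); reads are multinomial at 10⁴ per
fraction; qPCR totals are the true per-fraction copy sums under
multiplicative lognormal noise (σ = 0.1 on the log scale, a typical
qPCR technical spread); and each taxon's target WAD receives an
independent N(0, 0.002 g/ml) jitter per tube representing between-
replicate gradient and biological variability. Tube totals default to
2.5×10⁹ 16S copies per g dry mass, the magnitude observed in young
glacier-forefield soil. Water additions default to 5 g ambient + 5 g
tracer (doubled water content). Randomness fans out from one root seed
via `numpy.random.SeedSequence.spawn`, one child stream per tube in
generation order, so datasets are bit-reproducible.

What the simulator does **not** emulate: sequencing error and chimeras,
compositional artifacts of amplicon workflows, taxon turnover during the
incubation, density-gradient asymmetries, or correlated qPCR bias across
fractions. Passing recovery tests therefore demonstrates correctness of
the estimator chain under the stated noise model, not robustness to every
artifact of real amplicon data.

## Numerical choices

* WAD of an absent taxon (zero copies) is NaN, and taxa with no defined
  WAD in one isotope arm are dropped with a logged reason.
* The Gaussian kernel exponent is shifted by its row minimum before
  exponentiation so point-mass taxa (tiny dispersion) cannot underflow to
  an all-zero row.
* Bootstrap draws use `numpy.random.default_rng`; per-taxon seeds derive
  from the run seed by spawning in sorted-taxon order, making whole-run
  outputs byte-identical across reruns with the same config.
* Percentile CIs use NumPy's linear interpolation; the point estimate is
  the bootstrap median.
* Regression uses `scipy.stats.linregress` on the retained window
  (deadband, deadband + window].

## Problem sizes

Validation runs use 40-taxon communities (200 for the null calibration)
under the full 5 + 5 tube design, 1000 bootstrap iterations for interval
estimates and 200 for repeated-seed power checks across 100 seeds —
sizes at which the Monte-Carlo error of the checked quantities is well
below the tolerances being asserted.

## Known limitations

* RGR ignores turnover and assumes a constant soil-water enrichment over
  the incubation (no evaporation/exchange decay); both biases are
  inherited from the underlying model, not the implementation.
* The presence filter interprets "present" as nonzero reads (identical
  to nonzero copies whenever the fraction's qPCR total is positive).
* Downstream inferential statistics (mixed models, ANOVA contrasts,
  ordination) are out of scope; the emitted tidy tables are their
  intended input.
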