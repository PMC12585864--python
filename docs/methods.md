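# Methods

## Scales and conversions

Isotope values are per-mil (‰) δ values on the VPDB scale throughout.
δ¹⁸O values published on the VSMOW scale are converted with the carbonate
convention δ¹⁸O_VPDB = (δ¹⁸O_VSMOW − 30.91)/1.03091; the transform is
affine, so the round trip is exact to floating-point precision.

Enamel δ¹³C is mapped to the modern-equivalent diet scale as

    diet_meq = enamel − E + (atm(epoch) − atm(modern))

with diet–enamel enrichment E = 14.1 ‰ and atmospheric CO₂ δ¹³C references
−6.3 / −6.5 / −8.0 ‰ for Pliocene / Pleistocene / modern. Two points about
this formula deserve notice:

* The sign of the atmospheric term is fixed by arithmetic, not prose: with
  these constants every Pleistocene conversion is a −12.6 ‰ translation and
  every modern conversion a −14.1 ‰ translation, which reproduces all fifty
  derived table cells of the reference dataset to 2 dp. A "same
  fractionation in modern air" verbal reading could suggest the opposite
  sign; the published table arithmetic is treated as authoritative.
* The transform is a pure translation per epoch, so within-profile
  differences, standard deviations and ranks are identical on the enamel
  and diet-meq scales.

Reported values are rounded with correctly-rounded decimal semantics
(Python `round`), 2 dp in tables and 1 dp in summaries. This matters at
the margin: a δ¹⁸O minimum of −8.05 prints as −8.1 under decimal rounding
but −8.0 under numpy's scaled float rounding. Internal computation is never
rounded.

## Diet reconstruction

The five-class vegetation scheme (closed-canopy forest up to pure C₄
grassland) is defined on the enamel scale from −20.5 to +6.5 ‰ and shifted
by −14.1 ‰ for diet-meq values. The published bounds touch
("−14.5 to −9.5", "−9.5 to −6.5") without stating inclusivity; bins are
implemented half-open [lower, upper) with the last bin closed, so boundary
hits are deterministic and the scheme partitions its range. Values outside
the total range return an explicit `outside_scheme` sentinel — never a
silent clamp.

The C₄ fraction is linear mixing between end members −34.6 ‰ (C₃) and
−7.6 ‰ (C₄) on the diet-meq scale. End members are interpreted on the
diet-meq scale because the published percentages reproduce exactly under
that reading. Their provenance is not derivable here, so they are plain
configurable constants. Fractions outside [0, 1] can arise when measurement
noise overshoots an end member; they are clamped and flagged rather than
rejected.

## Profile statistics

Standard deviations use the sample (n−1) denominator — recomputation of the
juvenile's δ¹³C_diet-meq spread decides this empirically (1.09 ‰ with n−1
versus 1.03 ‰ with n against a printed 1.09). A single usable sample
reports SD as undefined, not zero. Missing grooves (insufficient enamel
powder) are represented explicitly and excluded from every statistic.

The time axis maps groove distance to years through the enamel extension
rate, default 12 mm yr⁻¹ so the 1 mm groove spacing is approximately
monthly; the plausible proboscidean range 8–21 mm yr⁻¹ is exposed as a
parameter.

## Weaning-shift detection

No standard inferential definition of an intra-tooth weaning signal exists;
the detector here is deliberately simple plumbing, fully parameterized:

* Split the profile into the first k non-missing samples (default k = 3)
  and the tail; compute effect = |mean(early) − mean(tail)| / SD(tail).
* Flag a shift when effect ≥ t (default t = 2.0) **and** the leading k+2
  samples trend monotonically toward the tail.

The monotonicity guard is evaluated on the 3-point moving average of the
leading segment, ignoring reversals smaller than 15 % of the early–tail
gap. Raw successive differences of noisy samples would veto genuine shifts
almost half the time even at signal-to-noise 5; smoothing tests the trend
at the same scale the two-window statistic compares, and on simulated null
profiles the guard plus the effect threshold still yield zero false
positives in 200 seeded replicates. Profiles shorter than k+3 usable
samples return a *non-evaluable* report, distinct from a negative. The
statistic is invariant to adding a constant and flips direction under
negation.

The weaning *position* is estimated separately by least squares: the
nursing excursion is modeled as a linear ramp from full offset at the first
sample to zero at candidate completion index w, and the shared w maximizing
the joint Gaussian profile likelihood over both analytes is returned. Two
domain priors sharpen the fit: amplitude signs are fixed by milk physiology
(δ¹³C depleted, δ¹⁸O enriched), and candidates are restricted to the first
half of the profile because weaning is an early-ontogeny event. Joint
two-channel estimation roughly halves the variance relative to a single
channel — the weaning signal is a paired excursion by definition.

## Cross-taxa comparison

Serial profiles are collapsed to one mean per individual before testing, so
they are commensurate with literature bulk values (a bulk sample is a
time-average). Comparisons use the two-sided Wilcoxon rank-sum test; the
reported W is the first-sample Mann–Whitney U (pairs with focal > other,
ties counted half), computed by direct pair counting so the complement
identity W(x,y) + W(y,x) = n₁n₂ holds exactly. p-values are exact
(permutation distribution) when min(n) ≤ 8 and the data are tie-free,
otherwise a tie-corrected normal approximation with continuity correction;
the mode is user-overridable. Whether the published p-values were exact or
asymptotic is unstated, hence the override.

Holm's step-down adjustment is applied across the family of all pairwise
focal-vs-other tests within one analyte; families are not pooled across
analytes. Effect sizes are rank-biserial correlations, oriented so r = +1
when the comparison taxon lies entirely below the focal taxon, with 95 %
percentile-bootstrap confidence intervals (2000 resamples of both groups,
seeded and bit-reproducible). A comparison whose CI spans zero is labelled
*uncertain* regardless of its p-value.

## The forward simulator

`generate_profile` builds a diet-meq signal as baseline + seasonal sinusoid
+ nursing ramp + i.i.d. Gaussian noise, applies moving-average damping, and
converts to the enamel scale by inverting the diet-meq transform, so
simulated tables flow through the pipeline unchanged. δ¹⁸O is built
analogously with the nursing offset sign reversed. What it emulates, and
what it does not:

* **Nursing**: δ¹³C offset −1.5 ‰ (the magnitude reported for proboscidean
  milk depletion) and δ¹⁸O offset +1.5 ‰ (enrichment direction is known,
  magnitude is not; chosen symmetric and configurable), decaying linearly
  (or exponentially) to zero at the weaning sample.
* **Damping**: enamel maturation time-averages the input signal; modeled as
  a centered moving average of width w with shrinking edge windows. The
  closed-form gain sin(πw/P)/(w·sin(π/P)) for a period-P sinusoid anchors
  the tests (w = 3, P = 12 gives 0.911). Damping never increases variance.
  Real maturation geometry (appositional angles, maturation kinetics) is
  *not* modeled, and no inverse deconvolution is attempted.
* **Noise**: Gaussian i.i.d.; real analytical error is likely smaller than
  biological scatter but neither is separately quantified, so a single SD
  covers both.

Passing the simulation-based tests therefore demonstrates correctness of
the statistical machinery under the assumed signal structure, not fidelity
of that structure to any particular fossil.

Validation scenarios (all seeded, 200 replicates each) and measured
behavior:

* weaning-position recovery: 30-sample profiles (2.5 yr of monthly growth,
  well within proboscidean molar formation time), weaning completing at
  sample 6 — mirroring the real juvenile's groove 3→6 transition — offsets
  ∓1.5 ‰, noise 0.5 ‰ (signal/noise 3): ≥ 90 % of estimates within ±2
  samples;
* false positives: null profiles with seasonality 0.5 ‰ and noise 0.3 ‰:
  ≤ 5 % (observed 0);
* sensitivity: offset 5 × noise SD: ≥ 90 % detected;
* two-taxon power: 3 ‰ baseline shift, 0.3 ‰ noise, 10 + 10 individuals:
  rank-sum rejection at α = 0.05 in ≥ 95 % of runs.

## Degenerate inputs and numerical choices

Empty profiles, all-missing analytes, non-positive extension rates,
degenerate mixing models (equal end members), out-of-range p-values and
unknown epochs raise typed errors; a ‰ sanity window [−40, +20] rejects
ratio-scale inputs at construction. A constant tail gives effect 0 for a
constant profile and ∞ for a genuine step (SD = 0 handled explicitly).
Bootstrap and simulation seeds derive from `numpy.random.SeedSequence`
spawning, so per-individual streams are independent and reproducible.

## Known limitations

* The detection rule is a screening heuristic, not changepoint inference;
  no formal error control beyond the simulated operating characteristics.
* The cross-taxa replication of published W statistics requires the
  original per-individual compilation, which is not redistributable here;
  the test skips without it.
* Ontogenetic ages are inputs; nothing here estimates age from wear.
* δ¹⁸O is interpreted directly; no drinking-water back-calculation and no
  phosphate–carbonate conversion.
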