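# Methods

## The model and its assumptions

`radonrecon` implements a *discrete* (non-stochastic) long-term-average
dispersion model: every random quantity is fixed at its central value, and
the output is an annualized increment of outdoor Rn-222 above natural
background. The chain is

1. **Source term.** The two K-65 silos are one ground-level circular area
   source (radius ρ = 50 m at the midpoint between them) with a
   piecewise-constant release rate. The shipped timeline has five events
   covering Jul 1952 – Dec 1988 (438 months) at median rates 1900, 4900,
   6200, 950 and 540 Ci·y⁻¹, with 5th/95th-percentile brackets carried
   alongside. Consecutive events share their printed boundary month
   (Jun 1953, Sep 1958); we assign the shared month to the **earlier**
   event, i.e. the transition happens at the end of the boundary month.
   This yields a contiguous non-overlapping timeline whose median integral,
   164,890 Ci, rounds to the documented headline total of 1.6 × 10⁵ Ci at
   two significant figures (the alternative later-event convention gives
   165,248 Ci → 1.7 × 10⁵). Nothing is emitted before Jul 1952 even though
   drummed waste was stored on site from late 1951: no release rate was
   ever quantified for that period. Rates are stored in Ci·y⁻¹ and
   converted with the Julian year (3.1557 × 10⁷ s) only inside the
   dispersion step.

2. **Meteorology.** Monthly joint-frequency tables are stored factored:
   stability-class frequencies h_s (sum 1 per month) and conditional cell
   frequencies g_{q,d|s} over 16 directions × 6 speed classes (sum 1 within
   each class); both normalizations are validated to 1 × 10⁻⁹ on load.
   Speed-class midpoints are fixed at 1, 3, 5, 7, 9, 11 m·s⁻¹; the open
   ">10 m·s⁻¹" class is represented by 11, and calm winds are absorbed by
   the 0–2 m·s⁻¹ class rather than modelled separately. Wind ratios
   Σ_q f_{q,d,s}/u_q are kept per stability class so the diffusion function
   can be weighted per class, consolidated from 16 directions to the octet
   by half-splitting every intermediate direction (which conserves the
   total exactly), and annualized as the unweighted mean over the 12
   months — the month-length weighting question is unresolvable from the
   historical description, and the unweighted mean matches "averaged
   across all months" most directly.

3. **Dispersion.** The historical calibration curve for the diffusion
   function was never tabulated, so σ_z uses the Briggs open-country
   (rural) interpolation formulas — standard, closed-form, defined for all
   six stability classes — and the model's own (x/ρ)^c calibration factor
   absorbs residual shape error. The sector-averaged ground-level value is
   D_s(x) = √(2/π)/(σ_z(s,x) · 2πx/8); the sector width is 2π/8 because
   receptors live on the octet grid. The area source is evaluated as a
   point source at the receptor distance with an evaluation floor of 2ρ
   (100 m): all real receptors sit at ≥ 1600 m ≫ 50 m, where disk and
   point sources agree. That claim is enforced, not assumed — an explicit
   2-D quadrature of point-source plumes over the 50 m disk, averaged over
   the 45° sector arc, must agree with the closed form within 10% for all
   six classes at 500–8000 m (observed maximum disagreement ≈ 6%, in
   class A at 500 m where the lateral plume spills past the sector edge).
   Plume depletion, decay in transit (Rn half-life 3.8 d versus sub-hour
   travel times), terrain and building wakes are neglected; the φ factors
   that would carry such effects are fixed at their geometric mean of 1.
   The calibration exponent uses the stated mean 0.19 directly.

4. **Exposure assembly.** Concentrations are computed on the full
   (sector × calendar month) grid for 1952–1988; the annual value of a
   sector-year is defined as the mean of its 12 monthly values, so the two
   resolutions can never disagree. Every subject resident in a sector for
   a full year sees the identical concentration; partial years average the
   monthly values over the months actually resident (a month counts if the
   interval covers any day of it). The subject mean is the
   duration-weighted mean of annual values; sector rankings average over
   the full 1952–1988 window including low-emission years, which is what
   makes the Maximum/Mean ratio constant across sectors whenever one met
   table is held fixed. Background radon (≈0.24–0.58 pCi·L⁻¹ in the
   region) is *not* added: the model output is the increment above
   background. Geometric summary statistics use natural logs of strictly
   positive subject means, excluding (and counting) non-positive ones.

## Residential-history cleaning

Records carry FROM/TO month and year only. Rules, in order: records missing
either year are dropped; records whose sector id is absent from the grid are
dropped; a missing FROM month defaults to 1 July and a missing TO month to
30 June (the year midpoint, so errors offset in expectation); a FROM date
before the subject's DOB is replaced by the DOB (families often reported the
family's move-in date), unless the DOB is after the exposure window, in
which case the record is dropped; the interval is then clipped to
Jul 1952 – Dec 1988. The window follows the source-term coverage: exposure
is zero without emission, so the 1951 drummed-storage period contributes
nothing either way. Overlapping residences of one subject are kept and
logged, not resolved — double-counted months inflate both the numerator and
the duration weight symmetrically. Cleaning is idempotent, and date
arithmetic is Gregorian-correct even though month granularity dominates.
SAS-encoded dates (day counts from 1960-01-01) are auto-detected per value.

## Synthetic data: what it emulates and what it does not

The real cohort is consent-restricted and the 1987–1991 tower
joint-frequency tables live in an out-of-print agency report, so the
generators emulate *structure*, not the true site statistics:

* **Cohort** — per-residence missingness probabilities default to the
  documented rates (8.49% FROM month, 7.55% TO month, 0.49%/0.72%
  FROM/TO year); arrival/departure months are near-uniform with a mild
  June/July excess and Feb/Mar/Nov/Dec deficit; residential density favours
  the historically populous NE/E/SE sectors. Relocation rate (0.07·y⁻¹,
  a typical mid-century residential mobility figure) and decade growth
  multipliers (0.7/0.95/1.2/1.15, growth to the 1970s then decline during
  decommissioning) are plain modelling choices. The generator also emits
  the pre-injection ground truth so the cleaning stage can be validated
  record-for-record.
* **Meteorology** — prevailing-direction weights favour NW/W/SW, a calm
  bias doubles the weight of the <2 m·s⁻¹ class, and a seasonal tilt makes
  winters windier than summers; both normalization constraints hold exactly
  by construction. One master seed drives named substreams
  (`SeedSequence([seed, crc32(name)])`), so identical seeds give
  byte-identical outputs and new generators never perturb existing draws.

Consequently, passing tests demonstrate the *mechanics* — conservation,
linearity, separability, cleaning fidelity, exceedance counting — on data
with realistic structure; absolute synthetic concentrations are typically
an order of magnitude below historical estimates because the synthetic wind
rose is far less calm and stable than the real site record, and no attempt
is made to tune it toward historical exposure tables.

## Numerical choices

* Normalization tolerance 1 × 10⁻⁹ on met tables; consolidation conserves
  totals to < 1 × 10⁻¹²; separability holds to 1 × 10⁻⁹ on fixed met.
* Receptor distance is the historically rounded ring midpoint 1600·ring m, not the
  exact mile (1609 m).
* The quadrature oracle uses midpoint polar integration over the disk
  (24 radial × 48 angular nodes) and trapezoidal averaging over 49 arc
  positions; it is written against independently transcribed Briggs
  coefficients.
* Problem sizes in the test-suite and acceptance script — 10,000-subject
  cohorts for missingness recovery, 2,000 subjects for the end-to-end
  scenario, 400 for the locked regression fixture — are chosen so the
  binomial 3-sd recovery bounds are tight while the whole suite runs in
  seconds.
* Output CSVs round to full precision internally, 6 decimals in the locked
  regression digest; the digest is over parsed, rounded values so header
  metadata and float formatting do not enter.

## Known limitations

* The true id→geometry mapping of the 100 historical sectors was never
  published; only the ~20 ids appearing in historical summary tables are
  pinned (one of them, B05, is printed with two different octets in
  different decades — we use its first appearance, NW). The remaining ids
  are synthetic and deterministic.
* The real per-sector and cohort exposure tables cannot be reproduced
  without the restricted residential data and the original meteorological
  tables; no target values for them are asserted anywhere.
* No Monte Carlo propagation of K, c, or the φ factors: the model is
  deliberately discrete. The percentile source-term brackets are carried
  through the API (`quantile="p05"/"p95"`) but not combined into
  uncertainty intervals.
* Workplace/school time away from the residence, indoor infiltration
  modelling, and radon-progeny dosimetry are out of scope.
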