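# radonrecon

Reconstruction of historical outdoor radon (Rn-222) exposure for a community
cohort living around a fixed emission source — the K-65 uranium-mill-tailings
storage silos at the Fernald site in southwest Ohio, which released radon from
1952 through 1988. The package is aimed at exposure scientists and
epidemiologists who need annualized outdoor Rn concentrations on a polar
receptor grid and duration-weighted per-subject exposures from
month-resolution residential histories, for example as the exposure side of a
lung-cancer incidence analysis.

## Model

The ground-level Rn concentration at a receptor in octet direction *d* at
distance *x* during period *t* is

```
X_{d,t}(x) = K (x/ρ)^c · Σ_q Σ_s  f_{q,d*,s} / u_q  · D_s(x) · Q_t · φ_resid · φ_met
```

* `K (x/ρ)^c` — empirical calibration factor anchored at the source radius
  ρ = 50 m; ln K ~ N(−0.44, 0.69²), c ~ N(0.19, 0.32²). The discrete model
  uses the central values.
* `Σ Σ f/u` — the *wind ratio* (s·m⁻¹): monthly joint frequencies
  f_{q,d,s} over 6 speed classes (midpoints 1–11 m·s⁻¹), 16 directions, and
  Pasquill–Gifford stability classes A–F, divided by the class-midpoint
  speed, summed, and consolidated to the 8-direction octet rose. Winds are
  named by where they blow *from*, so receptors in octet *d* use the
  reciprocal direction *d\** (differing by 180°).
* `D_s(x)` — sector-averaged ground-level Gaussian diffusion,
  `√(2/π) / (σ_z(s,x) · 2πx/8)` m⁻², with Briggs open-country σ_z.
* `Q_t` — piecewise-constant release rate from the shipped emission-event
  timeline (Ci·y⁻¹, converted to Ci·s⁻¹), 1900 → 4900 → 6200 → 950 → 540
  Ci·y⁻¹ across the five documented eras.
* `φ_resid`, `φ_met` — lognormal adjustment factors with geometric mean 1,
  fixed at 1 in this discrete model.

A final factor of 10⁹ converts Ci·m⁻³ to pCi·L⁻¹, directly comparable to the
EPA indoor action level of 4 pCi·L⁻¹. Per-subject annual exposures average
the monthly sector concentrations over the months actually resident; the
subject mean is the duration-weighted mean over years. The real cohort and
tower meteorology are access-restricted, so a first-class synthetic module
generates cohorts (with the documented missing-data rates) and normalized
joint-frequency tables for every pipeline stage.

## Worked example

```python
import radonrecon as rr
from radonrecon.synthetic_data import MetSpec, generate_met

timeline = rr.EmissionTimeline.default()
timeline.total_release((1952, 7), (1988, 12))   # 164890 Ci  (≈1.6e5)
timeline.monthly_rate(1965, 6)                  # 6200.0 Ci/y

grid = rr.default_grid()                        # 100 sectors, 5 rings × 8 octets
tables = generate_met(MetSpec(seed=7))          # 12 synthetic monthly wind tables
matrix = rr.build_matrix(grid, timeline, tables)
matrix.annual_value("B03", 1965)                # 0.329 pCi/L (NE, 1600 m)

from datetime import date
from radonrecon.residential_history import CleanedResidence
subject = rr.Subject("s1", date(1940, 1, 1), [
    CleanedResidence("s1", "B03", date(1958, 1, 1), date(1962, 12, 31)),
    CleanedResidence("s1", "H02", date(1963, 1, 1), date(1969, 12, 31)),
])
rr.subject_exposure(matrix, subject).mean       # 0.342 pCi/L over 12 years
```

The total-release integral is the month-weighted sum of the event rates; the
sector concentration is the plume model above evaluated with the June-1965
release era and the synthetic wind rose; and the subject mean is the
12-year duration-weighted average across the two addresses (5 years in the
nearest NE sector, 7 in the nearest SE sector). Absolute concentrations
depend on the synthetic wind tables — calmer, more stable conditions raise
them — so only their structure, not their magnitude, should be compared with
historical estimates.

There is also a CLI:

```sh
radonrecon simulate --n-subjects 500 --seed 1 --out-dir scenario/
radonrecon reconstruct --sectors scenario/sectors.csv \
    --met scenario/met_conditional.csv --met-class scenario/met_class.csv \
    --emissions scenario/emissions.csv --residences scenario/residences.csv \
    --config scenario/config.yaml --out-dir results/
radonrecon summarize --exposures results/subject_exposures.csv
```

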