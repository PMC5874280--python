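# Methods

## The diurnal model

Hourly temperature on day *i* is reconstructed from that day's minimum
Tn_i and maximum Tx_i, the neighbouring days' values, and the sunrise and
sunset hours h_R, h_S in decimal true solar time (TST):

* h < h_R,i + c (pre-sunrise):
  `T = Tn_i + (TS_{i-1} - Tn_i) * [exp(-b*t/n1) - (t/n1)*exp(-b)]`,
  with `t = h - h_S,i-1 + 24` and `n1 = h_R,i - h_S,i-1 + c + 24`;
* h_R,i + c <= h <= h_S,i (day):
  `T = Tn_i + (Tx_i - Tn_i) * sin(pi*(h - h_R,i - c) /
  (h_S,i - h_R,i + 2a - 2c))`;
* h > h_S,i (post-sunset): the same exponential form with `t = h - h_S,i`,
  `n2 = h_R,i+1 - h_S,i + c + 24`, relaxing towards Tn_{i+1}.

TS is the day branch evaluated at sunset. Because the bracketed night term
equals 1 at t = 0 and 0 at t = n, the curve passes exactly through TS at
sunset and through the coming day's Tn at sunrise + c, and the evening
branch of day i is algebraically identical to the morning branch of day
i+1 — the series is continuous through midnight to machine precision (the
test suite asserts < 1e-9 °C). An alternative reading of the night
correction in which the additive `-(t/n)*exp(-b)` term is *not* scaled by
(TS − Tn) circulates in the literature; it does not pass through Tn and is
retained only for comparison behind `night_form="literal"`.

Parameters, with units, defaults and meaning:

| parameter | unit | generic default | meaning |
|---|---|---|---|
| a | h | 2.71 | lag of the daily maximum after solar noon |
| b | – | 3.14 | nocturnal decay rate (larger = faster evening cooling) |
| c | h | 0.75 | lag of the daily minimum after sunrise |

Sanity bounds (−2 < a < 6, b > 0, −2 < c < 4) flag but never clip fitted
values: high-alpine sites can legitimately produce a > 5.5, which signals
that the model's timing assumptions are failing there, not that the
optimiser should be constrained.

Edge days of a series have no previous sunset temperature / next minimum;
they reuse their own values as surrogates and are flagged `edge` in the
output. Days with missing Tn/Tx propagate NaN hours; no imputation.

### Hour conventions

The model core works in continuous decimal TST. The default sampling grid
is h = 1..24 — the stamp at hour h closes the interval ending at h, so
00:00 belongs to the previous day, matching the degree-day summation over
h = 1..24 — with h = 0..23 and arbitrary dense grids available. Conversion
between civil time and TST (longitude offset plus the equation of time)
happens only at the I/O boundary.

## Solar geometry

Declination and the equation of time use Spencer's Fourier series
(declination accurate to < 0.3°, EoT to < 1 min — far below the
sensitivity of the lag parameters). Sunrise/sunset come from the hour
angle `cos H = -tan(lat) tan(decl)`; by construction h_R + h_S = 24.
Polar day/night raises an explicit error (never triggered at mid-latitudes;
it guards misuse). No refraction or elevation correction is applied.

"Potential" daily radiation — the denominator of the clear-sky ratio — is
daily extraterrestrial radiation times a constant atmospheric
transmissivity, default 0.75. The transmissivity is a free knob, not an
atmospheric model; since the same value is used when generating synthetic
ratios and when classifying, it cancels from the ratio criterion.

## Calibration

Clear-sky days are those whose temperature minimum occurs before solar
noon and whose observed/potential radiation ratio exceeds 0.9 (both
configurable). The minimum's clock hour is read on [0, 24): a minimum at
the terminal midnight stamp is the start of the next morning's cooling
regime and counts as hour 0. With noisy data the minimum is located on a
±3 h moving average; the window is much shorter than the half-day scale of
the morning/afternoon question, cannot move a genuine afternoon minimum
across noon, and coincides with the raw minimum on noise-free curves.
Incomplete days are dropped (reported), not misclassified.

Calibration years (default 25) are drawn uniformly without replacement
with a user seed. Fitting maximises the modified index of agreement
(Legates–McCabe d1, exponent 1) between observed and reconstructed hourly
temperatures over the *concatenated* hours of all selected days (per-day
averaging is available as an option) using Nelder–Mead with xatol 1e-6,
fatol 1e-9, max 2000 iterations, started from the site-specific mean
triple (2.79, 3.16, 0.79). The "generic" fit is the identical optimisation
on the concatenation of several stations' clear-sky hours. Results carry
the convergence flag, iteration count and the objective at the optimum.

Estimator behaviour, measured on synthetic data: with noise-free input the
optimum of the pooled MIA is the generating triple and is recovered to
better than 1e-3. With 0.5 °C i.i.d. hourly noise and 100 clear days the
per-parameter spread is ~0.03–0.05; the night-decay coefficient b carries
a small positive bias (~+0.03) intrinsic to the absolute-deviation
objective (an NSE objective is unbiased under the same conditions), which
grows when the calibration days are winter-heavy — calibration sets should
span the seasonal cycle.

## Degree-days and phenological dates

aGDD accumulates the clipped hourly excess over Tb (default 10 °C — at the
demanding upper end of insect base temperatures) divided by 24; for days
with a tolerated number of missing hours the mean over available hours is
used, which equals the 1/24 sum on complete days. Threshold dates are the
first DOY with cumulative aGDD ≥ threshold. The empirical correction
f_corr is the mean over site-years of actual/estimated end-of-year ratios
(ratio-of-means available), applied multiplicatively to the whole
trajectory, so correction with f < 1 can only delay threshold dates. The
efficiency Ef is the fraction of site-years with |estimated − actual
DOY| ≤ 3; site-years where either trajectory never reaches the threshold
are excluded from the denominator and reported as a separate count.
Distribution comparisons of date samples (rank-sum, Kolmogorov–Smirnov)
are a thin hook over scipy.stats.

## Spatial stage

For each grid cell and calendar year: hourly reconstruction with the
cell's own latitude (longitude is irrelevant — the model runs in TST),
degree-day accumulation, optional correction, threshold date; then mean,
inter-annual SD (ddof = 1, requiring ≥ 2 reached years) and reached-year
count across years. Cells are processed independently, so any chunking or
ordering yields identical results. Cells above 1500 m a.s.l. (configurable)
are flagged high-altitude: a generic plain-land calibration is unreliable
there. Grids are NetCDF (time, lat, lon; cell-centre coordinates,
north-up; NaN as no-data); the CLI also writes a PNG quicklook.

## Synthetic data

The generator emulates a Swiss-plateau-like station: annual mean 9 °C,
seasonal amplitude 9 °C (warmest mid-July), diurnal range 8 ± 3 °C,
AR(1) day-to-day anomalies (rho 0.7, marginal SD 2 °C) on Tn and Tx,
hourly values from the diurnal model at a known triple plus i.i.d.
Gaussian noise (default SD 0.5 °C). A Bernoulli 30% of days are overcast:
their diurnal cycle is flattened (factor 0.3), they optionally receive a
tent-shaped afternoon cold intrusion that moves the minimum past noon
(emulating the sizeable real-world share of afternoon minima on disturbed
days), and their radiation ratio is drawn below the 0.9 threshold (clear
days above it). The daily series reports the generating Tn/Tx on clear
days and the distorted curve's own extrema on overcast days, as a real
archive extracted from hourly data would; the generating forcing is
returned separately as ground truth. All randomness flows from one seed
(per-site streams are spawned from it), so outputs are byte-identical
across runs.

What the generator does *not* emulate: fronts and persistence beyond
AR(1), humidity/radiation coupling, instrument drift, topographic shading.
Passing tests therefore demonstrate correctness of the algorithms under
controlled, model-consistent conditions — not skill on real station data.
One visible consequence: the fitted end-of-year correction factor on
synthetic data is close to 1 (the clear days are exactly model-shaped, so
there is no systematic afternoon warm bias to remove), whereas on real
data the same estimator yields values slightly below 1.

Synthetic grids are one station-style daily series shifted cell-wise by a
lapse rate (default −0.65 °C / 100 m) times the elevation anomaly, over a
smooth synthetic relief — a deterministic elevation gradient that makes
threshold-date monotonicity testable.

## Problem sizes

The test suite and the acceptance script run multi-year single-station
studies (2–3 years), 20-replicate noisy-recovery experiments at 100
calibration days each, and 20 × 20-cell, 2–3-year grids; these sizes give
sub-percent Monte-Carlo spread on every reported fraction while keeping a
full run in the minutes range on one core.

## Known limitations

* The literal night-branch variant is provided for comparison only; all
  identities and tests target the force-through form.
* f_corr is a single multiplicative end-of-year factor; it cannot fix
  seasonally varying bias.
* The clear-sky classifier needs complete 24-hour days; days failing that
  are excluded rather than imputed.
* The efficiency statistic conditions on both series reaching the
  threshold; its denominator shrinks for high thresholds in cool years.
* No sub-daily interpolation of humidity or radiation; temperature only.
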