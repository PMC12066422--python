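# Methods

## Model structure

The simulator is a whole-body, perfusion-limited PBPK model: 14 tissue
compartments connected in parallel between an arterial and a mixed-venous
blood pool, with the lung in series (venous → lung → arterial).  Distribution
into each tissue is flow-limited; tissue drug is assumed at equilibrium with
emergent blood through a tissue:blood partition coefficient.  The state
vector is the drug amount (mg) in the oral depot, each tissue, venous and
arterial blood, plus a cumulative-elimination compartment that closes the
mass balance exactly.  The system is linear and time-invariant between dose
events; oral doses are exact impulses to the depot with the integrator
restarted at each dose time.

Key structural choices, made where the published description is silent:

- **Elimination site.** Only a whole-body apparent clearance is available, so
  elimination acts on venous *plasma* concentration from the venous pool:
  rate `CL_app · (A_VEN/V_VEN)/bpr`.  Bioavailability is fixed at 1; any
  first-pass loss is absorbed into the calibrated clearance.
- **Absorption routing.** Depot → gut tissue via first-order `gi_ka`, with no
  portal/first-pass routing: the compartment structure is strictly parallel,
  and we implement exactly that.
- **Partition-coefficient dialect.** The tabulated `Kp` are tissue:plasma;
  the rate equation needs tissue:blood.  We convert with the blood-to-plasma
  ratio, `KpB = Kp · Kp_scaler / bpr`, applying the scaler to the
  tissue:plasma value (the convention in which the scaler is tabulated).
- **Missing tissues.** Only 11 tissues have tabulated `Kp`.  Stomach borrows
  gut's value, pancreas borrows spleen's (adjacent splanchnic organs with
  similar perfusion character), and rest-of-body uses the mean of the 11
  tabulated values.
- **Vss metadata.** The tabulated `Vss_per_kg` is carried as metadata (it
  belongs to the clearance-derivation formula); the simulated distribution
  volume emerges from `ΣV_T·Kp` and is tuned via `Kp_scaler`, not by forcing
  Vss.

## Reference physiology

The physiology of the single virtual healthy subject behind the published
parameter sets is not itself published, so the package defines its own
documented reference adult (70 kg), assembled from conventional
reference-human tables:

| tissue | V (L) | Q (L/h) | | tissue | V (L) | Q (L/h) |
|---|---|---|---|---|---|---|
| lung | 0.50 | 336.0 | | liver | 1.80 | 21.84 |
| heart | 0.33 | 13.44 | | stomach | 0.15 | 3.36 |
| brain | 1.45 | 40.32 | | gut | 1.65 | 47.04 |
| muscle | 29.00 | 57.12 | | bone | 8.50 | 16.80 |
| adipose | 14.30 | 16.80 | | kidney | 0.31 | 63.84 |
| skin | 3.30 | 16.80 | | rest of body | 2.00 | 28.56 |
| spleen | 0.18 | 6.72 | | pancreas | 0.10 | 3.36 |

Cardiac output is 336 L/h (5.6 L/min whole blood); total blood volume 5.2 L
split venous:arterial 3:1 (3.9 / 1.3 L).  Rest-of-body takes the residual
flow fraction so non-lung flows sum to cardiac output by construction; total
perfused volume is 68.77 L.  Volumes and flows scale linearly with body
weight (simple allometry — adequate for a single-reference-subject use).
Any internally consistent set can be substituted via a YAML override, which
is validated against the same invariants (14 tissues, positivity, flow
balance).

## Compound parameters and calibration

Five compound records are built in, transcribed from published parameter
sheets: molecular weight, fraction unbound `f_up`, blood-to-plasma ratio
`bpr`, absorption constant `gi_ka` (1/h), apparent clearance `CL_app` (L/h),
`Vss` per kg, 11 tissue:plasma `Kp` values with a per-compound `Kp_scaler`,
and IC50s toward CYP11B1/CYP11B2 (nmol/L).  The standard derivation formulas
(`f_up = 1 − ppbr`; `CL_app = Vss·0.693/t½`;
`log10 Peff = 0.6795·log10 Papp − 0.3355`; `gi_ka = 2·Peff/r` with
small-intestinal radius 1.25 cm) are exposed for user-supplied compounds.
The permeability regression operates in the as-published units of its source
data, which are not fully specified; it is implemented exactly as printed
and documented as such.

Molecular weights from SMILES use RDKit for parsing and implicit-hydrogen
counting, with masses summed from the conventional (IUPAC 2007) average
atomic-weight table; this is the table consistent with the published
per-compound weights at two decimals.

Calibration multiplies `Kp_scaler` by 0.85 and divides `CL_app` by 4.7 —
the factors obtained by fitting the model drug to observed clinical
exposure — applied uniformly to all compounds.  `calibrate_to_observed`
reproduces this workflow as a deterministic grid search minimising RMSE
between simulated and observed concentrations (ties break toward the
smallest `kp_factor`, then smallest `cl_divisor`).

Two published after-calibration entries are inconsistent with exact
recomputation from their own inputs by one unit in the last decimal
(a clearance of 14.83/4.7 = 3.155 printed as 3.15; a scaler of
0.91·0.85 = 0.7735 printed as 0.78); the package keeps full precision
internally and reports rounded values, and its regression tests assert
agreement within one unit of the printed precision.  Similarly, one printed
selectivity index (149) disagrees with the ratio of its own printed IC50s
(310/2.1 = 147.6); the library stores the IC50s and always computes the
ratio.

## Numerics

- Integrator: LSODA (stiffness-switching) with the constant system matrix
  supplied as the analytic Jacobian; `rtol 1e-8`, `atol 1e-10`, fixed per run.
- Output grid: 0.1 h by default (dense enough that linear-trapezoid AUC is
  insensitive to the quadrature rule); samples at a dose time are post-dose.
- Mass balance (depot + tissues + blood + eliminated = administered dose)
  holds to ~1e-13 relative and is asserted at 1e-6 in tests.
- Negative states beyond 1e-9 (relative) abort the run; smaller excursions
  are clipped to zero.
- NCA: linear-trapezoid AUC with interpolated window boundaries; terminal
  half-life from an OLS fit of log concentration on the last 5 post-peak
  samples (configurable); Cmax takes the earliest maximal sample.
- R² is reported about the observed mean and is NaN (with a warning) for a
  constant observed series.

## Study designs

SAD and MAD (24 h interval) dose grids are built in: {0.5, 1, 3, 10, 30} mg
for four compounds; Lorundrostat uses its clinical grids ({5, 10, 20, 50,
100} mg SAD; {3, 12.5, 50, 100} mg MAD).  MAD designs simulate 10 doses —
beyond five half-lives of the slowest calibrated compound, so the last
interval is at steady state — plus a 48 h washout used by the
terminal-slope fit.  PK endpoints (AUC0-24, Cmax, Tmax, T1/2) are reported
for the first and last dosing intervals; the 2-fold acceptance rule
(predicted/observed ratio within [0.5, 2], boundaries inclusive) judges
predictions against observations.

Because the steady-state summary underlying published inhibition claims is
not specified, the PD summary reports peak, trough and interval-average
inhibition for both enzymes rather than committing to one.

## What the tests do and do not show

The verification suite rests on analytic oracles for the linear model: total
mass conservation, dose proportionality, SAD-superposition equal to MAD, the
Bateman (one-compartment oral) solution recovered in the high-flow uniform-Kp
limit, and the constant-infusion steady state `Css = R/CL` — all at 0.1 % or
tighter.  Calibration recovery is demonstrated by regenerating observations
from known factors (exact recovery noiseless; within one grid step under 5 %
multiplicative noise at a fixed seed).  These establish correctness of the
implementation, not predictive accuracy in humans: reproduction of observed
clinical exposure is tolerance-based (the 2-fold band) because the original
virtual subject's physiology is unpublished, and observed concentration
curves exist only as figures, so goodness-of-fit metrics are exercised on
synthetic pairs.

## Known limitations

- Linear kinetics only: no saturable clearance, transporters, or
  enzyme-mediated interactions; no inter-individual variability.
- Oral route only (constant-rate infusion exists solely as a test harness).
- IC50 inputs mix species/assay provenance (recorded per compound in the
  record's provenance map); cross-species extrapolation caveats apply.
- The ML layer that predicted the ADME parameters upstream is out of scope;
  records come from the built-in sheets or user-supplied files via the same
  validated interface.
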