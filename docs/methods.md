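# Methods

This note documents the models, estimators, default parameters and design
choices behind `capkin`, and what the synthetic experiments do and do not
show about real data.

## The kinetic model

Pointed-end depolymerization is modeled as a homogeneous Poisson process:
each subunit loss is an independent event at rate `v` (subunits/s), and the
pointed-end coordinate steps back by the subunit rise (2.7 nm/subunit,
standard actin filament geometry) per event.  The condition rates default
to the values the study anchors:

| parameter | default | meaning |
|---|---|---|
| `v_sat` | 13 subunits/s | cofilin-decorated end at saturating CAP |
| `v_cof` | 13/30 ≈ 0.433 subunits/s | cofilin-decorated end, no CAP (~30-fold below saturation) |
| `v_bare` | 0.13 subunits/s | bare ADP-actin end (~100-fold below saturation) |
| `Kd` | 0.978 µM | CAP–pointed-end dissociation constant |
| `kon_eff` | 0.512 /s | pseudo-first-order association rate (kon·[CAP]) |
| `koff` | 2.5 /s | unbinding rate (residence 0.4 s) |
| `lambda_sev` | 0.005 /µm/s | severing rate per filament length |
| `subunit_rise` | 2.7 nm | length change per subunit |

The CAP concentration dependence is first-order saturation,
`v(C) = v_cof + (v_sat − v_cof)·C/(Kd + C)`.  `kon_eff` is chosen so the
equilibrium pointed-end occupancy `kon_eff/(kon_eff + koff)` equals the
observed 17% bound-frame fraction; `koff` is the inverse of the observed
0.4 s residence.  `lambda_sev` is not printed anywhere in the source
material; 0.005 events/µm/s is a realistic single-filament cofilin
severing frequency (order 10⁻³–10⁻² at sub-µM cofilin) and only scales the
severing demonstrations, not any recovered constant.

CAP binding at the pointed end is a continuous-time two-state Markov chain
(unbound ↔ bound).  All stochastic simulation is event-driven with exact
exponential waiting times from a single seeded generator per call, then
sampled on the imaging frame grid — there is no Δt discretization bias in
the ground truth, and identical (parameters, seed) give bit-identical
output.  Binding traces start in the stationary state, matching a chamber
that equilibrates before acquisition; starting all filaments unbound would
depress the bound-frame fraction by ~3% relative at the default rates.

## The imaging model

Filaments are rendered straight (microfluidics-aligned geometry), anchored
at the barbed end.  A fixed random subset of subunits (default 10%,
matching the labeling fractions used experimentally) carries a
fluorophore; labeled positions are binned into pixels (default 100 nm),
convolved with a Gaussian PSF (σ = 130 nm) and overlaid with Gaussian
camera background (mean 100, SD 5 counts; 50 counts per fluorophore).
Depolymerization movies default to 1 s frames; stream acquisitions to
5 frames/s over 12 s (60 frames).  Pixel size, exposure and frame interval
for the depolymerization assays are not stated in the source material, so
these defaults are explicit, configurable choices.  There is no
photobleaching, filament bending or barbed-end dynamics.

## End tracking and rate estimation

Each kymograph row is median-smoothed (3 px), split into plateau and
background by an isodata-style iteration, and the end placed at the
sub-pixel linear interpolation of the half-maximum crossing.  Rows whose
plateau-to-background contrast falls below 4 background SDs, or with no
above-threshold pixels, are flagged rather than used.  Pure-noise rows
reach a contrast of ~2.7 SDs, so the floor of 4 cleanly separates
"no filament" from real signal at the default SNR (~37).

Rates come from ordinary least squares on the unflagged trajectory with
one pass of MAD-based outlier rejection (3×1.4826×MAD).  Trajectories
containing pauses or severing steps are discarded with a reason, which
operationalizes the manual exclusion applied to real kymographs:

* a **severing-like break** is a two-segment fit that cuts the RMS
  residual by >40% and implies either a position jump at the breakpoint or
  a >3-fold slope change whose displacement is resolvable;
* a **pause** is a three-segment (slope/flat/slope) fit that cuts the RMS
  by >40% with a middle slope below a third of the outer slopes and a
  resolvable position deficit.

"Resolvable" means exceeding 7× the combined scale of residual noise and
the Poisson fluctuation `sqrt(rise·|v|·τ)` that constant-rate shortening
itself produces over the window τ.  Without that guard the rule discards
slow, staircase-like trajectories wholesale and biases slow-condition
rates upward by survivorship; at 7σ (chosen above the look-elsewhere level
of the breakpoint search) the false-discard rate is ~13% on slow
conditions with a residual ~+3% survivorship bias, while a genuine
20-frame pause sits at ~16σ and is always caught.

For speckle-limited sparse labeling the per-frame tracking error is set by
the ~27 nm mean spacing of fluorophores, not by camera noise; per-frame
RMS is then ~0.7 px, while slopes remain unbiased (the tracked edge
follows labeled subunits whose removal rate equals the true rate).  With
dense labeling per-frame RMS is well under 0.5 px.

Movie durations in the bundled experiments are chosen per condition so
each filament loses ~200 subunits (clipped to 60–1800 s): slow conditions
need the longer observation for the speckle edge to traverse several
pixels, exactly as slow real assays are recorded longer.

## Binding-event analysis

One detection threshold is used for every filament and both ends:
background + 3 SD, with background statistics pooled over all end traces
by median/MAD (robust to the sparse bound frames).  Contiguous
above-threshold runs are events; a run touching the final frame is
right-censored; a single-frame event is retained (minimum resolvable dwell
= one frame interval).  The pointed end is the end with more events, ties
broken by total above-threshold time, double ties left unassigned.

Dwell durations are frame counts times the frame interval.  The
single-exponential unbinding fit (`fit_unbinding`) maximizes the
likelihood of the discretized, censored dwell distribution: with per-frame
survival `p`, `p̂ = S/(S + n_unc)` where `S = Σ_unc(K−1) + Σ_cens K`, and
`koff = −ln p̂ / Δt`.  This removes the quantization bias of treating
frame counts as continuous durations (the continuous censored MLE would
overestimate the 0.4 s residence by ~27% at 5 frames/s).

One bias remains in any dwell-only estimator: an unbound gap shorter than
one frame leaves no unbound sample, so consecutive events merge and the
dwell fit converges to `−ln(p_bb)/Δt` — ~0.425 s instead of 0.400 s at the
default rates.  `fit_two_state` removes it: the frame-sampled chain is
Markov with transition matrix `exp(QΔt)`, so estimating both `p_uu` and
`p_bb` from transition counts and inverting
`p_uu + p_bb − 1 = exp(−(kon+koff)Δt)` recovers `koff` exactly.  The
pipeline reports the two-state estimate as its residence time and keeps
the dwell-survival fit alongside for comparison with the classical
analysis.

## Saturation fit and derived quantities

`fit_first_order_saturation` is nonlinear least squares (scipy) with Kd
fitted on a log scale to enforce positivity, deterministic initial guesses
(v0 = min rate, vmax = max rate, Kd = concentration nearest the
half-range), optional 1/SD² weighting, and explicit unidentifiability
flags (flat response, or Kd beyond the sampled range) instead of silent
numbers.  Fold changes carry delta-method SEs; subunits-per-association is
the product `vmax × residence` with propagated error.

## Severing statistics

The cumulative events-per-µm statistic is evaluated exactly as written,
with the denominator taken from the length table at the event's frame
(lengths shrink while the assay runs).  Domain survival uses the
product-limit (Kaplan–Meier) estimator via lifelines; "severed" is the
event and loss to another domain's severing, merging, or end of
observation are right-censoring.  The reannealing ratio uses the exact
Clopper–Pearson binomial 95% CI (beta quantiles), preferred at the small
counts typical of these experiments.

## Structure metrics

Structures are read with gemmi (PDB/mmCIF, multi-model); waters are
dropped and the highest-occupancy altloc conformer kept.  Superposition is
Kabsch (SVD, with proper-rotation correction).  The twist angle superposes
the target actin on the reference's inner domain (subdomains 3+4, Cα) and
reports the rotation angle of the best-fit transform carrying the
reference outer domain (subdomain 1) onto the target's; subdomain ranges
default to the canonical actin convention (SD1 = 1–32, 70–144, 338–375;
SD2 = 33–69; SD3 = 145–180, 270–337; SD4 = 181–269) and are configurable,
with an 80% Cα coverage floor.  Contacts use heavy atoms only (crystal
inputs lack hydrogens; this keeps crystal and trajectory inputs
comparable) at a default 3 Å cutoff; a contact frame count sums
contacting residues over both chains, and ensemble frequencies are
computed after an equilibration skip expressed in frames (with an
ns↔frame conversion helper for the 500 ns convention).  SASA is an
in-package Shrake–Rupley implementation (golden-spiral point mesh, Bondi
radii, 1.4 Å probe, 960 points by default — within 1% of convergence);
buried area is `(SASA_A + SASA_B − SASA_AB)/2`.  Clashes are heavy-atom
pairs closer than the Bondi radius sum minus 0.4 Å, the common steric
convention; the study shows clashes graphically without a numeric
criterion.

## What the synthetic experiments do and do not show

Passing recovery tests demonstrates that the estimators are correct and
calibrated under the stated generative model: Poisson shortening, a
memoryless two-state binding chain, static straight filaments, Gaussian
noise, no photobleaching or drift.  They do not validate the model against
real microscopy (filament bending, uneven illumination, bleaching,
non-exponential dwells from hidden states), and the structural pipeline's
agreement with deposited coordinates is only exercised where such a file
is supplied locally.  The buried-area check against the deposited crystal
structure additionally absorbs method differences between SASA
implementations of a few percent.

## Numerical conventions

Seeds: every simulation call takes one integer seed for a dedicated
`numpy` generator; experiment drivers derive child seeds through
`SeedSequence` so runs are reproducible end-to-end and embarrassingly
parallel.  Degenerate inputs raise informative `ValueError`s rather than
returning silent numbers (zero-length chains, flat saturation data,
alternating-state sequences faster than the frame rate, severing events at
zero total length).  Tie-breaks: pointed-end assignment falls back from
event count to total bound time to "unassigned"; altlocs resolve to the
highest occupancy; the isodata row threshold iterates four times from the
min/max midpoint.
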