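# capkin

Single-filament kinetics and structural metrics for CAP-driven actin
pointed-end depolymerization.

Cyclase-associated protein (CAP) binds the pointed end of cofilin-decorated
actin filaments through its N-terminal helical-folded domain (HFD) and
accelerates their depolymerization roughly 100-fold over bare ADP-actin
filaments (~30-fold over cofilin alone), removing on the order of five
subunits per binding event.  `capkin` re-implements, as a tested and
reusable pipeline, every quantitative analysis behind that finding:

* **Kymograph kinetics** — build space–time images from TIRF/microfluidics
  movies, track the shrinking pointed end with sub-pixel precision, and fit
  depolymerization rates with a principled pause/severing exclusion rule.
* **Pointed-end binding** — detect binding events at both filament ends from
  fluorescence traces with a single self-calibrating threshold, assign the
  pointed end by the most-events rule, and estimate the unbinding rate
  `koff` from censored, frame-quantized dwell times (and, bias-free, from
  the sampled two-state chain itself).
* **Concentration response** — first-order saturation fits
  `v(C) = v0 + (vmax − v0)·C/(Kd + C)` for the dissociation constant `Kd`,
  fold changes with delta-method errors, and the subunits-per-association
  product `vmax/koff`.
* **Severing statistics** — the cumulative events-per-µm statistic
  `f(t) = Σ_{u≤t} N_sev(u)/Σ_i l_i(u)`, Kaplan–Meier survival of single
  cofilin domains, and the two-color reannealing ratio with an exact
  binomial CI.
* **Structure metrics** — Kabsch superposition, the actin outer-domain
  twist angle (superpose on subdomains 3+4, measure the subdomain-1
  rotation), inter-chain residue contacts at a 3 Å cutoff over MD-style
  ensembles, buried interface area by Shrake–Rupley SASA, steric-clash
  detection and named atom distances, for PDB/mmCIF inputs.

Because the raw laboratory data cannot be regenerated at a desk, the
package ships a first-class **synthetic generator** that emulates the
experiments with exact event-driven stochastic kinetics (Poisson subunit
loss, a two-state binding chain, severing fields) and a forward imaging
model (partial fluorescent labeling, Gaussian PSF, camera noise).  Every
analysis stage is validated by recovering the generator's ground truth.

## Worked example

Simulate five filaments depolymerizing under cofilin + 3 µM N-CAP, render
their movies, and estimate the rates from the images:

```bash
capkin simulate depol --seed 1 --n-filaments 5 --cap-conc 3 \
    --duration 100 --out sim/
capkin analyze-depol --in sim/ --out rates.csv
```

`rates.csv` then contains one row per filament, e.g.

```
filament_id,slope_nm_s,rate_sub_s,fit_residual_nm,n_frames_used,discarded,reason
filament_000,-25.48,9.44,61.4,101,False,
filament_001,-25.40,9.41,52.0,96,False,
filament_002,-26.31,9.75,61.1,90,False,
...
```

A rate near 9.7 subunits/s is what the saturation model predicts at 3 µM
(`v(3) = 0.43 + 12.6·3/(0.98+3) ≈ 9.9` subunits/s); the residual is the RMS
deviation of the tracked end from the fitted line in nm.  The same
library calls are available from Python (`capkin.pipeline`,
`capkin.kymo`, ...), and `capkin analyze-binding`, `capkin
analyze-severing`, `capkin fit-saturation` and `capkin structure
contacts|twist|interface|clashes` cover the other analyses.

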