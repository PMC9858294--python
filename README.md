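# mortnet

Monthly all-cause death counts of neighbouring regions fluctuate in
striking synchrony. `mortnet` is a Python toolkit for modelling that
synchrony — the between-region **correlation network** of monthly
mortality — from two mechanisms: the U-shaped (biphasic) effect of
ambient temperature on mortality, and the exchange of an infective
mortality component between regions through traveller flux. It is aimed
at epidemiologists and modellers who want a transparent, fully generative
account of regional mortality co-fluctuation, and a baseline for
surveillance of anomalies in that network.

## The model

Counts `n_im` (region *i*, month *m*) are Poisson. Two model layers are
provided.

**Per-region temperature curve.** `lambda_i(T) = e^{-a_c T + b_c} +
e^{a_h T + b_h}` with both slopes positive: a cold arm, a hot arm, and a
mortality minimum at `T_min = (b_c - b_h + log(a_c/a_h))/(a_c + a_h)`.
Fitted per region by Poisson maximum likelihood; subtracting the fitted
curve gives temperature-normalised residual series.

**Flux-temperature network model.** Traveller flux between regions
follows a gravity law, `f_ij = c_ij + kappa_e pop_j GDP_i
e^{-d_ij/d0_e}` (commuters plus an episodic component). Each month an
epidemic starts from one patient zero (placed with probability
proportional to GDP) and spreads for 30 days under a metapopulation SIR
with daytime mixing matrix `phi_ij = f_ij/pop_j` and
temperature-dependent transmission `beta = e^{-a_beta T + b_beta}`
(capped below 1/dt). Expected deaths combine three additive parts:

    lambda_im = pop_i e^{a_h T_im + b_h} + rho0_i + mu R_i(t=30)

— a shared warm-season arm, a region baseline, and a fraction `mu` of
the month's recovered individuals. The `8 + n` parameters are fitted by
stochastic Poisson maximum likelihood (Adam, decaying learning rate,
batched months, sampled patient zeros) with two priors and, in a second
phase, a regulariser pulling the model's between-region correlations
towards the observed ones. See `docs/methods.md` for the full account.

## Worked example

Everything below runs on synthetic data with known ground truth — no
downloads. The generator (`mortnet.synthetic_data`) produces regions,
seasonal temperatures, a gravity-law commuter matrix and Poisson death
counts from the forward model itself.

```python
import mortnet as mn

truth = mn.make_truth(n_regions=8, n_months=108, seed=42)
deaths = mn.generate_mortality_panel(truth, seed=42)
dist = mn.distance_matrix(truth.regions)

# gravity fit of the commuter matrix (truth: kappa=3e-9, d0=150 km)
grav = mn.fit_gravity(truth.commuter_flux, dist, truth.regions)
print(f"gravity fit: kappa={grav.kappa:.3e}, d0={grav.d0:.1f} km "
      f"({grav.n_pairs_used} pairs)")

# biphasic temperature curve for one region
rid = truth.regions.region_ids[0]
fit = mn.fit_biphasic(deaths.row(rid), truth.temperatures.row(rid))
print(f"{rid}: a_c={fit.a_c:.4f}, a_h={fit.a_h:.4f}, "
      f"T_min={mn.t_min(fit):.2f} C")

# how much of the correlation network does temperature explain?
raw = mn.offdiag_summary(mn.correlation_matrix(deaths))
fits = mn.fit_biphasic_panel(deaths, truth.temperatures)
resid = mn.temperature_residuals(deaths, truth.temperatures, fits)
res = mn.offdiag_summary(mn.correlation_matrix(resid))
print(f"raw correlation: {raw['mean']:.3f} +/- {raw['sd']:.3f}")
print(f"residual correlation: {res['mean']:.3f} +/- {res['sd']:.3f}")
```

Output:

```
gravity fit: kappa=3.665e-09, d0=135.2 km (50 pairs)
R00: a_c=0.1038, a_h=0.0676, T_min=12.79 C
raw correlation: 0.913 +/- 0.056
residual correlation: 0.392 +/- 0.153
```

The gravity fit recovers the generating decay length (truth 150 km)
from 50 noisy, partly censored entries. The biphasic fit's cold arm
(`a_c = 0.104`) absorbs the infective winter mortality the forward
model produced, with the mortality minimum near 13 °C. The regional
death series are very strongly correlated (0.913 on average), and
removing the fitted temperature effect cuts that to 0.392: shared
seasonal forcing explains a large part of the network, and the
remainder is the flux-borne infective component the full model is
there to capture.

The full network model is fitted with `mn.fit_full_model` (see
`docs/methods.md` for the protocol) and compared to the data with
`mn.deaths_agreement` and `mn.model_data_agreement`.

## Command line

A thin CLI wraps the library for CSV-file workflows:

```bash
mortnet simulate --n-regions 20 --n-months 108 --seed 7 --out data/
mortnet fit-temperature --deaths data/deaths.csv --temps data/temps.csv --out biphasic.json
mortnet fit-flux --commuters data/od.csv --regions data/regions.csv --out gravity.json
mortnet fit --deaths data/deaths.csv --temps data/temps.csv \
            --commuters data/od.csv --regions data/regions.csv --out run/
mortnet correlate --deaths data/deaths.csv --out corr.csv
mortnet network --corr corr.csv --threshold 0.8 --out edges.csv
```

Real data enter through the same formats: a region table
(`region_id,name,population,gdp,lat,lon`), GHCN-Daily-style station
readings, a long-format origin-destination matrix and wide-format
monthly panels.

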