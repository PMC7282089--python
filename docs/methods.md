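# Methods

## Scope and model

fermflux quantifies how CO2 availability reshapes the anaerobic mixed-acid
fermentation of a succinate-producing thermophile
(*Pseudoclostridium thermosuccinogenes*). The core object is a declarative
stoichiometric ledger of the pathways from phosphoenolpyruvate (PEP) to the
excreted products:

* **succinate** — PEP is carboxylated by PEP carboxykinase (PEPCK; one CO2
  fixed, one GTP ≡ ATP-equivalent gained), then reduced via malate, fumarate
  and fumarate reductase;
* **lactate**, **acetate**, **ethanol** — via pyruvate; acetate and ethanol
  drain acetyl-CoA, which is supplied by pyruvate formate lyase (PFL:
  pyruvate → acetyl-CoA + formate, redox-neutral) and/or
  pyruvate:ferredoxin oxidoreductase (PFOR: pyruvate → acetyl-CoA + CO2 +
  one reduced-ferredoxin electron pair).

Because every branch is linear, the internal fluxes per mol glucose are
fully determined by the molar yields — there is no fitting or optimization:

    v_p   = Y_p            for p in {succinate, lactate, acetate, ethanol}
    v_PFL = Y_formate
    v_PFOR = Y_acetate + Y_ethanol − Y_formate   (acetyl-CoA node closure)

A negative PFOR flux (formate exceeding acetyl-CoA demand) is topologically
impossible and raised as an error; an explicit override clamps it to zero
and rescales PFL instead, for exploratory use with noisy inputs.

The flux vector maps linearly onto eight derived quantities per mol glucose
(production positive, consumption negative): acetyl-CoA turnover, reduced
ferredoxin from PFOR alone, total reduced ferredoxin, NADH, NADPH, total
redox cofactors (their sum, in electron pairs), acetate-kinase ATP alone,
and total ATP-equivalents. Glycolytic cofactors (2 NADH, net ATP per
glucose) are excluded throughout: the analysis compares the PEP-downstream
branches between conditions, where glycolysis cancels. An optional
whole-cell view can be composed by the user but is deliberately not a model
toggle.

## Cofactor assumptions (the toggles)

* `fr_ferredoxin_linked` (default on): fumarate reduction is coupled to
  ferredoxin reduction through the electron-bifurcating NADH
  dehydrogenase/heterodisulfide reductase complex, making succinate cost
  3 NADH and yield 1 Fd pair per mol; off, it costs 2 NADH and no Fd. The
  toggle moves exactly one electron pair between ledgers, so total redox is
  invariant — a property the tests enforce.
* `adh_nadph_dependent` (default on): the alcohol dehydrogenase step uses
  NADPH (acetaldehyde dehydrogenase stays NADH-linked). The exact NADH/NADPH
  split per ethanol shifts the NADH and NADPH rows equally and oppositely
  and cancels in their sum.
* `atp_per_pep_to_pyruvate` (default 1.0): ATP-equivalents credited per
  PEP → pyruvate conversion.
* `malate_shunt_transhydrogenation` (default 0): net NADH → NADPH
  transhydrogenation by the malate shunt per mol glucose, applied identically
  to every condition, so it cancels in between-condition differences.

Hydrogenases are not reactions in the model (no reactor H2 data exists to
constrain them); any net electron-pair surplus between conditions is
reported as a redox surplus presumably discharged as H2, without asserting a
mechanism.

## Yield and growth-rate estimation

Batch yields default to endpoint deltas, Y_p = ΔP / (−ΔS), between the
first sample and the sample of maximal cumulative glucose consumption. This
matches how single per-run yields are conventionally reported, and includes
lactate formed after growth arrest. A `regression` mode (least-squares slope
of product vs cumulative glucose consumed over all samples) is provided for
noisy multi-sample runs: it averages measurement noise (error sd roughly
3–4× smaller at 12 samples than the two-point estimate) but assumes
yield-proportional accumulation throughout, so it is inappropriate for
products with a delayed onset. Base-titration dilution is corrected only
when a dilution-factor column is supplied.

The growth rate is the least-squares slope of ln OD600 vs time. The
exponential window is chosen automatically as the longest contiguous run of
≥3 positive-OD samples with positive slope and R² ≥ 0.999 (fallback:
best-R² run, which returns 0 for constant OD). The positive-slope
requirement exists because the post-stationary OD decline is itself
log-linear and would otherwise compete on window length; the strict R²
works because, at ≤2% multiplicative OD noise, genuine exponential segments
fit with R² ≈ 0.9999 while any window crossing the arrest breaks well below
the threshold.

Chemostat yields are computed per replicate sample as P_out/(S_feed −
S_residual) and averaged with the replicate standard deviation. Samples
taken before three hydraulic retention times flag the profile as not steady
(`meta.extras["steady_state_ok"]`) instead of being dropped, so the user
can override.

The carbon balance converts glucose to C-moles (×6) and counts succinate,
acetate, lactate and ethanol at 3 C-mol each: succinate's fourth carbon is
fixed CO2, and the C1 unit split off for each acetate/ethanol (formate or
CO2) is folded into their coefficient. Formate is therefore a flux marker,
not a carbon-balanced product, and querying its carbon coefficient is an
error.

## CO2 budget

Exogenous supply over a window is flow × CO2 fraction × hours / molar
volume. The molar volume defaults to 22.4 l/mol (standard molar volume),
matching the conventional back-of-envelope arithmetic despite the 60 °C
reactor; it is configurable. Gas–liquid transfer is assumed 100% efficient,
so the supply is an upper bound on dissolved delivery — dissolved
CO2/bicarbonate speciation is out of scope. PEPCK demand per mol glucose
equals the succinate yield (one CO2 fixed per succinate); endogenous
production equals the PFOR flux (one CO2 per turnover). The window length
is a user parameter, never inferred from the data. The self-sufficiency
verdict compares production with demand on the per-glucose basis.

## Synthetic data

The generator emulates the statistical structure of pH-controlled sparged
batch reactors: exponential growth at μ from OD 0.05 until an OD ceiling of
4.0 (or glucose exhaustion), a cosmetic 10%/day OD decline afterwards
(excluded from the growth-rate window by the estimator itself), glucose
consumption coupled to biomass at 22 mM per OD unit during growth plus a
maintenance drain at 20% of the arrest-time rate, and products accumulating
as yield × cumulative glucose consumed. Defaults: 139 mM glucose (25 g/l),
12 samples over 48 h, 1 l/h sparge, 0.5 l working volume. With
`lactate_onset="at_stationary"` lactate accrues only after growth arrest,
scaled so the final amount still equals yield × total consumption —
whole-run estimates then recover the ground truth exactly while the time
course shows the delayed onset. Products are tied to glucose consumption,
not growth; growth- vs non-growth-associated kinetics are deliberately not
modelled, since the pipeline's targets are yields.

Measurement noise is multiplicative Gaussian per measurement (default CV
2%, an HPLC-like convention adopted in the absence of a published error
estimate), truncated at −90%. All randomness uses NumPy's PCG64
(`default_rng`), so fixed seeds reproduce bit-identically across platforms.

The default condition pair uses the reported whole-run yields of the 1% and
20% CO2 sparge conditions, with μ = 0.33 h⁻¹ (CO2-replete, the reported
batch value) and 0.15 h⁻¹ (CO2-limited), i.e. a >2-fold reduction. The
simulator contains no mechanistic CO2-dependent PFL/PFOR switching: that
relationship is what the analysis reports on, not what it assumes. Passing
tests therefore demonstrate estimator correctness and noise robustness, not
biological realism of the trajectories.

## Numerical choices and tolerances

* Acetyl-CoA node closure is enforced to 1e−9 (absolute, mol/mol glucose);
  the matrix and per-reaction-loop summary routes must agree to 1e−12.
* Comparisons against the published two-decimal table use ±0.03, the
  worst-case propagation of ±0.005 rounding of each printed yield through
  the linear map (e.g. NADH = −(3·Y_succ + Y_lac + Y_eth) can shift by
  0.025). Residual ±0.01–0.03 discrepancies against the published entries
  stem from unprinted unrounded yields and are absorbed by that band, never
  re-tuned.
* Monte-Carlo error propagation at 2% CV, 12 samples: endpoint yield
  estimates are ratios of two noisy measurements (relative sd ≈ 2.8%), so a
  yield of 0.56 carries sd ≈ 0.016 — a ±0.03 band then covers ≈94% of
  replicates, not 95%; the regression estimator reduces this to sd ≈ 0.01
  per yield, with a correlated ≈1.3% common-scale component that dominates
  the NADH-scale aggregates (sd ≈ 0.027). The end-to-end test bounds
  (±0.05 for the |value| ≤ 1.1 fields, ±0.09 ≈ 3σ for NADH-scale fields, in
  ≥95% of 200 fixed seeds) were frozen from this propagation analysis.
* Display rounding to two decimals happens only in report tables, never in
  computation.

## Known limitations

* Fluxes are determined, not estimated: no redundancy, no uncertainty
  propagation from replicate yield spread into the cofactor summary (the
  chemostat standard deviations are recorded but not propagated).
* The carbon balance cannot attribute the unaccounted fraction (biomass,
  exopolysaccharides) — it only quantifies it.
* The CO2 budget ignores dissolved-phase chemistry and assumes the printed
  molar volume; both choices favour comparability of the headline
  arithmetic over thermodynamic precision.
* The synthetic generator is phenomenological; it does not model salt
  stress, death/sporulation kinetics, or H2 evolution.
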