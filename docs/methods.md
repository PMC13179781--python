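# Methods

This note records the model structure, parameter conventions, numerical
choices and deliberate design decisions behind `sdf_cea`. The README gives
the short version; this is the reference for anyone auditing or extending
the model.

## 1. State space and transition structure

Each tooth is an independent Markov chain over five states, in fixed order:

| index | state | meaning |
|---|---|---|
| 0 | `NO_CARIES` | caries-free root surface |
| 1 | `ROOT_CARIES` | active root-caries lesion |
| 2 | `ARREST` | lesion arrested at the last treatment visit |
| 3 | `PERSISTENT` | lesion still active after the last treatment visit |
| 4 | `EXTRACTED` | tooth extracted (absorbing) |

Time advances in annual cycles of **two 6-month transitions** over a
19-year horizon (38 half-cycles), starting at age 45 with 21 teeth and
initial root-caries prevalence `p_init_caries = 0.68`.

Within each cycle:

1. **Relabel** (start of every cycle after the first): `ARREST →
   NO_CARIES`, `PERSISTENT → ROOT_CARIES`. Arrest and persistence are
   treated as one-visit outcomes, not durable states.
2. **Natural-history half-cycle**: `NO_CARIES → ROOT_CARIES` with
   probability `p_incidence_nat`; all other states hold.
3. **Treatment half-cycle** (the semiannual visit): `NO_CARIES` stays,
   develops caries (`p_incidence_tx`) or is extracted
   (`p_extract_nocaries`); `ROOT_CARIES` arrests (`p_arrest`), is extracted
   (`p_extract_caries`) or persists (remainder). Extraction occurs only at
   this step.

Structural constraint: NaF varnish is modelled as purely preventive, so
`naf.p_arrest = 0` is enforced by a validator and excluded from the PSA.
Branch probabilities are validated to sum to at most 1 within 1e-12.

The cohort recursion (`markov.run_cohort`) tracks the occupancy vector at
all 39 half-cycle boundaries. An independent vectorized per-tooth
microsimulation (`markov.simulate_microsim`, inverse-CDF sampling) serves
as an oracle: at 100 000 teeth the two agree within 3 binomial standard
errors at every state and time (tested), with observed maximum absolute
occupancy error ≈ 0.004.

## 2. Outcomes, costs and discounting

**Effectiveness.** Each half-cycle a non-extracted tooth contributes
0.5 years weighted by its state utility. Default utilities are 1 for all
live states and 0 for `EXTRACTED` (pinned), so the default effect is
discounted **extraction-free tooth-years**. End-of-step occupancy is used —
no half-cycle correction — discounted at the step's end time `t = k/2`
years with factor `(1 + r)^{-t}`, `r = 0.03/year`.

**Costs.** At every charged treatment visit a tooth accrues its strategy's
application cost (`c_sdf = 39`, `c_naf = 33` US$) times the probability it
is still present at the start of the step, plus a share of the per-visit
costs: oral examination 36, radiography 45, care-assistance/transportation
129 US$. Accounting is controlled by four explicit switches
(`EconomicSettings`), with defaults chosen by the calibration mode search
(§5):

- `cost_allocation = per_visit_shared`: the per-visit total *V* = 210 is
  divided by the 21 teeth and charged per tooth while any cohort mass
  remains (`per_tooth` would charge the full *V* per tooth).
- `charge_schedule = both_half_cycles`: visits are semiannual, i.e. both
  half-cycles of each year are charged (`second_only` models annual
  visits).
- `effect_aggregation = per_tooth_mean`: effects are reported per tooth.
- `cost_aggregation = cohort_sum`: costs are multiplied by the 21 teeth,
  i.e. reported for the whole subject.

The split between effect and cost aggregation is deliberate: the reference
results carry costs on the order of 10⁴ US$ (subject scale) next to
effects below 10 (per-tooth tooth-years). A single shared aggregation
switch cannot reproduce both; two independent switches can, and either can
be changed to obtain fully per-tooth or fully per-subject accounting.

**Comparison.** `economics.compare` reports incremental cost and effect,
the ICER (defined only when both increments are nonzero and of the same
sign; dominance is flagged otherwise), and net monetary benefit
`NMB = λ·E − C` at willingness-to-pay λ = 50 000 US$ per
extraction-free tooth-year.

## 3. Parameters and serialization

All inputs live in one frozen, validated `ModelParameters` tree
(pydantic): transition probabilities per strategy, cost items with
(low, base, high) ranges, economic settings, utilities, and optional PSA
distribution specs keyed by dotted parameter path (e.g.
`transition.sdf.p_arrest`). Parameter sets round-trip through YAML and
through a flat name/value CSV table. `get_value` / `set_value` /
`apply_values` address any scalar by dotted path; `apply_values` validates
only the final state so that jointly-drawn probabilities never trip
intermediate-state validators.

## 4. Sensitivity analysis

**One-way.** The five unit costs are scanned over their (low, base, high)
ranges: SDF application 25–53, NaF application 22–44, examination 27–63,
radiography 34–57, transportation/assistance 97–161 US$. Because both
strategies share identical visit schedules, the shared per-visit costs
(exam, x-ray, access) largely cancel from the *incremental* cost; the
one-way ICER is therefore flat in those three parameters and responds only
to the application costs (rising in `c_sdf`, falling in `c_naf`). This is
a structural property of any model in which both arms incur the same visit
stream, and is a known divergence from reference one-way results whose
implied sensitivities to shared costs are mutually inconsistent (they
imply three different incremental visit counts at once).

**Probabilistic.** Each specced parameter gets a distribution fitted to
its mean and 95% interval: beta for probabilities, gamma for costs. The
fit is exact in the mean and matches both interval endpoints to within a
1e-3 quantile tolerance using a method-of-moments warm start and a 1-D
Brent refinement over log-concentration (beta) or log-shape (gamma); an
infeasible mean/interval combination raises `FitError` rather than
silently degrading. Each parameter draws from its own independent
substream seeded by `SeedSequence([seed, crc32(name)])`, so draws are
reproducible and adding or removing one parameter's spec does not perturb
the others (tested). Jointly-constrained probability pairs
(`p_arrest` + `p_extract_caries`) are proportionally rescaled onto the
simplex if a joint draw exceeds 1.

**CEAC.** For each WTP on a grid, the acceptability of SDF is the fraction
of draws in which its NMB is strictly highest, with exact ties split
50/50. The 50% crossover is linearly interpolated between grid points.
Under the mean-preserving fixture distributions the crossover lands within
a few percent of the deterministic ICER (tested at 10%).

## 5. Synthetic fixture and calibration

The 6-month transition probabilities underlying the reference analysis are
not published, so the default parameter set is a **synthetic calibrated
stand-in** (`data/default_synthetic_params.yaml`, labelled as such). It is
produced by `analysis/01_calibrate_fixture.py`:

- **Free parameters (7)**: `p_incidence_nat` (tied to
  `naf.p_incidence_tx` — the varnish's preventive effect is expressed
  through the natural-history rate it faces), and per strategy
  `p_incidence_tx`, `p_extract_nocaries`, `p_arrest`, `p_extract_caries`,
  within plausibility boxes. The SDF box caps
  `p_arrest + p_extract_caries ≤ 0.90` so the fitted point is interior:
  a boundary optimum at exactly 1 would truncate half of all PSA draws and
  bias their mean.
- **Targets**: the four reference base-case outcomes
  (cost 8863 / effect 1.39 for NaF, 16 660 / 7.73 for SDF), squared
  relative-error loss.
- **Search**: differential evolution followed by a Nelder–Mead polish,
  repeated over the four accounting-mode combinations; the best mode
  (`per_visit_shared` × `both_half_cycles`) and parameter vector are kept.

The fit is good but not within 5% on all four targets, and this is
structural, not an optimizer failure: costs accrue on start-of-step
presence, which is always ≥ the end-of-step occupancy that drives effect,
so any parameter set matching SDF's high effect (7.73 tooth-years ⇒ most
teeth retained for most of 19 years) necessarily pays nearly the full
semiannual visit stream and overshoots SDF's printed cost. The packaged
`data/calibration_report.json` records the achieved values and residuals
(NaF within 2.4%; SDF cost +9.7%, SDF effect −7.1%; fixture ICER ≈ 1665
vs reference ≈ 1229) and the acceptance test verifies the reported
residuals are recomputable from the fixture itself. On self-generated
targets — where the model family contains the truth — the same calibrator
recovers all four observables to within 0.1% (tested), confirming the gap
lies in the target set, not the machinery. The problem is under-determined
(7 parameters, 4 targets), so the fixture is *a* parameter set reproducing
the outcomes as closely as possible, not an estimate of clinical rates.

`synthetic.generate_parameter_set(seed, scenario)` additionally generates
random plausible parameter sets (scenarios `default` / `pessimistic` /
`optimistic`) for testing and exploration. PSA specs are attached
self-consistently: each probability gets a beta spec at concentration
κ = 100 (a moderately informative prior scale, chosen a priori), each cost
a gamma spec, with the 95% interval computed from the fitted distribution
itself so mean and interval are exactly compatible; probabilities outside
(1e-4, 1 − 1e-4) are treated as structural and not varied. The generator
emulates the *shape* of the published evidence base (which parameters are
uncertain, their scales and families), not clinical effect sizes.

## 6. Problem sizes and numerical conventions

All sizes are this package's own defaults: 1000 PSA draws, WTP grid 0–5000
in steps of 50, 100 000 microsimulation teeth, differential-evolution
budget 120 iterations × population 20 for the shipped fixture (60 × 15 in
the recovery test). Probabilities are validated in [0, 1] with branch sums
≤ 1 + 1e-12; distribution fits use 1e-3 quantile tolerance; all currency
is undeflated US$ and all rates annual unless stated. Every stochastic
routine takes an explicit integer seed and is bit-reproducible under it.
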