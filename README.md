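# sdf-cea

Tooth-level Markov cost-effectiveness analysis of semiannual **38% silver
diamine fluoride (SDF)** application versus **5% sodium fluoride (NaF)
varnish** for managing high-risk root caries, from a healthcare-system
perspective with access-related non-medical costs included. The intended
users are health-economics analysts who want a scriptable, testable version
of this decision model: every stage — parameter validation, cohort
simulation, discounting and ICER/NMB arithmetic, one-way and probabilistic
sensitivity analysis — is an importable library function with a CLI and a
set of numbered analysis drivers on top.

## The model

A 45-year-old subject with 21 residual teeth at high risk of root caries is
followed for 19 years. Each tooth evolves independently over five states

```
no caries, root caries, caries arrest, persistent root caries, extracted
```

in annual cycles of two 6-month transitions. The first half-cycle is natural
history: caries-free teeth develop root caries with probability
*p*<sub>inc</sub>. The second half-cycle is the treatment visit: caries-free
teeth stay caries-free, develop caries or are extracted; teeth with active
root caries become arrested (SDF only — NaF varnish is preventive only),
persist, or are extracted. At the start of the next cycle arrested teeth are
relabelled caries-free and persistent teeth relabelled active root caries;
extraction is absorbing. The initial root-caries prevalence is 0.68.

Effectiveness is discounted **extraction-free tooth-years** (each 6-month
step a tooth survives contributes half a year, optionally utility-weighted).
Costs cover the fluoride application per tooth plus per-visit oral
examination, radiography and care-assistance/transportation charges. Both
streams are discounted at 3%/year. For strategies *A* (NaF) and *B* (SDF):

```
ICER = (C_B − C_A) / (E_B − E_A)
NMB_X = λ·E_X − C_X,          incremental NMB = NMB_B − NMB_A
```

with willingness-to-pay λ = US$50 000 per extraction-free tooth-year as the
reference. Parameter uncertainty uses beta distributions for probabilities
and gamma distributions for costs, each fitted to a mean and 95% interval;
1000 Monte Carlo draws feed cost-effectiveness acceptability curves (CEAC).

The exact 6-month transition probabilities behind the published analysis are
not redistributable, so the package ships a **synthetic calibrated
stand-in** (`src/sdf_cea/data/default_synthetic_params.yaml`): probabilities
fitted by derivative-free optimization so the model reproduces the published
per-strategy costs and effects as closely as the cost structure allows. The
fit and its residuals are recorded in the packaged
`data/calibration_report.json`; see `docs/methods.md` for why the published
base case cannot be matched exactly.

## Worked example

```python
from sdf_cea import load_default_parameters, run_base_case

params = load_default_parameters()
result = run_base_case(params)
print(result.to_frame().to_string(index=False))
```

prints (fixture parameters, 19-year horizon, 21 teeth, 3%/y discount):

```
strategy         cost  incremental_cost  effectiveness  incremental_effectiveness        icer           nmb
     NAF  8651.532376               NaN       1.397103                        NaN         NaN  61203.626226
     SDF 18282.635877       9631.103501       7.180596                   5.783493 1665.274594 340747.158970
```

Costs are discounted US$ for the whole 21-tooth subject; effectiveness is
discounted extraction-free tooth-years per tooth. Under the fixture, SDF
buys 5.78 extra extraction-free tooth-years per tooth for US$9631, an ICER
of about US$1665 per tooth-year — two orders of magnitude below the
US$50 000 willingness-to-pay reference, so SDF is decisively cost-effective
(incremental NMB ≈ US$279 500). The probabilistic analysis agrees: running
`python analysis/04_psa_ceac.py` reports that SDF's acceptability crosses
50% at a WTP of ≈US$1669, essentially the deterministic ICER, and SDF is
preferred in all 1000 draws at the reference WTP.

The numbered drivers under `analysis/` run the full pipeline and write
tables under `results/`:

| driver | writes |
|---|---|
| `01_calibrate_fixture.py` | calibrated fixture + calibration report |
| `02_base_case.py` | strategy comparison table, half-cycle trajectories |
| `03_one_way.py` | one-way cost scans (5 parameters × low/base/high) |
| `04_psa_ceac.py` | per-draw PSA results, CEAC table, crossover summary |

The same stages are available as a CLI:
`sdf-cea base-case|one-way|psa|calibrate|generate-fixture --help`.

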