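# greydecision

Grey-system decision analysis for annual cross-country indicator panels:
grey incidence analysis (GIA), the conservative min-max criterion, and
interval grey-number TOPSIS, plus a synthetic panel generator so the whole
pipeline can be exercised and tested without external data.

## The problem

Epidemiologists and health-policy analysts often need to rank which
socioeconomic factors (urbanization, population growth, HDI, access to
energy, unemployment, public health expenditure, ...) move most closely
with a mortality outcome across a small group of countries, from short
annual series — a setting with far too few observations for conventional
regression. Grey system theory treats such systems as partially known and
scores association by the *geometric closeness* of time-series images
rather than by fitted coefficients. This package implements the full
decision chain used in that literature:

1. **Grey incidence degrees** between a reference series x₀ (e.g. CVD
   mortality) and each comparator xᵢ, per country:
   - *Deng's degree* (DD-GIA): with deviations Δ(k) = |x₀(k) − xᵢ(k)| on
     dimensionless images and distinguishing coefficient ζ ∈ (0, 1],

     γ = (1/n) Σₖ (Δmin + ζΔmax) / (Δ(k) + ζΔmax).

   - *Absolute degree* (AD-GIA): with sᵢ the signed area of the zero-start
     image Xᵢ⁰(k) = xᵢ(k) − xᵢ(1),

     ε = (1 + |s₀| + |sᵢ|) / (1 + |s₀| + |sᵢ| + |sᵢ − s₀|).

   - *Second synthetic degree* (SSD-GIA): θ·ε + (1−θ)·γ, the mean of the
     two at the default θ = 0.5.
2. **Conservative (min-max) criterion** on the factor × country matrix
   v(F_k, C_p) of synthetic degrees: select min_p max_k v(F_k, C_p) —
   the country whose *worst-case* association is smallest, the cautious
   choice when the outcome is to be minimized.
3. **Grey TOPSIS**: crisp degrees are coarsened into interval grey numbers
   through a linguistic scale, normalized (benefit/cost aware), weighted,
   and each alternative is scored by its closeness
   ΣD⁻ / (ΣD⁺ + ΣD⁻) to the ideal pattern F^max versus the anti-ideal
   F^min, where the interval distance is
   d(⊗a, ⊗b) = √(½[(a̲−b̲)² + (ā−b̄)²]).

The estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
tooling; thin module-level functions expose each step individually, and a
`greydecision` CLI wraps the pipeline for shell use.

## Worked example

The package ships a worked example (`greydecision.datasets`): the degree
table, decision matrix and TOPSIS distance rows of a published analysis of
CVD mortality and six socioeconomic factors across the eight SAARC
countries, 2001–2017.

```python
import greydecision as gd
from greydecision.datasets import load_example_decision_matrix, load_example_distances

matrix = load_example_decision_matrix()          # 6 factors x 8 countries
out = gd.conservative_minmax(matrix)
print(out.per_criterion_max.round(5).to_string())
print(f"selected: {out.selected_criterion} at {out.selected_value:.5f}")
```

```
Pakistan       0.87709
Bangladesh     0.86363
Maldives       0.85508
Afghanistan    0.85007
Nepal          0.85347
India          0.90057
Sri Lanka      0.90210
Bhutan         0.85891
selected: Afghanistan at 0.85007
```

Each line is a country's worst-case (largest) association degree across
the six factors; the criterion picks the country whose worst case is
smallest. (The example's source also prints a per-country aggregate
vector whose minimum is 0.85005 at Pakistan; the two published inputs
disagree in one cell, and the package reproduces both computations — see
the `greydecision.datasets` docstring.)

The grey synthetic assessment degrees recomputed from the example's
distance rows:

```python
dp, dm = load_example_distances()
for f in dp.index:
    print(f, round(gd.synthetic_assessment_degree(dp.loc[f], dm.loc[f]), 3))
```

```
urbanization 0.463
population_growth 0.295
hdi 0.639
access_to_energy 0.509
unemployment 0.275
public_health_expenditure 0.545
```

A degree near 1 means the factor sits close to the ideal pattern (here:
strong contribution to *reducing* mortality); near 0, close to the
anti-ideal. Ranking these puts HDI first and unemployment last.

End to end on synthetic data with planted association strengths
0.9 / 0.5 / 0.1 (5% relative noise):

```python
from greydecision.simulate import SimulationConfig, FactorSpec

config = SimulationConfig(factor_specs=(
    FactorSpec("factor_a", +1, 0.9, 0.05),
    FactorSpec("factor_b", +1, 0.5, 0.05),
    FactorSpec("factor_c", +1, 0.1, 0.05),
))
panel = gd.generate_panel(config, seed=42)
model = gd.GreyIncidenceAnalysis().fit(panel.to_frame())
print(model.table_.groupby("factor")["ssd_gia"].mean().round(4).to_string())
print(" > ".join(gd.GreyTopsis().fit(gd.build_decision_matrix(model.results_)).ranking_))
```

```
factor_a    0.7580
factor_b    0.6457
factor_c    0.6271
factor_a > factor_b > factor_c
```

The mean synthetic degrees recover the planted strength order, as does the
final grey-TOPSIS ranking.

The same chain is available from the shell:

```sh
greydecision simulate --seed 42 --out panel.csv
greydecision gia --input panel.csv --out gia_table.csv
greydecision minmax --input gia_table.csv
greydecision run --out report/          # full bundle with provenance
```

## Documentation

`docs/methods.md` describes the model assumptions, the tunable parameters
(ζ, θ, the linguistic scale, weights, the distance metric), what the
synthetic generator does and does not emulate, and known limitations.
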