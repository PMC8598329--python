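# Methods

## Scope and model

The package scores the association between a reference annual series
(mortality) and comparator series (socioeconomic indicators) per country,
assembles the scores into a factor × country decision matrix, and ranks
countries (conservative min-max) and factors (interval grey-number
TOPSIS). All three stages operate on geometry — deviations, areas,
interval distances — not on fitted statistical models, which is what makes
them usable on series of 10–20 annual points.

Assumptions baked into the incidence stage:

* Series are annual, gap-free, and at least three points long. Missing
  years are rejected, never interpolated: with samples this small,
  imputation would silently manufacture geometry.
* Deng's degree compares *dimensionless images*; by default each series is
  divided by its first value (initial-value normalization), the standard
  choice for positive economic indicators, so the first value must be
  nonzero. Mean-value normalization and no normalization are available.
* The absolute degree compares *raw* series through their zero-start
  images and assumes unit spacing; it is invariant to translating either
  series but not to rescaling one of them — the scale ratio is exactly
  what it measures.
* Deviation extremes Δmin/Δmax in Deng's degree are taken over the single
  reference–comparator pair. The alternative (global extremes across all
  comparators) couples unrelated pairs and would make each degree depend
  on which other factors happen to be in the panel.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| ζ (`zeta`) | distinguishing coefficient damping Deng's coefficients | 0.5 | the conventional value; bounds the degree below by ζ/(1+ζ) when Δmin = 0 |
| θ (`theta`) | weight on the absolute degree in the synthesis | 0.5 | makes SSD the arithmetic mean of AD and DD, which exactly reproduces the worked example's synthesis column (47/48 rows) |
| `normalization` | preprocessing for Deng's degree | initial-value | dimensionless images starting at 1; absolute degree always sees raw series |
| linguistic scale | crisp → interval coarsening for TOPSIS | five classes: very_low [0, 0.2], low [0.2, 0.45], medium [0.45, 0.65], high [0.65, 0.85], very_high [0.85, 1] | bin edges coincide with class intervals; fully configurable because published grey-TOPSIS tables generally do not disclose their scale |
| weights | criterion weights in TOPSIS | equal | `"gia"` switches to normalized column means of the crisp degree matrix, tying weights to observed association strength |
| metric | interval distance | rms of endpoint differences | a true metric on intervals; reproduces the worked example's closeness degrees from its distance rows |

Values landing exactly on a bin edge go to the *higher* class —
deterministic and conservative (stronger association).

## Numerical and tie-breaking choices

* Identical series give Deng's degree exactly 1 (the Δmax = 0 branch
  returns 1 before any division); exact zero-start coincidence gives the
  absolute degree exactly 1.
* Country rankings break ties lexicographically by label; min-max ties go
  to the first criterion in declared column order. Both rules are
  order-stable so repeated runs produce identical files.
* The assessment degree ΣD⁻/(ΣD⁺+ΣD⁻) is undefined when both sums vanish
  (all alternatives identical); this raises an explicit error rather than
  returning an arbitrary value.
* Cost criteria are flipped to benefit orientation during normalization
  ([ℓ*/ā, ℓ*/a̲] with ℓ* the column's smallest lower bound), so ideal
  patterns are always componentwise maxima.

## TOPSIS monotonicity

Improving one benefit cell of an alternative (both interval endpoints up)
never lowers that alternative's assessment: its distance-to-ideal entry
cannot grow (the ideal is a componentwise max that moves with it) and its
distance-to-anti-ideal entry cannot shrink. Through the crisp path this
additionally relies on the default scale's property that the lower/upper
ratio of class intervals is non-decreasing across classes; with arbitrary
user scales plus ratio normalization the property can fail when an
alternative takes over a column maximum, so the guarantee (and its test)
is stated for the default scale.

## Synthetic panel generator

The generator emulates the *shape* of cross-country indicator panels: per
country a smooth quadratic mortality trend with stationary AR(1) noise
(coefficient 0.6 — annual socioeconomic series are autocorrelated), and
per factor a mixture of the standardized mortality signal with an
independent smooth path, controlled by an association strength s ∈ [0, 1]
and a direction ±1. The planted signal is rescaled by the reference's
standard deviation so the comparator's absolute variation is commensurate
with the reference's; this keeps the association visible to the area-based
absolute degree as well as to Deng's degree, and makes `noise_sd` a
relative noise level (fraction of signal amplitude). At s = 1 with zero
noise the factor is an exact unit-scale affine transform of the reference,
so its zero-start image coincides with the reference's and the absolute
degree is exactly 1.

Seeding: a master seed spawns one substream per (country, factor) pair, so
adding a factor or country never perturbs existing series, and identical
(config, seed) pairs yield byte-identical CSV output. Positivity is
enforced by a post-hoc shift (floor 0.5) rather than a log-transform, to
keep the planted link affine; the shift preserves both zero-start images
and, being applied per series, initial-value images only up to the shift.

Default conditions mirror an 8-country × 17-year (2001–2017) panel with
six factors whose strengths span 0.4–0.9 at 5% relative noise. Problem
sizes used in the distributional tests: the planted-recovery check runs
100 replicates of an 8-country, 2-factor (strengths 0.9 vs 0.1) panel; the
null-exchangeability check 200 replicates with six strength-0 factors; the
full ranking-recovery check uses three well-separated strengths
(0.9 / 0.5 / 0.1) — six closely spaced strengths cannot be reliably
ordered through a five-class linguistic coarsening, which quantizes
nearby degrees into the same interval.

What the generator does **not** emulate: real indicator units or levels
(all series share one magnitude scale), missing data, structural breaks,
cross-country correlation, or measurement revision artifacts. Passing
recovery tests therefore show that the pipeline detects planted geometric
association under idealized panel structure — not that it identifies
causal determinants in real data.

## Known limitations

* Deng's degree with pairwise extremes is invariant to rescaling the
  whole deviation vector: it scores the *profile* of deviations, not
  their size. Two series pairs with proportional deviation patterns get
  the same degree regardless of how far apart they are. The synthesis
  with the (scale-sensitive) absolute degree mitigates this.
* The worked example's ideal/anti-ideal interval table cannot be
  regenerated from its crisp matrix because the source's linguistic scale
  and weights are unstated; it is retained as a shape fixture only, and
  three documented internal inconsistencies of the source tables are
  reproduced verbatim rather than repaired (see the
  `greydecision.datasets` docstring).
* Only evenly spaced series are supported; other incidence variants
  (slope, B/T-mode) and grey forecasting are out of scope.
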