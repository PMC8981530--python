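# Methods

## Cost standardisation

Annual price tables give, per drug strength and calendar year, the total
dispensed tablet quantity and the total net ingredient cost (NIC) — the
basic acquisition cost before fees and discounts, which standardises cost
across prescribers. The average acquisition cost per tablet is
`spend / quantity`. To compare drugs of different potency, costs are
expressed per WHO defined daily dose (DDD: atorvastatin 20 mg, fluvastatin
60 mg, pravastatin 30 mg, rosuvastatin 10 mg, simvastatin 30 mg). Strengths
of one drug-year are pooled by total milligrams — cost per mg times DDD mg —
which is the only pooling that yields a single curve per drug without
arbitrary strength weights. "Quantity" is fixed to mean tablets, and the
strength catalogue (simvastatin/atorvastatin 10/20/40/80 mg, rosuvastatin
5/10/20/40 mg, pravastatin 10/20/40 mg, fluvastatin 20/40/80 mg) is a
shipped default that callers can override.

Money is deflated to constant 2018 GBP by `amount · 100 / index(year)`
using calendar-year GDP-deflator indices (base 2018 = 100). Deflation
applies to money only, never quantities, and a missing year is an error —
no extrapolation. Prices are annual because that is the resolution of
national price statistics; a month is costed at its enclosing year's value.

## Dose equivalence and the comparator policy

Statin doses are graded by the % LDL-cholesterol reduction they achieve,
grouped into intensity bands: low = [20, 30] %, medium = (30, 40] %,
high = (40, ∞) %. The boundaries are read as contiguous intervals on a
continuous scale, so 30 is low and 40 is medium. Substitution onto a target
statin returns the smallest target dose in the source's band (smallest,
because price is monotone in dose, making this the cost-minimising
admissible choice — a tie-break the source analyses leave open); if the
target has no dose in the band, the smallest dose achieving at least the
source reduction; failing that, the largest catalogued dose, flagged
band-unmatched. Records already on the target are untouched. Substitution
swaps agent and strength only — tablet count and duration are kept, since
daily-frequency differences are not modelled.

The policy comparator is a step function: simvastatin strictly before
May 2012, atorvastatin from May 2012 onwards (the cutover month maps to the
post comparator). It is evaluated per record at the record's own issue
month, so a patient whose history straddles the cutover is substituted
correctly on both sides.

The shipped equivalence table is a **synthetic default** assembled from
LDL-reduction percentages commonly cited in the dose-comparison
literature (e.g. atorvastatin 10/20/40/80 mg → 37/43/49/55 %). It is a
reasonable analysis default, not a clinical reference; all correctness
tests use small hand-built tables so nothing depends on these particular
numbers beyond their monotonicity and band coverage.

## Savings scenarios

Scenario 1 (first episode) restricts to records flagged as a patient's
first-ever statin prescription and caps each at 28 days, prorating tablets
by the day fraction `min(days, 28)/days` — a proration that is neutral to
pack-size conventions. Scenario 2 (all patients) includes every record
uncapped; its patient count is distinct patients per year. Both aggregate
by the calendar year of the issue month, deflate at that year, and append a
cumulative row (whose all-patients patient count is distinct patients over
the whole window, not the double-counting column sum). Savings are
`actual − hypothetical`, absolute and as % of actual; a year with zero
actual spend carries an undefined (null) percentage rather than zero.
Savings can legitimately be negative in years where the comparator was not
yet the cheapest same-band option. An optional scale factor blows both
patient counts and money up from sample to national level (off by default);
scaling counts without money would break the table's internal consistency,
so both are scaled.

## Trends and heterogeneity

Initiation market shares are first-episode counts per period (calendar
month or quarter) normalised per period; periods inside the observed span
with no initiations are kept as explicit empty markers. Practice quintiles
rank practices by their share of new patients on the focal statin, with cut
points at ranks ⌈kN/5⌉ and ties broken by practice identifier; group means
are unweighted across practices. Dynamic mode re-ranks every period and is
skipped (with a log notice) when fewer than five practices have any new
patient; fixed mode freezes membership at a baseline quarter (default
Q3-2003, the study window's first quarter) and errors if the baseline is
under-populated. Both granularities are supported because monthly ranking
is the natural definition while quarterly ranking is what small per-practice
counts require in practice; desk-scale runs use quarters.

The switch-away rate takes patients whose record sequence shows a
non-target→target switch and reports the percentage with a later non-target
record within a window of months; patients never prescribed again stay in
the denominator. With no switch events the rate is undefined (None), not
zero.

## The synthetic generator

The generator makes every stage testable without the proprietary
prescription extract and national price series, and makes explicit the
persistence process that a first-prescription-focused extract leaves
implicit.

**Prices.** Each statin has a branded real price per DDD; after patent
expiry the price multiplies by a per-quarter decay factor (default 0.75)
for each completed quarter, floored at 5 % of the branded price — the
stylised generic-entry collapse. Tablet prices scale with strength to the
power 0.8 (sublinear, as flat-pricing across strengths is common), annual
quantities are log-normal (σ = 0.2) around 200k tablets per strength, and
spend is quoted nominal so the pipeline must deflate it. Defaults: branded
£0.80–0.95 per DDD; expiries May 2003 (simvastatin) and May 2012
(atorvastatin) only — the two events that restructured the market.

**Choice.** Practice p holds preferences α(p, s) = σ·z with z standard
normal drawn once per practice (so cohorts with different σ and the same
seed are monotone-coupled). New patients arrive Poisson per practice-month
from a yearly schedule interpolating 1.15M (2004) → 0.78M (2018) scaled by
1/1000 to keep desk-scale runtimes. The initial statin follows
multinomial-logit probabilities ∝ exp(α(p,s) − β·price_per_DDD(s,t) +
γ·1[s recommended at t]), with the recommendation history defaulting to
simvastatin from January 2006 and atorvastatin from May 2014. Defaults
β = 6 (utility per £/DDD), γ = 1.5, σ = 1: chosen once so that the
simvastatin share starts near 0.3, saturates above 0.9 between the
expiries, and falls towards 0.2 by the window end — the qualitative
crossover of the real market. The logit form is the generator's explicit
modelling assumption, not an empirical claim.

**Persistence.** Each patient receives one 28-tablet, 28-day prescription
per month at the statin's modal strength (simvastatin 40 mg, atorvastatin
20 mg, rosuvastatin 10 mg, pravastatin 40 mg, fluvastatin 80 mg) until
discontinuation (geometric, monthly hazard 0.04 ≈ 20-month mean
persistence), switching to the current comparator each month with
probability 0.02. Only the first record is flagged first-episode. A single
integer seed drives one `numpy` generator threaded through all draws in a
fixed order, so output is byte-identical across runs.

**What the generator does not emulate.** No patient covariates, no
secondary-care initiation, no commissioning-group effects, no intolerance
or side-effect-driven switch-away mechanism, no strength mix within a
statin, and no guarantee of matching any published £ figure — passing tests
on synthetic cohorts validates the accounting and the qualitative dynamics,
not the real-data magnitudes, which require the proprietary extracts.

## Verification

The savings accounting is cross-checked against an independent brute-force
oracle (per-record loops, its own re-derivation of the substitution rule)
on random small fixtures to 1e-9 relative; conservation
(actual = hypothetical + savings) and linearity in tablet counts are
property-checked over hundreds of random fixtures; cohorts already on the
comparator are verified to be exact fixed points. Generator structure is
verified by calibration (realised initiation counts within three
multinomial standard errors of the model probabilities at 50,000
initiations) and by a conditional-logit refit recovering β within 15 % with
a correctly signed γ. The quintile-gap check uses a purpose-built dense
cohort (40 practices, ~50 initiations per practice-month) because at the
default 1/1000 volume scale practice-month shares are nearly binary and the
gap saturates regardless of σ.

## Numerical and degenerate-input choices

Tolerances: share sums to 1 within 1e-9; the savings-row identity is
enforced at 1e-6 relative on construction. Missing prices, deflator years
or equivalence rows raise typed errors naming the offending key — never
silent zeros. Empty record sets produce empty series; an empty savings
table cannot be written. The choice-model refit minimises the exact
multinomial negative log-likelihood with BFGS from (β, γ) = (1, 0); the
likelihood is globally convex in (β, γ), so initialisation is not
delicate.

## Known limitations

Annual pricing hides within-year price moves (the cutover-year comparator
price is a year average); the GDP-deflator series is calendar-year; the
all-patients scenario assumes instantaneous, costless switching and is an
upper bound; savings estimates inherit every simplification of the
synthetic generator listed above.
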