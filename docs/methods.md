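# Methods

This note documents the models and procedures implemented in `chemspace`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic validation does and does not
show.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chemical space and combinatorial statistics

A chemical space is a set of substance records (id, formula, first-report
year) over a study window; the snapshot at year *y* keeps records with
first year ≤ *y*, so snapshots are cumulative by construction.  Formulae
are compositions with exact rational coefficients (`fractions.Fraction`);
they are used exactly as given — no reduction to smallest integer ratios —
except inside the retrodiction module (below).  Distinct records may share
a formula: isomers, allotropes and polymorphs are deliberately *not*
deduplicated, because profile multiplicities depend on them.

Element combinations ignore coefficients (H₂SO₄ → HOS).  With *n* known
elements, the theoretical number of combinations of size *s* is C(n, s)
and of size ≥ 2 is 2ⁿ − n − 1; both are exact integers.  These are rough
upper bounds that ignore valency and stability.  The realized fraction
divides the number of *distinct observed combinations* of size *s* by
C(n, s); counting substances instead of combinations is available via
`count="substances"` because the statistic admits both readings.
"Elements known by year *y*" defaults to occurrence in the snapshot
(computable from the data alone); a user-supplied discovery-year table
overrides occurrence, since discovery dates are external scholarship.
Coverage ("*x*% of combinations span *y*% of the space") accumulates
combinations in descending substance-count order, ties broken
lexicographically for determinism.

## Substitutability similarity

The arranged formula of element *e* in formula *F* replaces *e*'s symbol
with the placeholder X and re-sorts all symbols lexicographically,
coefficients preserved.  X sorts as the literal letter X (between W and
Y); any consistent convention would do, since arranged formulae are
compared only for equality, but this one is fixed so golden outputs are
reproducible.

The profile F*x* collects one arranged formula per substance containing
*x* (a multiset; cardinality = number of *x*-substances).  The similarity

s(x→y) = Σ_{f ∈ Fx} mult(f) · [f ∈ support(Fy)] / |Fx|

counts F*x* multiplicities against F*y* *support membership*, not a
multiset-min intersection.  The min-intersection alternative would force
symmetric numerators, which contradicts the asymmetric numerator pairs
this measure is designed to produce; the chosen form is exactly "the
probability that a random compound of *x* remains a known compound under
the substitution x→y".  Values are exact rationals internally; rendering
rounds to two decimals.

SCE networks keep every element with ≥ 1 substance as a node (no
minimum-compound threshold), draw edges to *all* argmax partners (ties are
parallel out-edges, not broken), and draw no edge when the maximum is 0.
Node ranks come from ascending atomic-weight order; elements missing from
the supplied weight table keep their node, get rank −1, and are logged.
The package computes all pairwise numerators in one pass by grouping
profiles on the arranged-formula string; a naive substitute-and-look-up
loop serves as the independent oracle in the tests.

## Convergence, backbone, ubiquity

Overlap between yearly edge sets is |N_x ∩ N_y| / |N_x| (directed pairs,
set semantics); the overlap matrix puts the overlap *from the column year
toward the row year* in each cell, diagonal 1.

A backbone edge i→j with first co-occurrence year *y* (the first SCE
containing both endpoints) and frequency *f* has recurrence
100·f/(end_year − y).  The denominator is the window width as written,
i.e. the year-*y* SCE itself is not counted — an edge present in every
SCE since *y* therefore scores slightly above 100%.  The threshold
comparison is strict ("more than 60%"), and edges first possible in the
final year (zero-width window) are excluded and logged.  Backbone
frequency is per *directed* edge; the unordered-pair report qualifies a
pair when either direction passes.

Ubiquity subsampling draws, for each sample size *s*% (default 5…95 in
steps of 5) and each of `reps` replicates (default 100), a uniform
substance subsample without replacement, rebuilds the max-similarity
relations, and counts appearances of each full-space edge.  Each
(size, replicate) pair gets its own RNG stream spawned from the master
seed, so adding sizes or replicates never perturbs existing draws.
Elements absent from a subsample simply drop out of that replicate's
network.

## Retrodiction under historical atomic weights

For a chemist's weight table A with reference element H (hydrogen unless
the table states otherwise), the ratio (W/A)(e) =
(W(e)/W(H)) / (A(e)/A(H)) is formed from exact rationals.  The rescale
multiplier approximates this ratio by the *simplest* fraction within a
relative-error tolerance τ: the smallest-denominator Farey fraction whose
relative error is ≤ τ, ties broken by smaller error.  Ratios above 1 are
split as α + β (integer α, β ∈ (0,1]) and β is approximated.  The
alternative reading — globally minimal error up to a denominator cap — is
available as `mode="min_error"`.  The default τ sweep is 1%…20% in steps
of 1%.  The multiplier is applied in the (W/A) direction, which preserves
the substance's elemental mass ratios when the formula is re-read under
the chemist's weights and reproduces the doubled-iron Fe₂O₃ → FeO₃
example; the complementary (A/W) ratio is computed and recorded on every
coefficient.

Rescaled coefficients are brought to the smallest positive-integer vector
(multiply by the LCM of denominators, divide by the GCD), which makes
rescaling scale-invariant.  Because that normalization also reduces
already-integer formulae (H₂O₂ → HO), the retro scores compute *all
three* edge sets — the plain year-(y−1) SCE, the rescaled SCE, and the
reference SCE — on reduced formulae, so that an identity weight table
yields exactly the unperturbed network (tp_rate ≡ 1) and score differences
reflect the weight system rather than the normalization step.  Substances
containing elements absent from a chemist's table are dropped from his
space (and counted); an empty result is an error.  The true-positive rate
is |P_τ ∩ P_ref| / |P ∩ P_ref| and the false-positive rate
|P_τ \ P_ref| / |P_τ|; zero denominators are flagged as undefined rather
than coerced.

Ordering agreement between two weight systems is pairwise concordance
over shared elements: the fraction of unordered pairs ranked in the same
order, ties counting as discordant unless tied in both.

Historical weight tables are user-supplied delimited text (chemist, year,
element, weight, reference_element).  The package ships only two
*illustrative* builders — a Dalton-style table anchored at O = 7 on the
hydrogen scale with other weights at roughly half their modern
hydrogen-relative values, and an iron-doubled table — plus
`perturb_weights`, which builds exact-rational test tables with known
recoverable multipliers.  Neither illustrative table is a historical
record.

## Synthetic generator

The generator emulates the gross statistics of a nineteenth-century-style
substance corpus: new-substance counts per year are Poisson with mean
`initial_rate · growth_base^(year − start)`; elements enter on a
configured schedule; combination sizes are drawn from a distribution
supported on 1–8; an isomer channel duplicates existing formulae under
fresh ids; template reuse rises after a turning year, bending combination
diversity downward; and an organic-bias switch up-weights a designated
element subset after a configured year.  Defaults
(`default_config`): window 1800–1868, a stylized 60-element roster with 9
elements available in 1800, `initial_rate` 5 and `growth_base` 1.078
(≈ 11,000 substances by the final year), organic turn and reuse increase
at 1830 — chosen once to match the scale of the historical corpus this
kind of analysis targets.

Ground truth is planted through *templates*: a set of families, one fixed
member and coefficient per family, and one designated slot family.  Each
template event emits a cohort — one substance per included slot-family
member, identical except for the slot element — so cohort members share an
arranged formula by construction.  Slot coefficients are even and globally
unique per template while fixed coefficients are odd, which makes any
arranged-formula match provably intra-template: cross-family similarity is
structurally zero and equally-established siblings tie exactly at the
maximum.  The cost is that slot coefficients act as template tags rather
than chemistry.  Template reuse re-emits a template's families and members
with fresh coefficients, concentrating substances on existing element
combinations without duplicating formulae (duplicates are exclusively the
isomer channel's doing).  RNG streams are split per year, so changing one
year's volume does not reshuffle other years, and output is byte-identical
under a fixed seed.

`PlantedTruth` records the max-similarity pairs the construction implies:
within a family, element *x* is expected to point at every sibling
introduced no later than *x* (later siblings co-occur with *x* in strictly
fewer cohorts and cannot attain the maximum).  On the seeded two-epoch
validation space (12 elements, 4 families, ~2,000 substances) the
full-space SCE recovers the planted pairs; the ≥ 90% bound asserted in the
tests is a documented test threshold, not an external claim.

What passing these tests shows — and does not.  The generator validates
the machinery: that profiles, similarity, networks, backbone, ubiquity and
retrodiction compute what they claim on data with known structure.  It
does not show that real historical corpora have planted-family structure,
template-shaped formulae, or exact similarity ties; real similarity values
are typically small and noisy, and conclusions about real data rest on the
measure itself, not on these fixtures.  The 13-substance toy space is
self-defined with hand-computed expected values and is the package's
worked example, not a reproduction of any published fixture.

## Numerical and interface choices

- All similarity values, spans, overlaps and multipliers are exact
  rationals until the report layer, which rounds percentages and
  similarities to two decimals; machine-readable outputs keep full
  precision.
- Formula text is parsed case-sensitively as plain symbol+count
  concatenation (no Hill ordering); rational coefficients render as
  `p/q` and round-trip.  Unknown symbols name the offending token.
- The Farey search ascends denominators one by one; termination is
  guaranteed because the best order-q error vanishes as q grows.  With
  tolerances ≥ 1% and ratios bounded away from 0 the search stays in small
  denominators.
- Problem sizes in the test suite (random-space oracle checks at ≤ 50
  substances, a ~2,000-substance planted space, subsampling at 20–100
  replicates) were chosen so the full validation battery represents each
  regime while running in well under a minute.
- The pipeline writes a JSON manifest naming parameters, seeds and one
  artifact per stage; stochastic outputs carry their seed in the filename;
  a failed stage aborts with a stage-named error and a FAILED manifest
  marker; the retrodiction stage is skipped (and noted) when no weight
  tables are configured.

## Known limitations

- No structural chemistry: bonds, valence, isotopes, charges and hydrates
  are out of scope; formulae are flat compositions.
- The loader exposes a pluggable record filter but ships no curation
  rules; corpus curation is the user's responsibility.
- Backbone recurrence uses the printed window-width denominator
  (end − first year), which slightly overweights edges relative to a
  count-of-SCEs denominator; values above 100% are possible for
  ever-present edges.
- The ubiquity statistic is defined relative to the full-space edge set;
  edges that only appear in subsamples are not tracked.
- Historical weight systems beyond the illustrative builders must be
  supplied by the user; the package makes no claim about any particular
  chemist's table.
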