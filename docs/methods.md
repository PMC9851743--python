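# Methods

## Scope and data model

The pipeline operates on two inputs.  The *ancestry table* is a
tab-separated file with one row per (study, stage, broad ancestry,
recruitment countries) block, carrying a non-negative individual count;
the dialect's mandatory columns are `STUDY ACCESSION`, `PUBMEDID`,
`STAGE`, `NUMBER OF INDIVIDUALS`, `BROAD ANCESTRAL CATEGORY` and
`COUNTRY OF RECRUITMENT`, with optional `DATE` (publication year) and
`EFO CODES` columns used to place studies in time and in disease areas.
The *publication XML* carries ordered author lists in two dialects: a
structured one (per-author `<affiliation>` elements, explicit
`joint_first`/`joint_last` attributes) and a legacy one in which a
single author-list string carries superscript digits pointing into a
numbered affiliation block, with joint authorship marked by the glyphs
`†` (joint first) and `*` (joint last).  Only explicit flags or glyphs
are honoured; joint-contribution statements in running text are not
guessed at.

Studies map to ten non-communicable disease areas through a static
trait-ontology table (`EFO code → area`); a study joins every matching
area and the pooled `all_traits` category exactly once.  Multi-area
studies are counted once per area because areas are analysed
independently.  The bundled mapping file is a synthetic stand-in (the
real trait-to-area assignment is a supplementary resource not shipped
here) and is user-replaceable.

"Not Reported" is a first-class missingness marker (`NOT_REPORTED`),
distinct from an empty field: such rows are read, counted in the
manifest with a reason code, and excluded from proportion denominators.
Unresolvable affiliations become the `UNRESOLVED` category rather than
being dropped, so every table still sums to one and data loss stays
visible.

## Affiliation extraction

Free-text affiliations are reduced to a tidy corpus: URLs and e-mail
addresses removed, NFKD diacritic stripping, lower-casing, punctuation
runs collapsed to single spaces, and a small versioned stop-word list
applied (generic function words and their Romance/Germanic address
equivalents; terms like "department" and "university" are retained
because they carry signal).  The cleaning function is idempotent.

Entity resolution is staged and never guesses:

1. exact token-sequence match against the country gazetteer (canonical
   names, common aliases, ISO-3 codes), with the *last* match winning —
   postal addresses end with the country.  Two distinct countries tied
   at the same end position are an ambiguity, resolved to UNRESOLVED
   with a warning;
2. state/region → country lookup (US states, UK nations, etc.), an
   offline replacement for the geolocation service a live system would
   call;
3. fuzzy match at normalized edit similarity ≥ 0.92 (configurable),
   ties broken by longer alias, later window, then alphabetical
   canonical name.  The threshold is deliberately high: a miss is
   reported as UNRESOLVED rather than resolved wrongly.

Institutions resolve the same way against a synonym table (longest
alias wins, so "Harvard T.H. Chan School of Public Health" beats any
shorter embedded match).  The synonym table makes canonicalization
choices explicit and editable — e.g. whether a medical school merges
into its parent university is a table entry, not a code rule.

## Author categories and weighting

`first` is the first-listed author plus any joint-first authors;
`senior` the last-listed plus any joint-last; `all` is every co-author.
A single-author paper necessarily occupies all three categories (logged,
as the definitions force it).  Within a category every author has equal
weight 1/|category|, and an author with k affiliations splits that
weight k ways — there is no defensible way to pick a "primary"
affiliation from metadata alone.  Disease-area tables are unweighted
means of per-paper proportions, so a 500-author consortium paper counts
exactly once.  Dominance is this same statistic with institution
values; ubiquity is the share of papers on which an institution appears
at all.  Both are reported per authorship category; rankings truncate
to top-10 with alphabetical tie-breaks.

Participant-side proportions are sample-weighted quotients.  A cohort
of n individuals recruited in m countries contributes n/m to each — the
equal-share assumption used when no per-country breakdown exists.
Discovery and replication stage sizes are summed by default; a config
switch (`stages=('discovery',)`) gives the discovery-only sensitivity
view.  Individuals appearing in multiple studies are not deduplicated
(the metadata cannot support it).

## Gender inference

Given names are normalised (diacritics stripped, compound names split
on hyphens/spaces, first token kept) and looked up in two offline
name–gender dictionaries, each returning label/accuracy/samples, with
country-specific entries preferred and a global fallback.  Accuracies
on a 0–1 probability scale are rescaled to 0–100 at load time so the
two sources are comparable.  Reconciliation: equal labels stand; if
exactly one source is unknown the other wins; men/women conflicts go to
the higher accuracy, ties to the larger sample count, and a full tie is
conservatively unknown.  Initials-only names carry no signal: such
authors are excluded, and when more than half of a paper's authors are
initials (threshold configurable) the whole paper is excluded from
gender analysis, mirroring how whole journals abbreviated author names
in some years.  Excluded authors never enter gender denominators.
Gender proportions default to the same per-paper weighting as
countries; a pooled author-count mode (`gender_weighting="pooled"`) is
available since the two conventions differ for consortium-heavy
corpora.

## Trend tests

The final partially-elapsed calendar year can be excluded from every
trend window (`exclude_year`).  Three estimators are reported:

* **Cochran–Armitage** on yearly success/total counts with linear year
  scores (year minus window start).  The statistic is
  z = T/√Var(T), T = Σ sᵢ(xᵢ − nᵢp̄),
  Var(T) = p̄(1−p̄)(Σ nᵢsᵢ² − (Σ nᵢsᵢ)²/N), two-sided normal p.  The
  closed-form variance is validated in the tests against an exhaustive
  permutation enumeration (all placements of the observed successes
  over individual observations), which differs from it by exactly the
  finite-population factor (N−1)/N.
* **OLS** of the yearly proportion on year — the headline estimator
  because its output shape ("x pp/year, 95% CI") matches how such
  results are conventionally reported.  Unweighted by default (each
  year is one point); yearly-basis weights are a switch.
* **Beta regression** (logit link, constant precision φ) fit by maximum
  likelihood via a `statsmodels` GenericLikelihoodModel subclass (BFGS,
  with a Nelder–Mead fallback polish; start values from a logit-OLS
  fit).  Proportions touching 0 or 1 are squeezed with
  (y·(n−1)+0.5)/n before fitting, and this is flagged on the result.
  The reported slope is the average marginal effect
  (1/T)Σ β₁μₜ(1−μₜ) in pp/year with a delta-method 95% CI; the
  logit-scale slope and SE are carried alongside for calibration work.
  Non-convergent fits raise with the optimizer trace and are skipped
  (with a log line) in batch trend computation.

Chi-square homogeneity tests (Pearson, no continuity correction)
compare label distributions across groups; expected cells below 1
attach a warning.  All tests are two-sided at α = 0.05.

## Synthetic corpus generator

The generator's defaults are the study conditions: 2005–2021, 135
papers/year (≈2300 papers), an authorship country mixture led by the
US (0.37), UK (0.098), China (0.082), Japan (0.066) and Germany
(0.055); a recruitment mixture led by the UK (0.34), US (0.16) and
Iceland (0.096); an ancestry mixture of 91% European and 4.9% East
Asian with six minor categories; women's shares starting at 0.34 (all),
0.30 (first) and 0.25 (senior) with trends of 0, +0.93 and +0.85
pp/year respectively; 10% Not-Reported missingness in both the
ancestry and recruitment-country fields; 3% of papers with
initials-only author names; 20% multi-affiliation authors; 10%
joint-authorship papers; and author counts from a truncated negative
binomial (min 2, mean 12, shape 2, max 40) reflecting the heavy right
tail of consortium papers.  Sample sizes are log-normal (median ≈3000).
Papers before 2014 are emitted in the legacy superscript dialect at a
configurable rate (default: all of them).

All randomness derives from one root seed with documented per-stream
derivation (`default_rng([seed, stream])`; stream 0 is the corpus,
stream 1 the dictionaries, so adding stages cannot perturb existing
draws).  Identical config + seed produces byte-identical files.

Ground truth records *realized* draws, not nominal weights: the
generator computes the exact representation tables implied by what it
actually drew, so recovery tests assert strict equality instead of
statistical closeness.  The generated name dictionaries have a
controlled disagreement structure (3% conflicting labels, 4% unknown in
one source, matching the rates such services disagree at) constructed
so that reconciliation always recovers the drawn gender — which is what
lets end-to-end gender recovery be exact.

What the generator does *not* emulate, and hence what passing tests do
not show: real affiliation strings with typos, department-only
addresses or institutions missing from the gazetteer (recovery on real
text is necessarily below the 100% exact-match regime); PubMed DTD
edge cases beyond the two documented dialects; per-name gender accuracy
structure (real dictionaries are wrong for some names, not just
uncertain); duplicated individuals across studies; and any correlation
between disease area and country/ancestry mixtures (each area draws
from the same global mixtures).

## Numerical choices and conventions

Proportion tables must sum to 1 within 1e-9 (UNRESOLVED included) —
this conservation is asserted over randomized corpora.  Aggregations
run in deterministic input order, so outputs are reproducible to the
byte; the acceptance suite exploits this by requiring the pipeline's
CSV to equal the generator's ground-truth CSV and an independent
straight-loop recomputation exactly.  Empty denominators (no authors in
a category, all entries Not Reported) raise typed errors rather than
returning NaN.  Pipeline outputs are written to a temporary directory
and moved into place atomically, so a failed stage leaves no partial
tables; the manifest records input hashes, a config hash, and per-stage
kept/excluded row counts with reason codes.

## Problem sizes used in the checks

The bundled checks run at deliberately modest scale, chosen to exercise
every code path: oracle equivalence on 200 random toy corpora (≤20
papers, ≤8 authors, ≤3 affiliations); conservation over 1000 randomized
configurations; end-to-end exact recovery over 20 seeded configs
spanning both XML dialects, Not-Reported rates 0–0.3 and
multi-affiliation rates 0–0.5; Cochran–Armitage type-I calibration with
17 years × 200 trials × 1000 replicates (nominal range 0.03–0.07); OLS
recovery of a +0.9 pp/year trend over 500 replicates (bias ≤ 0.1 pp,
CI coverage 92–98%); and beta-regression recovery of a known
logit-slope at 100 replicates against a 3-SE criterion.  The
acceptance script runs the full default-scale corpus (≈2300 papers).

## Known limitations

Name-based gender inference is a proxy with well-known failure modes
and no notion of non-binary identity; the pipeline reports what the
dictionaries support and nothing more.  Country resolution assumes the
last country mention is the host country, which mislabels the rare
affiliation listing a partner country after the host.  Institution
scores are only as good as the synonym table; unmerged synonyms split
an institution's dominance.  Per-capita normalisation of country
contributions is out of scope, as are joinpoint models and
autocorrelation-robust trend errors.
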