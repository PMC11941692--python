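# Methods

## Model and procedure

`convmine` treats a *signature* as an ordered, de-duplicated list of protein
symbols attached to a category label. All downstream quantities are functions
of the binary incidence matrix between proteins and categories, of scored
undirected interaction edges, and of GMT term/universe memberships. The
pipeline stages, in order: commonality statistics → four-way Venn partition
and nested levels → per-level over-representation analysis (ORA) → consensus
interactome expansion of the innermost level → slice-wise enrichment against
a drug-response atlas → common-term intersection and protein frequency
ranking → consensus signature of the top-ranked protein → random-set
intersection nulls for that signature against the expansion and against an
optional partner signature.

Assumptions worth stating explicitly:

- Symbols are compared by exact string after whitespace-strip and
  uppercasing. No alias, ortholog, or nomenclature resolution is attempted;
  an optional user-supplied two-column alias map is applied before
  de-duplication. Unknown symbols are carried through, never silently
  dropped.
- Duplicate symbols within a category are dropped with a warning (first
  occurrence kept) rather than rejected, because machine-extracted lists
  commonly repeat entries.
- Interaction databases are treated as interchangeable evidence sources.
  Association-list resources that record partners of a query without
  pairwise scores are ingested as score-1.0 star graphs centered on the
  query, so they can participate in consensus counting; score thresholds
  bind only on databases that carry scores.
- Proteins may appear both as expansion seeds and as interactors of other
  seeds; seeds found as interactors are retained in the aggregate.

## Level construction

With disease incidence D and mechanism incidence M:

- L5 = proteins with commonality ≥ 2 in D **and** ≥ 2 in M (the all-four
  region of the Venn partition of totals and ≥2-commonality sets).
- L4 = L5 ∪ proteins in exactly three of the four Venn sets.
- L3 = L4 ∪ proteins in exactly one disease and exactly one mechanism
  (both totals, neither multi-membership set).
- L2 = L3 ∪ proteins reaching the commonality threshold in either arm.
- L1 = the union of all observed proteins.

Nesting L5 ⊆ L4 ⊆ L3 ⊆ L2 ⊆ L1 holds by construction and is property-tested
on randomized inputs. Each protein carries an audit code naming the
innermost rule that admitted it.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| commonality threshold k | 3 | categories | The operational convention for "well above mean": with ten 100-protein categories the commonality mean sits near 1.3–1.5 and mean+2·SD lands between 3 and 4, so ≥3 is the smallest integer cut consistently above it. The mean, SD, 2·SD, and mean+2·SD are always reported as diagnostics, under both the sample (n−1) and population conventions, so either reading of a printed "2SD" figure can be checked. `"mean_plus_2sd"` (ceil) is available as an alternative rule. |
| ORA min_overlap | 2 | proteins | A term supported by a single query protein is not evidence of set-level enrichment. |
| ORA alpha | 0.05 | probability | Raw (unadjusted) p drives the inclusion filter; Benjamini–Hochberg q-values are computed behind a flag and never drive filtering. |
| ORA universe | library universe | symbols | The hypergeometric background is always explicit and logged; there is no hidden genome-wide default. |
| interaction min_score | 0.4 | score units | The conventional medium-confidence interaction cutoff. The synthetic generator draws scores uniform(0.15, 1.0), so synthetic configs that must keep every planted edge use 0.15 or 0. |
| expansion min_db | 2 | databases | Independent evidence from at least two sources before an interactor is trusted. |
| null universe N | 20,000 | symbols | Human protein-coding scale, used when no universe file is supplied; always logged, because the analytic expectation n·|T|/N is inversely proportional to it. |
| null n_draws | 1000 | draws | Enough for the empirical mean to sit within a fraction of a percent of n·|T|/N; a 10-draw compat mode reproduces small-n mean ± SEM summaries. |
| combined_metric | (−log10 p) · k | — | A significance-times-support ranking score. Published "combined score" variants differ between engines and are not uniquely defined; this realization is documented rather than guessed, and ranking by raw p is always available. |

## Null models

**Network enrichment.** Two nulls for the expected induced edge count of an
n-node query set: the analytic density null C(n,2)·2E/(N(N−1)) from the
background database, and the default empirical null that resamples same-size
node sets from the database universe and counts induced edges, with p =
(#{draws ≥ observed}+1)/(n_draws+1) so p is never exactly zero. The
proprietary degree-corrected expected-edge models of the public network
servers are deliberately not imitated; the `null_spec` field records which
null produced each figure. Average clustering counts degree-<2 nodes as 0
and includes them in the mean — a stated convention, since excluding them
changes the average.

**Intersection nulls.** Random query sets are drawn uniformly without
replacement (Mersenne-Twister generator) from the explicit universe. The
summary reports the empirical mean ± SEM next to the closed-form
hypergeometric expectation and self-checks their agreement. Student's
equal-variance t is the default for comparing overlap series, with Welch and
paired variants behind flags.

**Discreteness of the ORA test.** The hypergeometric test is discrete: at
nominal α = 0.05 its attainable level is P(X ≥ k*) ≤ α, where k* is the
smallest overlap whose tail drops below α. Calibration is therefore checked
against that closed-form attainable level (and bounded by the nominal
level), not against 0.05 exactly; with 250-symbol queries over a
5000-symbol universe the attainable rate is ≈ 0.04.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *combinatorial* structure of the study inputs:
fixed-size signature collections (default 10 categories × 100 proteins) with
a planted fully-shared core and a tunable probability of re-drawing
previously used symbols; seven interaction databases over a common universe
whose consensus edges appear in ≥2 sources while noise edges stay
database-private; GMT libraries with terms of exact planted query overlap;
and drug atlases with one protein planted at a chosen inclusion frequency
(default 27 of 35 terms). All generators are pure functions of (config,
seed) with byte-identical replay, and symbols are synthetic ("G"-prefixed)
to avoid implying real-gene claims.

They do **not** emulate: realistic interactome topology (degree
distributions, clustering, hubs — consensus edges are uniform random pairs
plus explicit planted stars), literature or annotation bias, symbol
ambiguity between sources, or correlated term composition in real gene-set
libraries. Passing the planted-recovery tests therefore shows the set
arithmetic, consensus logic, and statistics are implemented correctly — not
that any particular biological signature collection will yield convergent
cohorts.

## Numerical choices

- Hypergeometric tails are evaluated through the log survival function and
  exponentiated, stable into the p ≈ 1e-300 range; they are verified against
  exhaustive subset enumeration for every parameter combination with
  N ≤ 12.
- ORA records sort by p ascending, ties broken by larger overlap then term
  label, making output invariant to query and library ordering. Frequency
  rankings break ties lexicographically.
- Degenerate inputs fail loudly: empty categories, empty GMT terms,
  self-loop edges, queries disjoint from the universe, and series too short
  for a t-test all raise, rather than returning NaN.
- All pipeline randomness derives from one master seed via SHA-256 of
  `"<seed>:<stage>"` mod 2^31, so any stage can be replayed independently.

## Test-design scale choices

The brute-force clustering-coefficient check runs over every graph in the
networkx graph atlas (all 1253 graphs on ≤ 7 nodes) plus 200 seeded random
8-node graphs — exhausting all labelled 8-node graphs (2^28) is not
informative beyond that. The ORA calibration uses 1000 random 250-symbol
queries against 30 non-planted terms of sizes 100–400 over a 5000-symbol
universe; the intersection-null check uses the pipeline-scale parameters
(query 321, target 1497, universe 20,000, 1000 draws). The end-to-end demo
runs at the study's native scale (10+10×100 signatures, 7 databases,
35-term atlas) and completes in seconds.

## Known limitations

- No identifier mapping: signatures from sources with divergent symbol
  conventions must be harmonized upstream (or via the alias map).
- The expansion treats every database as equally trustworthy; there is no
  per-source weighting or evidence-type stratification.
- The sampling network null resamples nodes uniformly, not
  degree-preservingly, so hub-heavy query sets inflate enrichment against
  it; the `null_spec` field makes the choice auditable.
- Published figures that depend on dated snapshots of external interaction
  databases and enrichment libraries cannot be regenerated from first
  principles; the package instead guarantees exact recovery of planted
  synthetic structure and exact agreement of every set-arithmetic operation
  with brute-force oracles.
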