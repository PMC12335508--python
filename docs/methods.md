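# Methods

## Molecular graphs and edge partitions

Molecules are hydrogen-suppressed graphs: vertices are heavy atoms, edges
are bonds reduced to topological adjacencies (bond order and element
identity never enter any computation; element labels are carried for
readability only).  This is the convention under which the published
polynomial edge counts match the drug skeletons — metoprolol, for
example, has 19 heavy atoms and, with one ring, 19 edges.

Two partitions of the edge set drive everything: by endpoint degrees
(d_u, d_v) and by endpoint neighbor-degree sums (S_u, S_v), keys stored
sorted (k ≤ l).  Useful identities, both enforced by tests on every
fixture and generated graph: Σ_v d_v = 2|E| and Σ_v S_v = Σ_v d_v²
(each degree d_u is counted once per neighbor).

## Index conventions

The six indices are defined in the README.  Two conventions deserve
note.  First, M1/M2 are computed from the *degree* partition and
NM1/NM2/NH/NSS from the *neighborhood* partition; the published
derivation table formally writes all six as operators on the
NM-polynomial, but the published values (e.g. 84/89 for metoprolol
against 178/427 for the same graph's neighborhood sums) are only
consistent with the split convention.  Second, NSS is read as
Σ m·√(kl/(k+l)) over neighborhood classes; this reproduces the published
28.77 for metoprolol and pins the reading of the derivation row.  The
operator route (Ds, Dt, Ss, St, J on the polynomial) is implemented
independently of the direct sums and the two must agree to 1e-9 relative
tolerance on every graph; the fractional operators listed alongside them
are not needed by any of the six indices and are not implemented.

## Fixture provenance and a non-realizability result

Six drug fixtures (metoprolol, bisoprolol, propranolol, amiodarone,
propafenone, timolol) are the true hydrogen-suppressed skeletons and
reproduce both the published polynomials and the published index rows
exactly.

For the other four drugs the published data are mutually inconsistent,
and we established a stronger fact than mere mismatch: **no simple
connected graph realizes the published polynomials of atenolol, sotalol
or flecainide together with their published M1/M2.**  The proof is an
exhaustive two-phase search: (i) enumerate all vertex-type multisets
(d_v, S_v) consistent with the partition's S-incidence counts, Σd = 2|E|,
Σd² = M1 and the identity ΣS = Σd², for every admissible degree cap
(d_v ≤ S_v bounds the cap by the largest printed S); (ii) complete
backtracking realization of the edge classes over those types with
symmetry breaking.  Every branch terminates with no solution.  The
published carvedilol polynomial is inconsistent in a more obvious way
(it sums to 31 edges and implies NM1 = 333 against the published 360).
The true atenolol/sotalol/flecainide skeletons reproduce the published
M1/M2 exactly but not the published NM-columns, which indicates
hand-tallying slips in the published partitions rather than different
structures.

The carvedilol fixture is therefore an *index-matched synthetic
reconstruction*: a connected simple graph with degree cap 4, found by
simulated annealing, whose six index values equal the published row
(M1=154, M2=180, NM1=360, NM2=1029, NSS→53.58, NH→6.41 at two decimals).
Its file is marked `.synthetic` and says so in a header comment.  The
atenolol, sotalol and flecainide fixtures ship as the true skeletons; the
index table they produce diverges from the published NM-columns of those
three rows, and the reproduce mode reports this as the documented
`polynomial-vs-index-table` divergence.  (An index-matched reconstruction
of those three rows was searched for the same way; within the explored
size/degree envelope none was found, consistent with the rows themselves
being slightly off any graph's attainable set.)

## QSPR stage

Quadratic fits use SVD-backed least squares on the design (1, x, x²)
rather than normal equations — x and x² are nearly collinear at index
magnitudes.  Reported statistics: R² = 1 − SSE/SST, R = +√R²,
adj-R² with p = 2 predictors, F = (R²/2)/((1−R²)/(n−3)) with upper-tail
p on (2, n−3) df, and RMSE = √(SSE/n) (the n-denominator convention;
the published tables never state theirs, so RMSE comparisons are
informational).  Saturated three-point fits report R² = 1 and F = ∞.
Fits are cross-checked against statsmodels OLS in the tests.

The QSPR stage takes the published index table as its input (the same
choice the source study made), because three fixture rows cannot
reproduce the published index values (above).

**Irreproducibility of the published regression tables.**  Fitting the
published index columns against the published property table reproduces
the published coefficient rows exactly for BCF and KOC (all four
Zagreb-family indices; coefficient-for-coefficient to print precision),
but not for the other properties, and for the NSS/NH columns not at all.
The failure is provable, not a tolerance issue: treating the printed
coefficient blocks of the four Zagreb-family indices as OLS solutions
over a common unknown property vector y leads to inconsistent normal
equations — no property column satisfies them simultaneously, however
perturbed.  The study evidently fitted a working property sheet that
differs from its printed property table.  One reconstruction: the
printed polarizability/NH model (52.5421 − 14.6256·NH + 2.2526·NH²) is
the exact OLS solution if flecainide's polarizability is ≈ 40.7 instead
of the printed 34.80.  Our faithful fit of the printed data gives
R² = 0.8812 for that model against the published 0.8913; both values are
reported, and the acceptance suite keeps the strict published-value
assertion (which therefore fails) as the record of this divergence.

## MCDM stage

All six criteria are benefit criteria: the published ideal-best row
equals the column maxima.  The decision matrix fed to the chain is
configurable — recomputed from graphs, a user CSV, or the published
normalized matrix; the last is the reproduction mode, because the
published matrix embeds NSS values for sotalol, carvedilol and
flecainide that contradict the published index table (the documented
`nss-decision-matrix` divergence; started from recomputed indices,
amiodarone attains the ideal in all six criteria and still ranks first).

Entropy weights: the published weight table is reproduced to 1e-6 only
by computing the Shannon expression on the *vector-normalized* (unit
Euclidean norm) columns and taking w_j ∝ |1 − E_j|.  Unit-norm columns
are not probability vectors, so E_j > 1 here and this variant weights
low-dispersion columns slightly more — the inverse of the textbook
sum-normalized method, which is provided as `entropy-sum` but does not
reproduce the published weights.  The implementation reports the
published variant as-is.

TOPSIS separations use the Euclidean distance (the published step
formula prints the radical without the square; only the squared form
reproduces the published separations).  Ranks sort descending with ties
resolved to input order.

**Staged rounding.**  The published chain was evidently computed table
from printed table: reproducing it to the sixth decimal requires rounding
each stage (half-up, 6 decimals) before the next consumes it, with two
refinements found by enumeration of the rounding variants: SAW scores
accumulate unrounded contributions, and closeness divides the rounded
separations.  `staged_rounding=True` (default) implements exactly this;
with it, every published MCDM table is matched to ±1 in the sixth
decimal except the closeness column, which is inconsistent with the
published separations themselves (recomputing L−/(L+ + L−) from the
printed L columns shifts several sixth decimals by up to 4e-6).  The
reproduce mode therefore compares closeness at 1e-5 with the
inconsistency on record; ranks are compared exactly.

## Synthetic generators

All generators are pure functions of a config (NumPy PCG64 seeded from
it).  Graphs: a random spanning tree grown under a degree cap (default 4,
mimicking organic skeletons, whose neighbor sums then stay in the
published range) plus Bernoulli ring-closing edges (default probability
0.1, giving the 0–3 rings typical of these drug skeletons).  Property
tables follow the quadratic generating model with Gaussian noise;
decision matrices are log-uniform positive.  The generators emulate the
*statistical shape* of the study inputs — sizes, degree caps, positivity,
the quadratic mean structure — not chemistry: no valence rules, no
realistic property units, no inter-property correlation.  Passing tests
on them therefore demonstrate correctness of the computations and their
invariants, not predictive validity of QSPR on real molecules.

Default problem sizes keep the whole suite fast: 200 seeded graphs
(5–20 vertices) for the operator-equality property, 500 replicates for
the noisy parameter-recovery check, n = 10 regression points matching
the study's sample size.

## Numerical choices and limitations

* Half-up decimal rounding everywhere a published table is emitted
  (6 decimals for MCDM tables, 2 for NSS/NH), full precision internally.
* Weight vectors must sum to 1 within 1e-12; degenerate entropy input
  (all columns zero-divergence) is an explicit error, as is an edgeless
  graph, a singular quadratic design, and a disconnected or multi-edge
  input graph (reported with line numbers).
* The pipeline treats the ten-drug dataset as fixed; no train/validation
  split is implemented (none is specified anywhere in the source
  analysis, whose tables all use n = 10).
* Figure styling (heatmaps, scatter plots) is out of scope; the numbers
  behind them (correlation matrix, fitted curves) are all emitted as CSV.
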