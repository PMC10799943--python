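# Methods

## The model

TCNB(m,n) is treated purely combinatorially, as a family of simple graphs
specified by its joint degree matrix: four vertex classes (degrees 1–4)
and five edge classes by unordered endpoint-degree pair, each with an
exact integer-coefficient frequency polynomial in the lattice dimensions
(m, n), m, n ≥ 1. All fifteen indices in scope are functions of the
edge-class frequencies alone, so this partition is a complete model for
them; no geometry, periodicity or chemical identity enters any
computation. Frequencies are stored as exact polynomials
(`BivariatePolynomial`, rational coefficients, degree capped at 2 per
variable) and never as floats — every downstream value must be exact, and
the degree cap turns symbol-manipulation bugs into immediate errors
(nothing in scope legitimately exceeds degree 2: the worst case is the
squared edge-count polynomial inside the second coindex identity).

The partition's internal consistency is checked as polynomial identities,
not just at sampled sizes: the handshake lemma (Σ d·|V_d| = 2|E|) and one
stub-balance identity per degree class (d·|V_d| equals the number of
edge-class endpoints of degree d, an intra-class edge counting twice).
All hold identically for the TCNB partition.

A note on the vertex total: the family's published running text states
the atom count with a 32mn term, while the degree classes sum to
33mn + 25m + 25n + 17. The class sum is adopted throughout — it is what
the partition implies, what the ReZG1 closed form equals, and what the
first-coindex values require — and the 32mn variant is carried as an
erratum record rather than silently dropped.

## Graph realization

The published description gives only class counts, so an explicit graph
is constructed to serve as a brute-force oracle. Vertex ids are assigned
contiguously per degree class (degree 1 first). Edge classes are wired in
the order (1,3), (3,4), (2,3), (2,2), (3,3) — most-constrained classes
first: degree-1 and degree-4 stubs belong to a single class each, so
placing them first leaves the flexible degree-3 intra-class edges to
absorb the remainder. Within a class each edge takes the vertex with the
most unused stubs on each side (smallest id on ties), skipping partners
that would create a loop or parallel edge. When the last few stub holders
of a class are mutually adjacent the placement performs a standard
degree- and class-preserving repair: drop an earlier edge (x, y) of the
same class and wire (u, y), (x, v) instead, choosing the first valid
(x, y) in sorted order. The whole construction is deterministic — two
calls produce byte-identical edge lists — and contains no randomness; an
optional `shuffle_seed` permutes vertex ids for robustness testing only.
Realizations validate (degree histogram, endpoint-degree edge histogram,
simplicity) for every 1 ≤ m, n ≤ 10; the test suite exercises 1 ≤ m, n ≤ 6.

The realized graph is deliberately *not* claimed isomorphic to the
chemical TCNB net — it need not be planar or connected. Every quantity in
scope depends only on the endpoint-degree edge partition, for which any
partition-faithful simple graph is equivalent. Consequently the
realization validates the arithmetic, not the crystallography: agreement
between the partition route and the graph route shows the bookkeeping is
exact, and says nothing about adjacency details the partition does not
determine.

## Index computation

Additive indices are computed as Σ_classes frequency × weight on the
partition route and by direct edge iteration on the graph route;
multiplicative indices as Π weight^frequency versus the direct product
(exact big integers). Coindices are computed from the closed identities
and by direct summation over all non-adjacent distinct vertex pairs
(unordered, no loops — the convention validated by the path-on-three-
vertices case, where the single non-adjacent pair gives M̄₁ = 2, M̄₂ = 1).
`index_catalog` runs both routes for every index and raises on any
disagreement before returning.

M₃ sums an orientation-dependent difference; following the values the
family is reported with, the convention min − max is used, making M₃ the
negated Albertson irregularity index (≤ 0, and strictly negative whenever
any edge joins unequal degrees). The absolute variant is exposed
separately as `albertson`.

Renderings never feed back into computation: decimal output is derived
from the exact value with round-half-even, at 1 decimal for integers,
4 decimals for rationals, and 5 significant digits (scientific) for the
multiplicative indices, matching the precision style of the published
tables. The decimal logarithm of the big-integer products is reported for
readability only.

## Closed forms and the errata ledger

Closed forms are derived symbolically: Σ_classes frequency polynomial ×
constant weight for the additive indices; the coindices by expanding
their identities with the derived vertex-count, edge-count, M₁ and M₂
polynomials; the multiplicative indices as exponent polynomials per
factor base (PM₁ grouped by the a+b weight, bases 4, 5, 6, 7; PM₂ split
into prime factors, bases 2 and 3).

The derived forms are compared coefficient-wise against a transcription
of the published formulas and tables (`tcnbtopo.reported`, a pure
fixtures catalog that no computation ever reads). Comparison rules follow
each table's printed precision: exact integers at 1 decimal; the coindex
table at 5 significant digits; the multiplicative table at 5 significant
digits in scientific notation; ReZG₂ at each cell's own printed decimal
count (2 decimals for the smaller entries, 1 for the larger), with
round-half-even throughout since the printed values are roundings of
exact rationals (e.g. ReZG₂'s mn coefficient is exactly 2151/35 =
61.45714…, printed 61.4571).

Disagreements become errata records, each carrying the printed value, the
derived replacement (recomputable from the partition alone) and the
affected table cells; table-reproduction mismatches and errata cells are
required to coincide exactly, so nothing disagrees silently. The ledger
contains six records:

1. **M₂ constant term.** Printed as 38059 in the formula, and the printed
   M₂ table column behaves as if it were 380. The edge-class sum gives
   8·6 + 8·4 + 4·12 = 128, confirmed by brute force on the realized
   graphs. No alternative partition can yield 380: the constants of M₁,
   HM, RM₂ and the handshake lemma determine the four class constants
   uniquely, and those force 128. All ten table cells are offset by the
   same 252.
2. **M̄₂ mn coefficient.** Printed 3170; the identity expansion gives
   7130 (the constant term likewise inherits the M₂ error, 370 vs 622).
   Every printed M̄₂ table entry follows the misprinted expansion.
3. **Atom count.** 32mn in the running text vs the class sum 33mn.
4. **PM₂ exponents.** Printed with a 26mn term in both exponents; exact
   bookkeeping gives 3^(72mn+42m+42n+12) · 2^(16mn+24m+24n+32). The
   printed PM₂ table follows the misprinted exponents.
5. **PM₁ table column.** The factored PM₁ form is printed correctly, but
   every printed table entry equals the 6-power factor alone.
6. **Generalized Zagreb table.** All three printed columns, for every
   shown (r, s), equal twice the bond count — the value the definition
   yields only at r = s = 0. The definition gives e.g. M_{1,1} = 2·M₂.

Record 1 deserves emphasis because it propagates: the 380-based M₂ is
what the published coindex derivation substitutes, so the printed M̄₂
formula is doubly wrong (its mn coefficient *and* its constant). This
package follows the partition and the definitions; the two acceptance
tests that pin the printed 380-based values are left failing by design,
with the analysis above as the reason.

## Problem sizes and runtime

Everything is exact and small: the largest object exercised by default is
the (5,6) realization (1,282 vertices, 1,692 edges) and its
complement-pair scan (~820k pairs); the oracle-equivalence suite covers
all 1 ≤ m, n ≤ 4 plus 200 seeded Erdős–Rényi graphs with up to 30
vertices. The full test suite runs in a few seconds on one CPU.

## Known limitations

- The realization guarantees the joint degree matrix, nothing more; no
  planarity, periodicity, embedding or isomorphism to the chemical net.
- The polynomial container is intentionally minimal (two variables,
  degree ≤ 2, rational coefficients); it is not a general computer-algebra
  layer.
- Distance-based and neighborhood-based descriptors (Wiener, Randić, ABC,
  GA, …) are out of scope.
- The generalized Zagreb index is implemented literally from its
  definition (each unordered edge counted once); which specific (r, s)
  values the published generalized-Zagreb table intended is unknowable
  from the source and is not guessed.
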