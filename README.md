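# tcnbtopo

Exact degree-based topological indices of the tetracyanobenzene
metal–organic framework graph family TCNB(m,n).

## The problem

Tetracyanobenzene (TCNB) coordinates with transition-metal ions to form a
two-dimensional metal–organic framework. For structure–property (QSPR)
work the framework is abstracted to a molecular graph: atoms are vertices,
bonds are edges, and a family TCNB(m,n) is indexed by a horizontal
expansion m ≥ 1 and a vertical expansion n ≥ 1. The family is described by
its **vertex partition** (four atom types, of degrees λ = 1…4) and its
**edge partition** (five bond types, classified by the endpoint-degree
pair), each class size an exact polynomial in (m, n); the lattice has
33mn + 25m + 25n + 17 atoms and 44mn + 32m + 32n + 20 bonds.

Every index computed here is a function of that edge partition alone:

| index | per-edge weight w(λ_u, λ_v) |
|---|---|
| first / second Zagreb, M₁ / M₂ | λ_u + λ_v,  λ_u·λ_v |
| third Zagreb, M₃ | λ_u − λ_v (smaller − larger; −Albertson) |
| hyper-Zagreb, HM | (λ_u + λ_v)² |
| reduced second Zagreb, RM₂ | (λ_u − 1)(λ_v − 1) |
| redefined Zagreb, ReZG₁/₂/₃ | (λ_u+λ_v)/(λ_uλ_v),  λ_uλ_v/(λ_u+λ_v),  λ_uλ_v(λ_u+λ_v) |
| generalized Zagreb, M_{r,s} | λ_u^r λ_v^s + λ_u^s λ_v^r |
| multiplicative Zagreb, PM₁ / PM₂ | ∏(λ_u+λ_v),  ∏(λ_u·λ_v) |

with the additive ones summed over edges (Σ_{uv∈E} w) and the
multiplicative ones multiplied (exact big integers). The Zagreb
**coindices** sum over non-adjacent distinct vertex pairs and satisfy

    M̄₁ = 2 m_χ (n_χ − 1) − M₁        M̄₂ = 2 m_χ² − M₁/2 − M₂

for a graph with n_χ vertices and m_χ edges.

The package provides, for all of the above:

- the partition model with internal-consistency checks (handshake lemma,
  per-degree stub balance, as *polynomial identities*);
- a deterministic explicit simple-graph realization of the partition (a
  joint-degree-matrix realization), so every index has a brute-force
  oracle on an actual edge set;
- exact index computation along **both** routes, asserted equal;
- symbolic closed-form polynomials in (m, n) for every index, derived
  from the class frequencies with exact rational arithmetic;
- an **errata ledger**: the derived values are compared against the
  published reference formulas and comparison tables, and every
  disagreement (several of the printed values are misprints, e.g. the M₂
  constant term and the M̄₂ mn coefficient) is flagged with the derived
  replacement.

## Worked example

```python
>>> from tcnbtopo import index_catalog, derive_closed_form
>>> for v in index_catalog((2, 3)):      # dual-route verified
...     print(v.name, v.exact if len(str(v.exact)) <= 44 else v.scientific)
M1 2492
M2 3508
M3 -212
albertson 212
HM 14312
RM2 1460
ReZG1 340
ReZG2 42559/70
ReZG3 20620
M_{1,1} 7016
M_{1,2} 20620
M_{2,2} 60800
PM1 1.5615e+330
PM2 4.9288e+386
M1bar 298540
M2bar 389518
>>> derive_closed_form("M1")
BivariatePolynomial(252*mn + 176*m + 176*n + 100)
```

TCNB(2,3) has 340 atoms and 444 bonds. M₁ = 2492 is the sum of
endpoint-degree sums over all 444 bonds — computed once from the edge
partition and once by brute force on the realized 340-vertex graph, with
exact agreement asserted before anything is returned. ReZG₂ is kept as
the exact rational 42559/70 (≈ 607.99); PM₁ ≈ 1.56·10³³⁰ is held as an
exact integer and rendered at 5 significant digits. M_{1,1} = 7016 =
2·M₂, as the definition requires. The closed form for M₁ reproduces the
published 252mn + 176m + 176n + 100.

The same functionality is exposed on the command line:

```
tcnb indices --m 2 --n 3          # index catalog
tcnb realize --m 1 --n 1 --out g.txt   # explicit edge list
tcnb derive --index M1bar         # symbolic closed form
tcnb tables --table 4             # reproduce a comparison table
tcnb errata --format json         # the errata ledger
```

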