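# nosokit

Deterministic, rule-based analysis of formalized diagnostic criteria.

Diagnostic manuals define mental and physical disorders narratively, usually
as cardinality rules over symptom checklists ("at least five of the following
nine, one of which must be ..."). `nosokit` makes such definitions
machine-actionable and asks the questions narrative prose cannot answer
exhaustively: *which symptom combinations satisfy a definition, and can two
definitions ever be confused?*

## The model

Let *S* be a fixed symptom universe. A disorder is a monotone logical rule
over *S* built from `VAR`, `AND`, `OR` and `AT_LEAST(k, …)`; any subset
*C ⊆ S* satisfying the rule is a **criteria-satisfying symptom combination
(CSSC)**. A CSSC is **irredundant** if no proper subset satisfies the rule;
a symptom is **relevant** if it occurs in some irredundant CSSC; a CSSC is
**weakly irredundant** if it contains only relevant symptoms. The weakly
irredundant set *S_D* is each disorder's combinatorial fingerprint (matrices
render irrelevant symptoms as `?`, treated as 0 in computations).

Two delineation requirements decide whether a pair (A, B) supports
differential diagnosis:

* **no-overlap** — *S_A ∩ S_B = ∅*: no symptom profile minimally-in-kind
  satisfies both definitions;
* **no-subsumption** — no *c ∈ S_A*, *d ∈ S_B* with *c ⊂ d* (assessed per
  direction; equivalently, in criteria-satisfaction form, no weakly
  irredundant CSSC of one disorder satisfies the other's rule).

Graded relatedness uses the **Maximum Pairwise Cosine Similarity**: embed
both CSSC sets as binary matrices **A**, **B** in the shared symptom space,
take for each column its best cosine match on the other side,

S_MC(A_i, **B**) = max_j S_C(A_i, B_j),  φ_max/φ_mean = max/mean over i,

and MPCS_max / MPCS_mean = the larger of the two directional aggregates, so
0 ≤ MPCS_mean ≤ MPCS_max ≤ 1, MPCS_max = 1 iff a CSSC is shared and
MPCS_max = 0 iff the relevant symptom sets are disjoint. CSSC clouds are
visualized in 2-D by a Sammon mapping (PCA initialization, gradient descent
on Sammon's stress *E*).

## Worked example

The packaged toy system defines four disorders over symptoms {a, b, c, d}:
W = a ∧ (b ∨ c), X = d ∧ (b ∨ c), Y = b ∧ (c ∨ d), Z = a ∨ d.

```sh
nosokit compare $(python -c "from nosokit.fixtures import data_path; print(data_path('toy_disorders.json'))")
```

prints (header comment elided):

```
disorder	W	X	Y	Z
W	1.000	0.556	0.661	0.664
X	0.556	1.000	0.939	0.664
Y	0.661	0.939	1.000	0.428
Z	0.664	0.664	0.428	1.000
```

W and X are clearly related (they share b and c) but delineable:
`nosokit delineate … W X` exits 0. X and Y are not — they share the weakly
irredundant CSSCs {b,d} and {b,c,d}, `nosokit delineate … X Y` exits 2 and
lists both witnesses, and their MPCS_max is 1.000. Z fails no-subsumption
against both W and X: its minimal CSSC {a} is strictly contained in W's
{a,b}, so any Z-presentation can silently grow into a W-presentation.

`nosokit enumerate … W --matrix w.tsv` writes W's ternary CSSC matrix

```
symptom	c1	c2	c3
a	1	1	1
b	1	0	1
c	0	1	1
d	?	?	?
```

(three weakly irredundant CSSCs; d is diagnostically irrelevant for W), and
the bundled DSM-style example ("at least 5 of 9, including at least 1 of the
2 core symptoms") yields `n_total = 227` by both explicit enumeration and
the closed-form laminar count.

## Layout

| module | contents |
| --- | --- |
| `nosokit.criteria` | symptom universes, monotone expressions, parsing/validation, evaluation, harmonization tables |
| `nosokit.enumeration` | weakly irredundant enumeration, minimal sets, relevance, classification, counting, ternary matrices |
| `nosokit.delineation` | no-overlap / no-subsumption checks, subsumption counts, pairwise reports |
| `nosokit.similarity` | binary cosine, shared-space embedding, MPCS aggregates and matrices |
| `nosokit.projection` | Sammon mapping and labeled pair projections |
| `nosokit.cli` | `nosokit enumerate | delineate | compare | project | audit` |
| `nosokit.fixtures` / `nosokit.oracle` | packaged toy/DSM-like fixtures, random definition generator, brute-force oracles |

See `docs/methods.md` for the formal definitions, numerical choices and
known limitations.
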