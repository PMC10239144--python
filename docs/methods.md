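# Methods

## The model

`katzncp` scores candidate miRNA–disease associations in three stages.

**Stage 1 — similarity construction.** Given a Boolean association matrix
`MD` (`nm` miRNAs × `nd` diseases) and a forest of per-disease ancestor
DAGs:

* *Disease semantic similarity*, two schemes over the ancestor sets
  `N(d)`. In the hop-discounted scheme, an ancestor term `t` of disease
  `d` contributes `D_d(t) = max over children c of t in DAG(d) of
  0.5·D_d(c)`, with `D_d(d) = 1`; equivalently `0.5^(shortest hop distance
  to d)`. In the information-content scheme, `D_d(t) = −log(k_t / n)`
  where `k_t` is the number of diseases whose DAG contains `t` and `n`
  the number of diseases in the forest. Both schemes define a semantic
  value `DV(d) = Σ_t D_d(t)` and the pairwise similarity

      DD(i, j) = Σ_{t ∈ N(d_i) ∩ N(d_j)} (D_{d_i}(t) + D_{d_j}(t)) / (DV(d_i) + DV(d_j)).

  The diagonal is 1 whenever `DV > 0`. Under the information-content
  scheme a disease whose every ancestor (including itself) is universal
  has `DV = 0`; such pairs get similarity 0 with a warning rather than a
  division error.
* *miRNA functional similarity* `MM`, the best-match average: with
  disease sets `D(m_i)`, `D(m_j)`, each disease in one set is matched to
  its most similar disease in the other set under `DD`, and the matched
  similarities are averaged over `|D(m_i)| + |D(m_j)|`. Entries involving
  a miRNA with no known association are *undefined* (NaN plus a mask),
  never silently zero.
* *Gaussian interaction-profile kernels* `GD`, `GM` over the columns/rows
  of `MD`: `exp(−γ‖p_i − p_j‖²)` with bandwidth `γ` equal to the
  reciprocal mean squared profile norm, so the kernel adapts to matrix
  density. An all-zero matrix leaves `γ` undefined and is rejected.
* *Integration*: `ID` is the mean of the two semantic schemes where both
  diseases have a DAG and `GD` elsewhere; `IM` is the mean of the two
  functional schemes where defined and `GM` elsewhere. Both diagonals are
  pinned to 1 (the information-content scheme does not guarantee a unit
  diagonal on its own), so the similarity blocks behave like correlation
  matrices inside the adjacency.

**Stage 2 — KATZ walk scoring.** The heterogeneous adjacency

    A = [[IM, MD], [MDᵀ, ID]]

is scored in closed form by the damped walk count
`s = (I − βA)⁻¹ − I = Σ_{l≥1} β^l A^l`. The damping factor is
parameterised as `β = α / eigA` with `eigA` the largest eigenvalue of the
symmetric matrix `A` (equal to its spectral norm), so any `α ∈ [0, 1)`
guarantees convergence of the series by construction. The raw-`β`
interface is deliberately not exposed. The resolvent is evaluated by
solving the linear system `(I − βA)X = I` (never by explicit inversion)
and symmetrised to remove solver round-off; a condition number above
`1e12` is fatal. The estimated score matrix `MD_e` is the upper-right
`nm × nd` block of `s`.

**Stage 3 — network consistency projection.** `MD_e` is refined by scalar
projections onto the two similarity spaces,

    MD_pm(i, j) = IM(i, :)·MD_e(:, j) / ‖MD_e(:, j)‖₂
    MD_pd(i, j) = MD_e(i, :)·ID(:, j) / ‖MD_e(i, :)‖₂

and the final score is their elementwise mean. Both projections are
defined directly in miRNA × disease orientation — with symmetric `ID`
this is the only dimensionally consistent reading and makes the
combination a plain average. Zero-norm columns/rows of `MD_e` (possible
only at `α = 0` or for empty profiles) yield zero projections, so
entities with no signal rank last deterministically instead of producing
NaN. The denominators are Euclidean norms; no additional normalisation by
`‖IM(i, :)‖` or `‖ID(:, j)‖` is applied (some consistency-projection
variants do; this formulation does not).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | walk damping weight, dimensionless in `[0, 1)` | 0.02 | selected by a LOOCV grid on the curated benchmark; `alpha = 0` degenerates to the zero score matrix |
| `recompute_kernels` | recompute `GD`/`GM`/`MM` inside each CV fold | `True` | the leakage-free protocol; `False` freezes them at full-matrix values for sensitivity analysis |

`eigA` and `β` are derived, never set directly.

## Evaluation protocols

* **LOOCV** — each known association is zeroed in turn, every
  association-derived matrix is recomputed, and the held-out pair's score
  is ranked against all pairs unobserved in the *full* matrix (global
  candidate set, one pooled ROC).
* **LOMOCV** — each miRNA's entire row is zeroed ("new miRNA"); its
  diseases are ranked within the row. With the row gone the miRNA's
  functional similarity is undefined and the integrated similarity falls
  back to the Gaussian kernel of its all-zero profile — exactly the
  mechanism that makes new-entity prediction possible at all.
* **LODOCV** — the column-wise mirror ("isolated disease").

The ROC treats a prediction at or above the threshold as positive, takes
thresholds at all distinct observed scores, groups ties at one operating
point, and integrates by trapezoid; this makes the AUC identical to the
tie-corrected Mann–Whitney U statistic divided by `n_pos · n_neg`, which
the tests assert to `1e-12` against a brute-force double loop.

Semantic similarities are computed once per dataset (they do not depend
on `MD`); everything else is recomputed per fold so no fold can see its
held-out entries. The audit hook in `loocv` exposes each fold's masked
matrix and similarity bundle so tests verify this directly.

## Synthetic data

Two generators provide deterministic fixtures.

*Plain generator* (`generate_synthetic`): places exactly
`round(density · nm · nd)` ones at uniform positions (so the realised
density matches the request for every seed, not just in expectation) and
gives each disease an ancestor chain of uniform depth `0..dag_depth`
drawn without replacement from a shared term pool — deep enough that
some disease pairs share ancestors and some share none.

*Block generator* (`generate_block_synthetic`): assigns miRNAs and
diseases round-robin to 5 clusters; a within-cluster pair is 20× more
likely to be associated than a between-cluster pair, with the two rates
solved so the expected density equals the request (at density 0.15:
`p_in = 0.625`, `p_out = 0.03125`, ≈83 % of associations within
clusters). Each cluster owns a disjoint ancestor subpool, so semantic
similarity is high within a disease cluster and zero across clusters.
The 20:1 preference was chosen so that cluster structure is the dominant
planted signal — at weaker preference the between-cluster noise itself
caps what any predictor could recover.

What the generators do *not* emulate, and hence what passing tests do not
show about real data: heavy-tailed degree distributions (hub miRNAs and
intensively studied diseases), correlated annotation depth between the
hierarchy and study effort, and any signal tying a miRNA's identity to
anything beyond its associations. The last point matters for LOMOCV: a
synthetic miRNA's cluster membership is defined *only* by its
associations, so zeroing its row destroys all identifying information and
leave-one-miRNA-out AUC on the block fixture sits near (even slightly
below) chance — the held-out diseases each lose one degree, which a
popularity-driven fallback ranks marginally lower. On real catalogues,
new-miRNA prediction instead rides on degree structure and shared
annotation hierarchies. Leave-one-disease-out does recover signal here
(≈0.85) because an isolated disease keeps its ancestor DAG, which ties it
to its cluster.

Default problem sizes for the shipped validation runs (40 × 25 at density
0.15 for cross-validation; 50 random networks ≤ 10 nodes for the
resolvent check; 40 forests ≤ 6 diseases for the semantic check) were
chosen as the smallest instances at which the measured properties are
stable across seeds.

## Numerical choices

* Hop-discounted contributions by dynamic programming in reverse
  topological order; ties in the max are order-independent.
* Similarity matrices are validated symmetric within `1e-12` and inside
  `[0, 1]`; the integration step clips only sub-`1e-12` floating
  excursions — larger violations raise.
* Exact score ties in ranking receive mid-rank (0.5 credit), matching the
  U-statistic convention.
* `alpha ≥ 1`, all-zero association matrices, cyclic "DAGs", and
  diseases missing from their own ancestor graph are rejected with
  specific errors rather than propagated as NaN.

## Known limitations

* Dense linear algebra throughout: the resolvent solve is
  `O((nm + nd)³)`, fine for catalogue-scale inputs (≈10³ nodes), not for
  genome-scale networks; no sparse/Krylov path is provided.
* Functional-similarity construction is `O(nm² · d̄²)` in the mean
  disease-set size; per-fold recomputation makes LOOCV quadratic in the
  number of associations times that cost.
* The two semantic schemes are blended with fixed equal weights; no
  similarity-fusion learning is attempted.
* Case-study style validation against external databases is out of scope;
  the evaluation here is purely cross-validation on the supplied matrix.
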