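# Methods

## Model

`qwprio` scores candidate disease genes by a continuous-time quantum walk on
the PPI graph. The Hilbert space is spanned by one basis state per node; the
state evolves as `|ψ(t)⟩ = e^{−itH}|ψ(0)⟩` with ħ = 1 and the seed-modified
adjacency Hamiltonian `H = A + α·diag(v_S)`. Unlike the classical
continuous-time random walk, which must use the Laplacian to conserve
probability, any Hermitian matrix is a valid quantum generator; using the
adjacency plus seed self-loops exploits that freedom. The α term raises the
on-site energy of seed nodes, which traps amplitude near the seed
neighbourhood (on the two-node graph this is exact: the maximal seed-escape
probability is `4/(4+α²)`, the two-level Rabi formula). The score of node v
is `L_t(v) = Σ_{s∈S} P_vs(t)` with `P_uv(t) = |⟨v|e^{−itH}|u⟩|²`.

Assumptions: the network is undirected and unweighted with entries in
{0, 1}; self-loops (self-interacting proteins) are stored as `A_ii = 1` and
contribute 1 to degree; gene identifiers are opaque, matched exactly and
case-sensitively. Analysis runs on the full graph — seeds outside the
largest connected component are logged, and nodes unreachable from all
seeds validly score 0 under every method.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `t` | walk time (dimensionless, ħ=1) | 0.45 | kept fixed across networks and diseases; not rescaled by spectral radius |
| `α` | seed self-loop weight | 5 | real, may be negative; 0 recovers the plain adjacency walk |
| DK `t` | diffusion time of `e^{−tL}` | 0.3 | documented default; exact value used in published comparisons is configurable |
| RWR `r` | restart probability | 0.75 | standard literature choice; column-stochastic `W`, isolated nodes get an implicit self-loop |
| DIAMOnD `seed_weight` | seed link multiplicity | 1 | >1 counts seed links/members multiple times in all hypergeometric counts |
| `holdout_fraction` | seeds removed per CV split | 0.5 | holdout size is round-half-up of `fraction·d` |
| `repetitions` | CV splits per disease | 10 | |
| cutoffs | recall@N grid | 25, 300 | |
| `min_coverage` | minimum mapped seeds per disease | 15 | under-covered diseases raise a distinct coverage error |

## Score computation

The literal per-seed definition is the default: `|S|` basis states are
propagated and their probability rows summed (valid because `P_vs = P_sv`
for real symmetric H). A cheaper single-propagation variant that evolves
the normalized seed superposition `v_S/√|S|` is available behind
`mode="superposition"`; it differs by inter-seed interference cross-terms
and is not used in evaluation. Complex arithmetic is mandatory; there is no
real-only fast path.

Networks with ≤ 500 nodes are propagated by dense eigendecomposition
(exact up to roundoff); larger ones use `scipy.sparse.linalg.expm_multiply`,
which never forms the dense propagator. Both routes are validated in the
test suite against an independent dense `scipy.linalg.expm` oracle to 1e−8
relative error, and unitarity (probability rows summing to 1) is asserted
to 1e−8.

## Evaluation protocol

Per disease and repetition: split seeds (round-half-up holdout), score with
every method using *only* the training seeds (held-out seeds never receive
the α boost — they are relabelled as non-seeds before scoring), rank all
non-training nodes by descending score, and read off recall@N and average
precision. Ties anywhere are broken by ascending gene identifier, making
every pipeline output byte-reproducible. The per-cell RNG seed is derived
as `(rng_seed + repetition + crc32(disease_id)) mod 2³¹`, so results are
invariant to disease ordering and any single cell can be re-run in
isolation.

Method comparison uses mean reciprocal ranks: per disease, methods are
ranked by recall with fractional (mean) ranks on ties; MRR is the mean
reciprocal rank over diseases. The default summary averages recall over
repetitions per disease before ranking and reports the standard deviation
across diseases' reciprocal ranks; `mrr_summary(per_repetition=True)`
instead computes one MRR per repetition and reports mean ± sd across
repetitions. AP uses the full candidate ranking; DIAMOnD, which only orders
the nodes it adds, has unranked candidates placed last in identifier order
via its score adapter (score = n_add − position, 0 for unranked).

Enrichment of a prioritized list against a reference gene set is the exact
upper-tail hypergeometric probability `P(X ≥ k)`.

## Synthetic benchmark

The generator emulates the features of real interactomes that the method
relies on: approximate scale-freeness (Barabási–Albert preferential
attachment), sparsity, local clustering, optional self-interacting
proteins, and disease genes concentrated in a local neighbourhood. Modules
are placed by snowball (BFS-frontier) sampling from a random anchor —
matching the local-module hypothesis — and densified with random internal
edges to a target internal density (default 0.35 for a 20-gene module, a
clearly-detectable but non-clique regime). A uniform-sampling adversarial
mode is deliberately absent from the default suite; snowball reflects the
regime the method targets.

Standard fixtures: small (n = 200, 5 planted 20-gene modules) for fast
regression tests, medium (n = 2000, 5 × 25-gene modules) to exercise the
sparse propagation path; the acceptance script runs the medium benchmark.
These sizes keep the full test suite in single-digit minutes on one CPU.

What passing tests do *not* show about real data: planted modules are
cleaner and denser than curated disease gene sets, the degree distribution
lacks the very heavy hubs of real PPIs, there is no annotation noise or
ascertainment bias, and absolute recall/MRR values on the benchmark do not
transfer to real interactomes — only the relative mechanics (propagation
correctness, protocol correctness, better-than-chance recovery) are
validated.

## Numerical choices

- Propagation tolerance: 1e−8 relative, configurable through the dense
  threshold; dense eigendecomposition is used as the internal route below
  501 nodes.
- RWR convergence: 1-norm residual ≤ 1e−10, iteration cap 10 000, error on
  non-convergence.
- Degenerate inputs: empty seed sets, single-node networks, empty holdouts
  and inconsistent enrichment counts raise typed input errors; a scorer
  failure inside cross-validation is recorded per cell and excluded with a
  warning rather than aborting the run.
- DIAMOnD tie-breaking: candidates within relative 1e−12 of the minimal
  p-value tie; ties resolve by ascending identifier.

## Known limitations

- Degree-preserving rewiring (`rewire_preserving_degrees`) only erodes
  clustering when the planted structure is not implied by the degree
  sequence; a dense clique occupying a large fraction of a small graph
  yields a configuration-model null with *higher* clustering, so null-model
  comparisons should use the standard sparse fixtures.
- `t` is not renormalized across network sizes; transferring `t = 0.45`
  to networks of very different spectral radius changes the walk's
  effective horizon.
- The DK/RWR default hyperparameters are documented choices, not fitted
  values; published comparisons may use different ones, so both are CLI
  flags.
- No identifier translation layer: seed files must use the same gene
  identifier namespace as the edge list.
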