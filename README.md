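# qwprio

Disease gene prioritization on protein–protein interaction (PPI) networks by
**continuous-time quantum walks**, with the classical network-propagation
baselines it is usually compared against and a seed-holdout cross-validation
pipeline for head-to-head method comparison.

## The problem

Diseases are rarely caused by single genes: the associated proteins tend to
cluster in a local neighbourhood of the interactome (a *disease module*).
Given a PPI network and a small set of curated *seed genes* for a disease,
the prioritization task is to rank all other genes by their likelihood of
belonging to the same module. Classical approaches propagate the seed signal
diffusively (heat kernels, random walks with restart). `qwprio` implements a
quantum-mechanical alternative and the machinery to evaluate it.

## The model

A walker's state is a complex amplitude vector over the `n` network nodes
evolving unitarily (ħ = 1):

    |ψ(t)⟩ = e^{−itH} |ψ(0)⟩,     H = A + α·diag(v_S)

where `A` is the binary symmetric adjacency matrix, `v_S` the indicator of
the seed set `S`, and `α` a real seed self-loop weight. Adding `α` to seed
diagonals is equivalent to attaching `α` self-edges at each seed and keeps
the walker localized near the seed neighbourhood for longer. Transition
probabilities are squared propagator elements,

    P_uv(t) = |⟨v| e^{−itH} |u⟩|²,

and candidate gene `v` is scored by its total transition probability into
the seed set:

    L_t(v) = Σ_{s∈S} P_vs(t).

Defaults `t = 0.45`, `α = 5` are used uniformly across networks and
diseases. Propagation is exact — dense eigendecomposition up to 500 nodes,
Krylov sparse action (`scipy.sparse.linalg.expm_multiply`) above — and the
per-seed sum needs only `|S|` propagations since `P_vs = P_sv` for real
symmetric `H`.

Baselines, all behind the same scoring interface: diffusion kernel
(`e^{−tL}` with `L = D − A`), random walk with restart, neighbourhood
scoring (seed fraction among direct neighbours), and DIAMOnD (iterative
module growth by hypergeometric connectivity significance). Evaluation
follows the standard protocol: hold out 50 % of each disease's seeds, rank
the non-training nodes, measure recall@N (N = 25, 300 by default), repeat
10×, and compare methods across diseases by mean reciprocal rank (MRR) with
fractional ranks on ties. A hypergeometric enrichment test for prioritized
lists is included.

No external database is required: `qwprio.synthetic` generates sparse,
approximately scale-free networks with locally dense planted disease
modules (and optional self-interacting proteins) that serve as ground truth.

## Worked example

```python
from qwprio import CVConfig, benchmark_suite, make_scorer, network_stats, run_cv
from qwprio.synthetic import SMALL_FIXTURE

net, diseases = benchmark_suite([SMALL_FIXTURE], n_diseases=5)[0]
print(network_stats(net))

methods = {m: make_scorer(m) for m in ("qa", "dk", "rwr", "nbr")}
result = run_cv(net, diseases, methods,
                CVConfig(repetitions=10, top_n_grid=(25,), rng_seed=1))
print(result.mrr_summary().to_string(index=False))
print(result.mean_recall().groupby("method")["recall"].mean().round(3).to_string())
```

prints

```
NetworkStats(n=200, m=782, avg_degree=7.8, density=0.039095477386934675,
             avg_clustering=0.13025616280899524, assortativity=-0.05792526146066144,
             sip_count=4)
 cutoff method      mrr       sd
     25     dk 0.466667 0.074536
     25    nbr 0.250000 0.000000
     25     qa 0.500000 0.288675
     25    rwr 0.866667 0.298142
method
dk     0.872
nbr    0.522
qa     0.820
rwr    0.942
```

The fixture is a 200-node scale-free network carrying five planted 20-gene
disease modules. The last block is each method's recall@25 averaged over
diseases and ten 50 %-holdout repetitions: the quantum walk recovers 82 % of
held-out module genes in its top 25 candidates — far above the ≈13 % a
uniform random ranking would achieve — while the MRR table ranks the methods
against each other per disease (1.0 = best on every disease).

The same pipeline is available from the shell:

```sh
qwprio simulate --n 200 --rng-seed 7 --out-dir fixture/
qwprio crossval --network fixture/network.tsv --seeds fixture/diseases.tsv \
    --methods qa,dk,rwr,nbr --reps 10 --cutoffs 25,300 --rng-seed 1 --out-dir cv/
qwprio score --network fixture/network.tsv --seeds fixture/diseases.tsv \
    --method qa --time 0.45 --alpha 5 --out-dir scores/
qwprio stats --network fixture/network.tsv --stdout
```

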