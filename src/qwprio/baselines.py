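"""Classical gene prioritization baselines: DK, RWR, NBR, and DIAMOnD.

All four return (or are adapted to) the common :class:`~qwprio.walk.ScoreVector`
contract so the evaluation pipeline can compare them head-to-head with the
quantum walk:

* diffusion kernel (DK): heat-kernel scoring via exp(-t L), L the Laplacian;
* random walk with restart (RWR): stationary distribution of a teleporting
  walk over the column-stochastic adjacency;
* neighbourhood scoring (NBR): fraction of a node's neighbours that are seeds;
* DIAMOnD: iterative module growth by hypergeometric connectivity
  significance, adapted to a score vector by rank position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import hypergeom

from .exceptions import ConvergenceError, InputFormatError
from .graph import PPINetwork, SeedSet, laplacian
from .walk import DENSE_THRESHOLD, ScoreVector

logger = logging.getLogger(__name__)

__all__ = [
    "RWRParameters",
    "DiamondState",
    "dk_scores",
    "rwr_scores",
    "nbr_scores",
    "diamond_ranking",
    "diamond_scores",
]


@dataclass(frozen=True)
class RWRParameters:
    """Restart probability and convergence controls for RWR."""

    restart: float = 0.75
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.restart <= 1):
            raise InputFormatError("restart probability must be in (0, 1]")
        if self.tol <= 0:
            raise InputFormatError("tol must be > 0")


@dataclass(frozen=True)
class DiamondState:
    """Result of DIAMOnD module growth.

    ``ranked_additions`` lists (node index, connectivity p-value) in addition
    order; ``current_module`` is seeds plus all additions.
    """

    ranked_additions: list[tuple[int, float]]
    current_module: set[int]


def dk_scores(
    net: PPINetwork,
    seeds: SeedSet,
    t: float = 0.3,
    dense_threshold: int = DENSE_THRESHOLD,
) -> ScoreVector:
    """Diffusion-kernel scores: scores[v] = sum_{s in S} K_vs, K = exp(-t L).

    K is symmetric and doubly stochastic (L has zero row sums), so the score
    vector is simply K @ v_S, computed by eigendecomposition for small
    networks and by sparse Krylov action otherwise.
    """
    if t <= 0:
        raise InputFormatError("diffusion time must be > 0")
    L = laplacian(net)
    v = seeds.indicator
    if net.n <= dense_threshold:
        w, U = np.linalg.eigh(L.toarray())
        scores = U @ (np.exp(-t * w) * (U.T @ v))
    else:
        scores = sp.linalg.expm_multiply(-t * L.tocsc(), v)
    return ScoreVector("dk", scores, {"t": t})


def rwr_scores(
    net: PPINetwork,
    seeds: SeedSet,
    params: RWRParameters | None = None,
) -> ScoreVector:
    """Random walk with restart: fixed point of p = (1-r) W p + r p0.

    W is the column-stochastic adjacency (self-loops included as written);
    an isolated node receives an implicit self-loop so W stays stochastic.
    p0 is uniform over the seeds.  Power iteration until the 1-norm change
    falls below ``tol``; the result sums to 1.
    """
    if params is None:
        params = RWRParameters()
    A = net.adjacency
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = colsum == 0
    inv = np.where(isolated, 1.0, 1.0 / np.where(isolated, 1.0, colsum))
    W = (A @ sp.diags(inv)).tolil()
    for i in np.flatnonzero(isolated):
        W[i, i] = 1.0
    W = W.tocsr()
    p0 = seeds.indicator / len(seeds)
    r = params.restart
    p = p0.copy()
    for _ in range(params.max_iter):
        p_next = (1 - r) * (W @ p) + r * p0
        if np.abs(p_next - p).sum() <= params.tol:
            return ScoreVector("rwr", p_next, {"restart": r, "tol": params.tol})
        p = p_next
    raise ConvergenceError(
        f"RWR did not converge in {params.max_iter} iterations (r={r}, tol={params.tol})"
    )


def nbr_scores(net: PPINetwork, seeds: SeedSet, normalize: bool = True) -> ScoreVector:
    """Neighbourhood scoring: scores[v] = |N(v) ∩ S| / |N(v)|.

    N(v) excludes v itself (self-loops ignored); isolated nodes score 0.
    ``normalize=False`` gives the raw seed-neighbour count variant.
    """
    A = net.without_self_loops().adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    seed_links = A @ seeds.indicator
    if not normalize:
        return ScoreVector("nbr", seed_links, {"normalize": False})
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(deg > 0, seed_links / np.where(deg > 0, deg, 1.0), 0.0)
    return ScoreVector("nbr", scores, {"normalize": True})


def diamond_ranking(
    net: PPINetwork,
    seeds: SeedSet,
    n_add: int,
    seed_weight: int = 1,
) -> DiamondState:
    """DIAMOnD: grow the disease module by hypergeometric connectivity.

    At each step every candidate v outside the current module is tested for
    connectivity significance: with N = n nodes in the universe, s0 = module
    size as successes and k = deg(v) draws, the p-value is P(X >= k_s) where
    k_s counts v's links into the module.  The most significant candidate
    (smallest p-value; ties broken by ascending gene identifier) joins the
    module and the next iteration recounts connectivity against the enlarged
    module.  Self-loops are excluded from both k and k_s.

    ``seed_weight`` > 1 counts each link to a seed node as that many links
    (and inflates the universe and success counts consistently), matching
    the original algorithm's seed up-weighting.

    Candidates never connected to the module are appended after all connected
    ones with p-value 1.0, in ascending identifier order.  If ``n_add``
    exceeds the candidate count the result is truncated with a warning.
    """
    if n_add < 1:
        raise InputFormatError("n_add must be >= 1")
    A = net.without_self_loops().adjacency
    n = net.n
    deg = np.asarray(A.sum(axis=1)).ravel().astype(int)
    seed_arr = seeds.indicator
    links_to_seeds = (A @ seed_arr).astype(int)
    in_module = seed_arr.astype(bool).copy()
    links_to_module = links_to_seeds.copy()

    n_cand = n - len(seeds)
    if n_add > n_cand:
        logger.warning("n_add=%d exceeds %d candidates; truncating", n_add, n_cand)
        n_add = n_cand

    w = int(seed_weight)
    n_seed_in_module = len(seeds)
    additions: list[tuple[int, float]] = []
    ids = net.node_ids
    for _ in range(n_add):
        cand = np.flatnonzero(~in_module & (links_to_module > 0))
        if cand.size == 0:
            break
        module_size = int(in_module.sum())
        # seed up-weighting: seed links (and seed module members) count w times
        ks = links_to_module[cand] + (w - 1) * links_to_seeds[cand]
        kk = deg[cand] + (w - 1) * links_to_seeds[cand]
        s0 = module_size + (w - 1) * n_seed_in_module
        N = n + (w - 1) * n_seed_in_module
        pvals = hypergeom.sf(ks - 1, N, s0, kk)
        best_p = pvals.min()
        tied = cand[pvals <= best_p * (1 + 1e-12)]
        pick = min(tied, key=lambda i: ids[i])
        additions.append((int(pick), float(pvals[cand == pick][0])))
        in_module[pick] = True
        links_to_module += A[:, pick].toarray().ravel().astype(int)
    if len(additions) < n_add:
        # exhaust remaining candidates: never connected, p-value 1
        leftover = sorted(np.flatnonzero(~in_module), key=lambda i: ids[i])
        for i in leftover[: n_add - len(additions)]:
            additions.append((int(i), 1.0))
            in_module[i] = True
    return DiamondState(additions, {int(i) for i in np.flatnonzero(in_module)})


def diamond_scores(net: PPINetwork, seeds: SeedSet, n_add: int) -> ScoreVector:
    """Adapter encoding the DIAMOnD addition order as a score vector.

    The node added at position p (0-based) scores ``n_add - p``; unranked
    nodes score 0, so descending-score order reproduces the DIAMOnD ranking.
    """
    state = diamond_ranking(net, seeds, n_add)
    scores = np.zeros(net.n)
    for pos, (node, _p) in enumerate(state.ranked_additions):
        scores[node] = n_add - pos
    return ScoreVector("diamond", scores, {"n_add": n_add})
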