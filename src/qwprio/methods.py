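"""Registry adapting every prioritization method to the common scorer
signature ``(net, train_seeds) -> ScoreVector`` used by the CV pipeline."""

from __future__ import annotations

from functools import partial

from .baselines import RWRParameters, diamond_scores, dk_scores, nbr_scores, rwr_scores
from .evaluation import Scorer
from .exceptions import InputFormatError
from .graph import PPINetwork, SeedSet
from .walk import WalkParameters, qa_scores

METHOD_NAMES = ("qa", "dk", "rwr", "nbr", "diamond")

__all__ = ["METHOD_NAMES", "make_scorer"]


def make_scorer(
    method: str,
    t: float = 0.45,
    alpha: float = 5.0,
    dk_time: float = 0.3,
    restart: float = 0.75,
    n_add: int = 300,
    qa_mode: str = "per_seed",
) -> Scorer:
    """Build a scorer closure for one method with fixed hyperparameters."""
    if method == "qa":
        params = WalkParameters(t=t, alpha=alpha)
        return partial(qa_scores, params=params, mode=qa_mode)
    if method == "dk":
        return partial(dk_scores, t=dk_time)
    if method == "rwr":
        return partial(rwr_scores, params=RWRParameters(restart=restart))
    if method == "nbr":
        return nbr_scores
    if method == "diamond":
        return lambda net, seeds: diamond_scores(net, seeds, n_add=n_add)
    raise InputFormatError(f"unknown method: {method!r} (choose from {METHOD_NAMES})")


def degree_scorer(net: PPINetwork, seeds: SeedSet):
    """Null baseline ranking nodes purely by degree (seed-agnostic)."""
    from .walk import ScoreVector

    return ScoreVector("degree", net.degrees().astype(float), {})
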