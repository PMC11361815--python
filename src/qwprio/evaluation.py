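"""Cross-validation, recall/precision metrics, MRR comparison, enrichment.

The evaluation protocol: for each disease, hold out half of the seed genes
(relabelled as non-seeds), score every node with each method using only the
retained training seeds, rank the non-training nodes by descending score,
and measure the fraction of held-out seeds recovered in the top N
(recall@N).  Repeating the split several times and averaging gives stable
per-disease recall values; methods are then compared across diseases by
mean reciprocal rank (MRR): per disease, rank methods by recall (fractional
ranks on ties), take reciprocal ranks, average over diseases.

Also provides the upper-tail hypergeometric enrichment test used to assess
overlap between a prioritized gene list and a reference disease module.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .exceptions import InputFormatError
from .graph import PPINetwork, SeedSet
from .walk import ScoreVector

logger = logging.getLogger(__name__)

Scorer = Callable[[PPINetwork, SeedSet], ScoreVector]

__all__ = [
    "CVConfig",
    "RankedList",
    "RecallCurve",
    "MRRRecord",
    "EnrichmentResult",
    "CVResult",
    "split_seeds",
    "rank_candidates",
    "recall_at",
    "average_precision",
    "mrr_across_methods",
    "run_cv",
    "hypergeometric_enrichment",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    Defaults follow the standard protocol: hold out 50% of seeds, repeat 10
    times, report recall at N = 25 and N = 300.
    """

    holdout_fraction: float = 0.5
    repetitions: int = 10
    top_n_grid: tuple[int, ...] = (25, 300)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.holdout_fraction < 1):
            raise InputFormatError("holdout_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise InputFormatError("repetitions must be >= 1")
        grid = tuple(int(c) for c in self.top_n_grid)
        if not grid or any(c <= 0 for c in grid) or list(grid) != sorted(grid):
            raise InputFormatError("top_n_grid must be positive and sorted")
        object.__setattr__(self, "top_n_grid", grid)


@dataclass(frozen=True)
class RankedList:
    """Candidate nodes in descending-score order with holdout labels.

    Contains every node except the retained (training) seeds, exactly once;
    ``holdout_mask[i]`` is True when ``ordered_nodes[i]`` is a held-out seed.
    """

    ordered_nodes: np.ndarray
    holdout_mask: np.ndarray

    @property
    def n_holdout(self) -> int:
        return int(self.holdout_mask.sum())


@dataclass(frozen=True)
class RecallCurve:
    cutoffs: tuple[int, ...]
    recall: tuple[float, ...]


@dataclass(frozen=True)
class MRRRecord:
    method: str
    mrr: float
    per_disease_rr: tuple[float, ...]


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    list_size: int
    reference_size: int
    universe: int
    p_value: float


@dataclass
class CVResult:
    """Tidy per-cell recall/AP tables plus the method-comparison summary."""

    recall: pd.DataFrame  # columns: disease, method, repetition, cutoff, recall
    ap: pd.DataFrame  # columns: disease, method, repetition, ap
    config: CVConfig
    failures: list[tuple[str, str, int, str]] = field(default_factory=list)

    def mean_recall(self) -> pd.DataFrame:
        """Per (disease, method, cutoff) recall averaged over repetitions."""
        return (
            self.recall.groupby(["disease", "method", "cutoff"], sort=False)["recall"]
            .mean()
            .reset_index()
        )

    def mrr_summary(self, per_repetition: bool = False) -> pd.DataFrame:
        """MRR per method and cutoff, with standard deviation.

        Default: recall is first averaged over repetitions per disease;
        methods are then ranked per disease and reciprocal ranks averaged,
        with the standard deviation taken across diseases' reciprocal ranks.
        ``per_repetition=True`` instead computes one MRR per repetition and
        reports mean and standard deviation across repetitions.
        """
        rows = []
        if per_repetition:
            for (cutoff, rep), sub in self.recall.groupby(
                ["cutoff", "repetition"], sort=True
            ):
                table = sub.pivot(index="disease", columns="method", values="recall")
                for rec in mrr_across_methods(
                    {d: table.loc[d].to_dict() for d in table.index}
                ):
                    rows.append(
                        {"cutoff": cutoff, "repetition": rep,
                         "method": rec.method, "mrr": rec.mrr}
                    )
            df = pd.DataFrame(rows)
            out = (
                df.groupby(["cutoff", "method"], sort=True)["mrr"]
                .agg(mrr="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan)
                .reset_index()
            )
            return out
        mean = self.mean_recall()
        for cutoff, sub in mean.groupby("cutoff", sort=True):
            table = sub.pivot(index="disease", columns="method", values="recall")
            recs = mrr_across_methods(
                {d: table.loc[d].to_dict() for d in table.index}
            )
            for rec in recs:
                rr = np.array(rec.per_disease_rr)
                rows.append(
                    {
                        "cutoff": cutoff,
                        "method": rec.method,
                        "mrr": rec.mrr,
                        "sd": float(rr.std(ddof=1)) if rr.size > 1 else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


def split_seeds(
    seeds: SeedSet, fraction: float, rng_seed: int
) -> tuple[SeedSet, SeedSet]:
    """Randomly partition a seed set into (train, holdout).

    Holdout size is round-half-up of ``fraction * |seeds|``.  The partition
    is a pure function of ``rng_seed``.
    """
    d = len(seeds)
    if d < 2:
        raise InputFormatError(f"{seeds.disease_id}: need >= 2 seeds to split")
    if not (0 < fraction < 1):
        raise InputFormatError("holdout fraction must be in (0, 1)")
    n_hold = int(np.floor(fraction * d + 0.5))
    n_hold = min(max(n_hold, 1), d - 1)
    rng = np.random.default_rng(rng_seed)
    order = np.array(sorted(seeds.seed_indices))
    rng.shuffle(order)
    holdout = frozenset(int(i) for i in order[:n_hold])
    train = frozenset(int(i) for i in order[n_hold:])
    return (
        SeedSet(seeds.disease_id, train, seeds.n),
        SeedSet(seeds.disease_id, holdout, seeds.n),
    )


def rank_candidates(
    net: PPINetwork,
    scores: ScoreVector,
    train: SeedSet,
    holdout: SeedSet,
) -> RankedList:
    """Rank all non-training nodes by descending score.

    Held-out seeds are candidates like any other non-seed (they were
    relabelled as non-seeds before scoring).  Ties are broken by ascending
    gene identifier — the global deterministic tie rule.
    """
    if train.seed_indices & holdout.seed_indices:
        raise InputFormatError("train and holdout seed sets overlap")
    s = scores.scores
    candidates = [i for i in range(net.n) if i not in train.seed_indices]
    candidates.sort(key=lambda i: (-s[i], net.node_ids[i]))
    ordered = np.array(candidates, dtype=int)
    mask = np.isin(ordered, sorted(holdout.seed_indices))
    return RankedList(ordered, mask)


def recall_at(ranked: RankedList, N: int) -> float:
    """Fraction of held-out seeds appearing in the top N candidates."""
    if N < 1:
        raise InputFormatError("N must be >= 1")
    h = ranked.n_holdout
    if h == 0:
        raise InputFormatError("empty holdout set")
    return float(ranked.holdout_mask[:N].sum()) / h


def average_precision(ranked: RankedList) -> float:
    """AP over the full candidate ranking: mean of i/r_i over holdout hits."""
    h = ranked.n_holdout
    if h == 0:
        raise InputFormatError("empty holdout set")
    hit_ranks = np.flatnonzero(ranked.holdout_mask) + 1
    precisions = np.arange(1, h + 1) / hit_ranks
    return float(precisions.mean())


def recall_curve(ranked: RankedList, cutoffs: Sequence[int]) -> RecallCurve:
    return RecallCurve(tuple(int(c) for c in cutoffs), tuple(recall_at(ranked, c) for c in cutoffs))


def mrr_across_methods(
    recalls: Mapping[str, Mapping[str, float]]
) -> list[MRRRecord]:
    """Mean reciprocal rank of each method over diseases.

    ``recalls[disease][method]`` is that method's recall for the disease.
    Per disease, methods are ranked by descending recall with fractional
    (mean) ranks on ties; a method's reciprocal rank is 1/rank; its MRR is
    the mean over diseases.  Every disease must cover every method.
    """
    diseases = list(recalls)
    if not diseases:
        raise InputFormatError("no diseases given")
    methods = list(recalls[diseases[0]])
    if len(methods) < 2:
        raise InputFormatError("need >= 2 methods to compare")
    for d in diseases:
        if set(recalls[d]) != set(methods):
            raise InputFormatError(f"disease {d!r} is missing some methods")
    rr = {m: [] for m in methods}
    for d in diseases:
        vals = np.array([recalls[d][m] for m in methods], dtype=float)
        ranks = rankdata(-vals, method="average")
        for m, r in zip(methods, ranks):
            rr[m].append(1.0 / r)
    return [
        MRRRecord(m, float(np.mean(rr[m])), tuple(rr[m])) for m in methods
    ]


def _cell_seed(base: int, disease_id: str, repetition: int) -> int:
    """Derived RNG seed for one (disease, repetition) cell.

    Mixing in a stable hash of the disease identifier makes the result
    independent of disease ordering, and ``base + repetition`` keeps any
    single repetition re-runnable in isolation.
    """
    return (int(base) + repetition + zlib.crc32(disease_id.encode())) % (2**31)


def run_cv(
    net: PPINetwork,
    diseases: Sequence[SeedSet],
    methods: Mapping[str, Scorer],
    config: CVConfig | None = None,
) -> CVResult:
    """Run the full cross-validation pipeline.

    For each disease and repetition the seed set is split once and every
    method scores the identical train/holdout partition.  A scorer failure
    on one cell is recorded and excluded with a warning rather than aborting
    the whole run.  Fully reproducible from ``config.rng_seed``.
    """
    if config is None:
        config = CVConfig()
    if len(methods) < 1:
        raise InputFormatError("at least one method required")
    recall_rows, ap_rows, failures = [], [], []
    for disease in diseases:
        for rep in range(config.repetitions):
            seed = _cell_seed(config.rng_seed, disease.disease_id, rep)
            train, holdout = split_seeds(disease, config.holdout_fraction, seed)
            for name, scorer in methods.items():
                try:
                    sv = scorer(net, train)
                    ranked = rank_candidates(net, sv, train, holdout)
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    logger.warning(
                        "%s / %s / rep %d failed: %s", disease.disease_id, name, rep, exc
                    )
                    failures.append((disease.disease_id, name, rep, str(exc)))
                    continue
                for cutoff in config.top_n_grid:
                    recall_rows.append(
                        {
                            "disease": disease.disease_id,
                            "method": name,
                            "repetition": rep,
                            "cutoff": cutoff,
                            "recall": recall_at(ranked, cutoff),
                        }
                    )
                ap_rows.append(
                    {
                        "disease": disease.disease_id,
                        "method": name,
                        "repetition": rep,
                        "ap": average_precision(ranked),
                    }
                )
    recall_df = pd.DataFrame(
        recall_rows, columns=["disease", "method", "repetition", "cutoff", "recall"]
    ).sort_values(["disease", "method", "repetition", "cutoff"], kind="stable")
    ap_df = pd.DataFrame(
        ap_rows, columns=["disease", "method", "repetition", "ap"]
    ).sort_values(["disease", "method", "repetition"], kind="stable")
    return CVResult(
        recall_df.reset_index(drop=True), ap_df.reset_index(drop=True), config, failures
    )


def hypergeometric_enrichment(
    k: int, list_size: int, reference_size: int, universe: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= k) for gene-list overlap.

    X counts the overlap of a random ``list_size``-subset of the universe
    with a fixed reference set of ``reference_size`` genes.
    """
    if not (0 <= k <= min(list_size, reference_size) <= universe):
        raise InputFormatError("inconsistent enrichment counts")
    if list_size > universe or reference_size > universe:
        raise InputFormatError("list/reference larger than universe")
    p = float(hypergeom.sf(k - 1, universe, reference_size, list_size))
    return EnrichmentResult(k, list_size, reference_size, universe, min(p, 1.0))
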