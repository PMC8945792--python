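"""Weighted running-sum set enrichment over a ranked lipid list.

Given lipids ranked by a differential-abundance score, walk the list:
at each member of the set ("hit") the running sum rises by that lipid's
weight ``|score|^p / sum_hits |score|^p``; at each non-member ("miss")
it falls by ``1 / (N - N_hits)``. The enrichment score (ES) is the
running-sum value of maximal absolute deviation from zero, positive when
the set concentrates at the top of the ranking, negative at the bottom.

Significance comes from a lipid-label permutation null: random member
subsets of the same size drawn from the ranked ids. With only a handful
of samples per group in typical mediator panels, phenotype relabelling
would admit far too few permutations, so the preranked/label scheme is
the only well-powered choice. The normalized score (NES) divides ES by
the mean |null ES| of matching sign; the FDR q of a set is the ratio of
the matching-sign tail fraction in the pooled null NES to the same tail
fraction among observed NES, capped at 1.

Determinism: one master seed; each set draws its permutations from a
child seed derived from (master seed, set_id), so results do not depend
on collection order.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sets import LipidSet, LipidSetCollection


class EnrichmentError(ValueError):
    pass


@dataclass
class RankedList:
    """Descending (lipid, score) ranking with unique ids and finite scores."""

    ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != self.scores.size:
            raise EnrichmentError("ids and scores lengths differ")
        if len(self.ids) < 2:
            raise EnrichmentError("ranked list needs at least 2 entries")
        if len(set(self.ids)) != len(self.ids):
            raise EnrichmentError("duplicate ids in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise EnrichmentError("scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise EnrichmentError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankedList":
        """Build from a (lipid, score) frame as emitted by ``rank_metric``."""
        return cls(ids=tuple(df["lipid"]), scores=df["score"].to_numpy())


def child_seed(master_seed: int, set_id: str) -> int:
    """Deterministic per-set seed, independent of collection order."""
    digest = hashlib.blake2b(
        f"{master_seed}:{set_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ------------------------------------------------------------ core statistic


def enrichment_score(
    ranked: RankedList, lipid_set: LipidSet | set[str], p_exp: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """ES, full running sum and hit positions for one set.

    Requires a proper non-empty overlap: at least one member in the list
    and at least one non-member (otherwise the miss decrement is
    undefined).
    """
    members = set(lipid_set.members if isinstance(lipid_set, LipidSet) else lipid_set)
    n = len(ranked)
    hit_mask = np.fromiter((i in members for i in ranked.ids), bool, count=n)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise EnrichmentError("set has no overlap with the ranked list")
    if n_hits == n:
        raise EnrichmentError("set covers the whole list; ES undefined")
    w = np.abs(ranked.scores) ** p_exp
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        # all hit weights zero (e.g. p_exp>0 with zero scores): equal weights
        w_hit = hit_mask / n_hits
        total = 1.0
    steps = w_hit / total - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    return es, running, np.flatnonzero(hit_mask)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position vectors of equal size.

    ``positions`` is (n_draws, k) of sorted 0-based ranks; ``weights``
    holds |score|^p per rank. The running-sum extremes are attained at a
    hit (positive candidates) or just before a hit (negative
    candidates), so only those 2k points need evaluating.
    """
    n_draws, k = positions.shape
    w = weights[positions]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        total = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / total
    t = np.arange(k)
    miss_before = (positions - t) / (n - k)
    at_hit = cum - miss_before
    before_hit = at_hit - w / total
    pos = at_hit.max(axis=1)
    neg = before_hit.min(axis=1)
    return np.where(pos >= -neg, pos, neg)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    p_exp: float = 1.0,
) -> np.ndarray:
    """Null ES distribution from random member subsets of the list's ids."""
    n = len(ranked)
    if not 1 <= set_size < n:
        raise EnrichmentError(f"set_size must be in [1, {n - 1}], got {set_size}")
    if n_perm < 100:
        raise EnrichmentError("n_perm must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # k smallest of N uniforms per row = uniform random subset
    u = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(u, set_size, axis=1)[:, :set_size], axis=1)
    weights = np.abs(ranked.scores) ** p_exp
    return _es_from_positions(positions, weights, n)


def nominal_p(es: float, nulls: np.ndarray) -> float:
    """Add-one tail probability against matching-sign null ES."""
    if es == 0:
        return 1.0
    same = nulls[nulls > 0] if es > 0 else nulls[nulls < 0]
    k = int((np.abs(same) >= abs(es)).sum())
    return (1 + k) / (1 + same.size)


def normalized_es(es: float, nulls: np.ndarray) -> float:
    """ES divided by the mean |null ES| of matching sign (NaN if none)."""
    if es == 0:
        return 0.0
    same = nulls[nulls > 0] if es > 0 else nulls[nulls < 0]
    if same.size == 0:
        return np.nan
    return float(es / np.abs(same).mean())


def leading_edge(
    running: np.ndarray, hit_indices: np.ndarray, es: float, ids: tuple[str, ...]
) -> list[str]:
    """Members driving the ES peak.

    For positive ES: hits at or before the peak; for negative: hits at or
    after the trough; empty for ES exactly zero.
    """
    if es == 0:
        return []
    if es > 0:
        peak = int(np.argmax(running))
        take = hit_indices[hit_indices <= peak]
    else:
        trough = int(np.argmin(running))
        take = hit_indices[hit_indices >= trough]
    return [ids[i] for i in take]


def nes_and_fdr(
    observed: dict[str, float], nulls: dict[str, np.ndarray]
) -> pd.DataFrame:
    """NES, nominal p and permutation FDR q for scored sets.

    Null ES of each set are normalized by that set's own matching-sign
    mean, then pooled; for an observed NES* the q-value is
    ``[tail fraction of pooled null NES] / [tail fraction of observed
    NES]`` on the matching sign, capped at 1.
    """
    missing = set(observed) - set(nulls)
    if missing:
        raise EnrichmentError(f"sets without a null distribution: {sorted(missing)}")
    rows = {}
    pooled = []
    for sid, es in observed.items():
        null = np.asarray(nulls[sid], dtype=float)
        rows[sid] = {
            "es": es,
            "nes": normalized_es(es, null),
            "p_nominal": nominal_p(es, null),
        }
        pos, neg = null[null > 0], null[null < 0]
        null_nes = np.concatenate(
            [
                pos / np.abs(pos).mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ]
        )
        pooled.append(null_nes)
    pooled = np.concatenate(pooled) if pooled else np.array([])
    obs_nes = np.array([r["nes"] for r in rows.values()])
    pool_pos, pool_neg = pooled[pooled > 0], pooled[pooled < 0]
    obs_pos = obs_nes[np.isfinite(obs_nes) & (obs_nes > 0)]
    obs_neg = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
    for sid, r in rows.items():
        nes = r["nes"]
        if not np.isfinite(nes) or nes == 0:
            r["q_fdr"] = np.nan if not np.isfinite(nes) else 1.0
            continue
        if nes > 0:
            null_tail = (pool_pos >= nes).mean() if pool_pos.size else 0.0
            obs_tail = (obs_pos >= nes).mean()
        else:
            null_tail = (pool_neg <= nes).mean() if pool_neg.size else 0.0
            obs_tail = (obs_neg <= nes).mean()
        r["q_fdr"] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "set_id"
    return out


# --------------------------------------------------------------- estimator


class LipidSetEnrichment(BaseEstimator):
    """Preranked set enrichment with permutation FDR.

    Parameters follow the conventional preranked defaults: weight
    exponent ``p_exp=1``, 1000 permutations, overlap bounds [3, 500].

    After ``fit(ranked)``:

    results_ : per-set frame (description, source, size, es, nes,
        p_nominal, q_fdr, leading_edge) — the balloon table.
    curves_ : set_id -> (rank, running_sum) frame for enrichment plots.
    skipped_ : set_id -> reason, for sets outside the overlap bounds.
    """

    def __init__(
        self,
        collection: LipidSetCollection | None = None,
        p_exp: float = 1.0,
        n_perm: int = 1000,
        min_size: int = 3,
        max_size: int = 500,
        seed: int = 0,
    ):
        self.collection = collection
        self.p_exp = p_exp
        self.n_perm = n_perm
        self.min_size = min_size
        self.max_size = max_size
        self.seed = seed

    def fit(self, ranked, y=None):
        if isinstance(ranked, pd.DataFrame):
            ranked = RankedList.from_frame(ranked)
        if self.collection is None or len(self.collection) == 0:
            warnings.warn("empty set collection; nothing to score")
            self.results_ = _empty_results()
            self.curves_, self.skipped_ = {}, {}
            return self
        present = set(ranked.ids)
        observed: dict[str, float] = {}
        nulls: dict[str, np.ndarray] = {}
        meta: dict[str, dict] = {}
        self.curves_ = {}
        self.skipped_ = {}
        for s in self.collection:
            overlap = [m for m in s.members if m in present]
            if len(overlap) < self.min_size or len(overlap) > self.max_size:
                self.skipped_[s.set_id] = (
                    f"overlap {len(overlap)} outside [{self.min_size}, "
                    f"{self.max_size}]"
                )
                continue
            if len(overlap) >= len(ranked):
                self.skipped_[s.set_id] = "set covers the whole ranked list"
                continue
            es, running, hit_idx = enrichment_score(ranked, set(overlap), self.p_exp)
            rng = np.random.default_rng(child_seed(self.seed, s.set_id))
            nulls[s.set_id] = permutation_null(
                ranked, len(overlap), self.n_perm, rng, self.p_exp
            )
            observed[s.set_id] = es
            meta[s.set_id] = {
                "description": s.description,
                "source": s.source,
                "size": len(overlap),
                "leading_edge": leading_edge(running, hit_idx, es, ranked.ids),
            }
            self.curves_[s.set_id] = pd.DataFrame(
                {"rank": np.arange(1, len(ranked) + 1), "running_sum": running}
            )
        if not observed:
            warnings.warn("no set passed the overlap filter")
            self.results_ = _empty_results()
            return self
        stats = nes_and_fdr(observed, nulls)
        extra = pd.DataFrame.from_dict(meta, orient="index")
        self.results_ = extra.join(stats)[
            ["description", "source", "size", "es", "nes", "p_nominal",
             "q_fdr", "leading_edge"]
        ]
        self.results_.index.name = "set_id"
        return self


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["description", "source", "size", "es", "nes", "p_nominal",
                 "q_fdr", "leading_edge"]
    ).rename_axis("set_id")


def run_lsea(
    ranked: pd.DataFrame | RankedList,
    collection: LipidSetCollection,
    p_exp: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 3,
    max_size: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, str]]:
    """Full enrichment pass: balloon table, per-set curves, skip report."""
    est = LipidSetEnrichment(
        collection=collection,
        p_exp=p_exp,
        n_perm=n_perm,
        min_size=min_size,
        max_size=max_size,
        seed=seed,
    ).fit(ranked)
    return est.results_, est.curves_, est.skipped_
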