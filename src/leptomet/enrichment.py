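"""Preranked metabolite-set enrichment over sub-pathway annotations.

Metabolites are ranked by the moderated t statistic (descending).  For a set
S the running sum gains ``|score_i|^p / sum_{hits} |score|^p`` at members and
loses ``1/(N - |S|)`` at non-members; the enrichment score (ES) is the signed
maximum deviation and the leading edge is the members at or before the
extremum (after it for negative ES).  The null is built by drawing random
member sets of the same size from the fixed ranking; ES is normalized by the
mean |null ES| of matching sign (NES) and the FDR q follows the pooled-null
NES convention of the preranked method.  A set is called significant when
fdr_q < 0.2 and p_raw < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FDR_THRESHOLD, NOMINAL_P

logger = logging.getLogger("leptomet")

DEFAULT_WEIGHT = 1.0
DEFAULT_MIN_SIZE = 3
DEFAULT_N_PERM = 1000


@dataclass
class RankedList:
    """Metabolite ids ordered by descending ranking score."""

    metabolite_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.metabolite_ids = np.asarray(self.metabolite_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.metabolite_ids) != len(self.scores):
            raise ValueError("ids and scores must align")
        if len(np.unique(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValueError("duplicate metabolite ids in ranking")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.metabolite_ids)

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Build from an id -> score mapping; ties broken by metabolite id."""
        frame = scores.rename("score").rename_axis("metabolite_id").reset_index()
        frame = frame.sort_values(["score", "metabolite_id"], ascending=[False, True], kind="stable")
        return cls(frame["metabolite_id"].to_numpy(), frame["score"].to_numpy())


def enrichment_score(
    ranked: RankedList, members, weight_exponent: float = DEFAULT_WEIGHT
):
    """Running-sum enrichment score for one metabolite set.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has one
    entry per ranked position and ``leading_edge`` lists the member ids at or
    before the extremum (from it onward for a negative score).
    """
    if weight_exponent < 0:
        raise ValueError("weight exponent must be >= 0")
    members = set(members)
    if not members:
        raise ValueError("empty metabolite set")
    n = len(ranked)
    if len(members) >= n:
        raise ValueError("set must be smaller than the ranked universe")
    unknown = members - set(ranked.metabolite_ids.tolist())
    if unknown:
        raise ValueError(f"set members absent from ranking: {sorted(map(str, unknown))[:5]}")

    hit = np.isin(ranked.metabolite_ids, list(members))
    return _es_from_hits(ranked.scores, hit, weight_exponent, ranked.metabolite_ids)


def _es_from_hits(scores, hit, weight_exponent, ids=None):
    n = len(scores)
    n_hit = int(hit.sum())
    weights = np.abs(scores) ** weight_exponent
    hit_weights = np.where(hit, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all member scores are zero: fall back to unweighted steps
        hit_weights = hit.astype(float)
        total = float(n_hit)
    steps = hit_weights / total - (~hit) / float(n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if ids is None:
        return float(es)
    if es >= 0:
        leading = ids[: i_max + 1][hit[: i_max + 1]]
    else:
        leading = ids[i_min:][hit[i_min:]]
    return float(es), running, list(leading)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> np.ndarray:
    """Null ES sample from uniformly random member sets of the given size.

    Sample permutation is impossible after ranking, so the null randomizes
    set membership on the fixed ranked list, reproducibly under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    n = len(ranked)
    if not 1 <= set_size <= n - 1:
        raise ValueError("set_size must be in [1, N-1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hit[:] = False
        hit[idx] = True
        out[b] = _es_from_hits(ranked.scores, hit, weight_exponent)
    return out


def normalize_and_fdr(observed: pd.DataFrame, nulls: dict[int, np.ndarray]) -> pd.DataFrame:
    """NES, permutation p and pooled-null FDR q for observed enrichment scores.

    ``observed`` needs columns set_id, es, size (plus any carried columns);
    ``nulls`` maps set size -> null ES sample.  NES divides ES by the mean
    |null ES| of matching sign from the size-matched null; p is the add-one
    corrected same-sign exceedance fraction; q compares the same-sign pooled
    null NES tail with the observed NES tail, capped at 1.
    """
    obs = observed.copy()
    nes = np.empty(len(obs))
    p_raw = np.empty(len(obs))
    null_nes_pool: list[np.ndarray] = []

    means = {}
    for size, sample in nulls.items():
        pos = sample[sample >= 0]
        neg = sample[sample < 0]
        means[size] = (
            pos.mean() if len(pos) else np.nan,
            np.abs(neg).mean() if len(neg) else np.nan,
        )
        scaled = np.where(
            sample >= 0,
            sample / means[size][0] if len(pos) else np.nan,
            sample / means[size][1] if len(neg) else np.nan,
        )
        null_nes_pool.append(scaled[np.isfinite(scaled)])
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])

    for k, row in enumerate(obs.itertuples()):
        sample = nulls[row.size]
        es = row.es
        same = sample[sample >= 0] if es >= 0 else sample[sample < 0]
        n_perm = len(sample)
        if len(same) == 0:
            logger.warning("set %s: no same-sign null values; p floored", row.set_id)
            p_raw[k] = 1.0 / (n_perm + 1)
            nes[k] = np.nan
            continue
        p_raw[k] = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
        mean_pos, mean_neg = means[row.size]
        nes[k] = es / mean_pos if es >= 0 else es / mean_neg

    obs["nes"] = nes
    obs["p_raw"] = p_raw
    obs["direction"] = np.where(obs["es"] >= 0, "up", "down")

    fdr = np.empty(len(obs))
    obs_nes = obs["nes"].to_numpy()
    for k, v in enumerate(obs_nes):
        if not np.isfinite(v):
            fdr[k] = 1.0
            continue
        if v >= 0:
            null_tail = np.mean(pool[pool >= 0] >= v) if np.any(pool >= 0) else 0.0
            obs_tail = np.mean(obs_nes[obs_nes >= 0] >= v)
        else:
            null_tail = np.mean(pool[pool < 0] <= v) if np.any(pool < 0) else 0.0
            obs_tail = np.mean(obs_nes[obs_nes < 0] <= v)
        fdr[k] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    obs["fdr_q"] = fdr
    obs["significant"] = (obs["fdr_q"] < FDR_THRESHOLD) & (obs["p_raw"] < NOMINAL_P)
    return obs


def sets_from_annotation(
    annotations: pd.DataFrame, universe, min_size: int = DEFAULT_MIN_SIZE
) -> dict[str, list]:
    """Sub-pathway -> member metabolite ids, restricted to the ranked universe."""
    universe = set(universe)
    out = {}
    for sub, grp in annotations.groupby("sub_pathway"):
        members = [m for m in grp["metabolite_id"] if m in universe]
        if len(members) >= min_size:
            out[str(sub)] = members
    return out


def run_enrichment(
    differential: pd.DataFrame,
    annotations: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    n_perm: int = DEFAULT_N_PERM,
    weight_exponent: float = DEFAULT_WEIGHT,
    seed: int = 0,
) -> pd.DataFrame:
    """Sub-pathway enrichment on metabolites preranked by moderated t."""
    ranked = RankedList.from_scores(differential.set_index("metabolite_id")["t_mod"])
    sets = sets_from_annotation(annotations, ranked.metabolite_ids, min_size)
    if not sets:
        raise ValueError("no metabolite set passes the size filter")

    rows = []
    leading = {}
    for set_id, members in sorted(sets.items()):
        es, _, le = enrichment_score(ranked, members, weight_exponent)
        rows.append({"set_id": set_id, "es": es, "size": len(members)})
        leading[set_id] = le
    obs = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    nulls = {
        size: permutation_null(ranked, size, n_perm, rng, weight_exponent)
        for size in sorted(obs["size"].unique())
    }
    result = normalize_and_fdr(obs, nulls)
    result["leading_edge"] = result["set_id"].map(leading)
    result["leading_edge_fraction"] = result["leading_edge"].map(len) / result["size"]
    return result.sort_values(["fdr_q", "p_raw", "set_id"], kind="stable").reset_index(drop=True)
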