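"""BMI metabolomic score and correlation statistics.

The score transfers a reference BMI signature (metabolite name + direction of
correlation with BMI, weights restricted to +/-1) onto a new panel: matched
metabolites are z-scored across the scoring cohort and summed with their
signs.  Children and adults are scored separately; the cohort is always an
explicit argument.  Associations are summarized as Pearson r with a Fisher-z
95% interval, tanh(atanh(r) +/- 1.96/sqrt(n-3)), and a two-sided p from the
t reference with n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossstudy import normalize_name
from .dataio import AbundanceMatrix

logger = logging.getLogger("leptomet")

Z_95 = 1.96


@dataclass
class ScoreModel:
    """Signed metabolite weights transferred from a reference signature."""

    entries: list[tuple[str, int]]  # (metabolite_id, weight in {-1, +1})
    n_reference: int

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolites in score model")
        if any(w not in (-1, 1) for _, w in self.entries):
            raise ValueError("score weights must be +1 or -1")
        if self.n_matched > self.n_reference:
            raise ValueError("matched more metabolites than the reference contains")

    @property
    def n_matched(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AssociationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float


def build_score_model(
    reference_directions: pd.DataFrame, available: pd.DataFrame
) -> ScoreModel:
    """Intersect a reference signature with the measured panel.

    ``reference_directions`` needs columns metabolite_name and direction
    (+1/-1); ``available`` is the annotation table (metabolite_id,
    biochemical_name).  Matching is by normalized biochemical name.
    """
    if not {"metabolite_name", "direction"} <= set(reference_directions.columns):
        raise ValueError("reference table needs metabolite_name and direction columns")
    directions = reference_directions["direction"].astype(int)
    if not directions.isin([-1, 1]).all():
        raise ValueError("reference directions must be +1 or -1")

    # keep parentheticals: lipid names are distinguished by their (C:D) token
    panel = {
        normalize_name(name, strip_parenthetical=False): mid
        for mid, name in zip(available["metabolite_id"], available["biochemical_name"])
    }
    entries = []
    unmatched = []
    seen = set()
    for name, sign in zip(reference_directions["metabolite_name"], directions):
        key = normalize_name(name, strip_parenthetical=False)
        mid = panel.get(key)
        if mid is None or mid in seen:
            unmatched.append(name)
            continue
        seen.add(mid)
        entries.append((mid, int(sign)))
    if not entries:
        raise ValueError("no reference metabolite matches the measured panel")
    if unmatched:
        logger.info("reference entries without a panel match: %s", ", ".join(map(str, unmatched[:10])))
    return ScoreModel(entries=entries, n_reference=len(reference_directions))


def compute_scores(
    matrix: AbundanceMatrix, model: ScoreModel, cohort
) -> pd.Series:
    """Signed sum of cohort-standardized metabolite values per sample.

    Each matched metabolite is z-scored across the cohort (ddof=1);
    zero-variance metabolites are dropped with a log message.  Cohort scores
    have mean 0 by construction.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValueError("standardization needs >= 3 samples in the cohort")
    data = matrix.data.loc[cohort]
    score = pd.Series(0.0, index=data.index, name="bmi_score")
    used = 0
    for mid, w in model.entries:
        x = data[mid].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("metabolite %s has zero variance in cohort; dropped from score", mid)
            continue
        score += w * (x - x.mean()) / sd
        used += 1
    if used == 0:
        raise ValueError("no score metabolite has variance in this cohort")
    return score


def pearson_with_ci(x, y) -> AssociationResult:
    """Pearson r with Fisher-z 95% CI and two-sided t-reference p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return fisher_ci(r, n)


def fisher_ci(r: float, n: int) -> AssociationResult:
    """CI and p for a given correlation and sample size (no raw data needed)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) == 1.0:
        return AssociationResult(r=r, n=n, ci_low=r, ci_high=r, p=0.0)
    z = np.arctanh(r)
    half = Z_95 / np.sqrt(n - 3)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return AssociationResult(
        r=r, n=n, ci_low=float(np.tanh(z - half)), ci_high=float(np.tanh(z + half)), p=p
    )
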