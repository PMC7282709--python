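"""Lipid structure parsing and structure-response association tests.

Vendor biochemical names encode fatty-acid structure as a ``(C:D...)`` token,
e.g. ``oleate (18:1n9)`` — C carbons, D double bonds.  Chain-length classes
follow the platform bins: medium chain C6-12, long chain C13-21, very long
chain C22 or more (shorter chains are labeled "short" and excluded from the
three classes).  Saturation classes: saturated (0 double bonds),
monounsaturated (1), polyunsaturated (>= 2).

Association tests take log10 fold changes from the differential stage:
Pearson correlation of chain length vs response within a length class
(Fisher-z CI), a Kruskal-Wallis rank test across saturation classes, and a
Fisher exact test of 12a-hydroxylation status against leading-edge presence
for bile acids (conditional-MLE odds ratio with exact CI).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .scores import AssociationResult, pearson_with_ci

_FA_TOKEN = re.compile(r"\((\d+):(\d+)[^)]*\)")
_FA_MALFORMED = re.compile(r"\(\d+:[^0-9)][^)]*\)|\(\d+:\)")

LENGTH_CLASSES = ("short", "medium", "long", "very_long")
SATURATION_CLASSES = ("saturated", "monounsaturated", "polyunsaturated")


@dataclass(frozen=True)
class FattyAcidStructure:
    chain_length: int
    double_bonds: int

    @property
    def saturation_class(self) -> str:
        if self.double_bonds == 0:
            return "saturated"
        if self.double_bonds == 1:
            return "monounsaturated"
        return "polyunsaturated"

    @property
    def length_class(self) -> str:
        if self.chain_length >= 22:
            return "very_long"
        if self.chain_length >= 13:
            return "long"
        if self.chain_length >= 6:
            return "medium"
        return "short"


def parse_fatty_acid(name: str) -> FattyAcidStructure | None:
    """Extract the first ``(C:D)`` token from a biochemical name.

    Returns None when no token is present; malformed tokens like ``(18:)``
    trigger a warning and None.
    """
    s = str(name)
    match = _FA_TOKEN.search(s)
    if match is None:
        if _FA_MALFORMED.search(s):
            warnings.warn(f"malformed fatty-acid token in {name!r}", stacklevel=2)
        return None
    return FattyAcidStructure(chain_length=int(match.group(1)), double_bonds=int(match.group(2)))


def annotate_structures(annotations: pd.DataFrame) -> pd.DataFrame:
    """Structure table for all annotation rows with a parseable name.

    Explicit ``chain_length``/``double_bonds`` columns win over the parsed
    token when present.
    """
    rows = []
    for _, row in annotations.iterrows():
        cl = row.get("chain_length")
        db = row.get("double_bonds")
        if pd.notna(cl) and pd.notna(db):
            fa = FattyAcidStructure(int(cl), int(db))
        else:
            fa = parse_fatty_acid(row["biochemical_name"])
            if fa is None:
                continue
        rows.append(
            {
                "metabolite_id": row["metabolite_id"],
                "chain_length": fa.chain_length,
                "double_bonds": fa.double_bonds,
                "saturation_class": fa.saturation_class,
                "length_class": fa.length_class,
            }
        )
    return pd.DataFrame(rows, columns=["metabolite_id", "chain_length", "double_bonds",
                                       "saturation_class", "length_class"])


def chainlength_response_correlation(
    fold_changes: pd.Series, structures: pd.DataFrame, length_class: str
) -> AssociationResult:
    """Pearson correlation of chain length vs log10 fold change in a class."""
    if length_class not in LENGTH_CLASSES:
        raise ValueError(f"unknown length class {length_class!r}")
    sub = structures[structures["length_class"] == length_class]
    sub = sub[sub["metabolite_id"].isin(fold_changes.index)]
    if len(sub) < 4:
        raise ValueError(f"need >= 4 metabolites in class {length_class!r}, have {len(sub)}")
    lengths = sub["chain_length"].to_numpy(dtype=float)
    if np.ptp(lengths) == 0:
        raise ValueError("all chain lengths identical; correlation undefined")
    fc = fold_changes.loc[sub["metabolite_id"]].to_numpy(dtype=float)
    return pearson_with_ci(lengths, fc)


def saturation_class_test(fold_changes: pd.Series, structures: pd.DataFrame):
    """Kruskal-Wallis rank test of response across saturation classes.

    Returns ``(H, df, p)`` with tie correction; df = groups - 1.  All values
    identical yields H = 0, p = 1 by convention.
    """
    groups = []
    for cls in SATURATION_CLASSES:
        ids = structures.loc[structures["saturation_class"] == cls, "metabolite_id"]
        ids = ids[ids.isin(fold_changes.index)]
        vals = fold_changes.loc[ids].to_numpy(dtype=float)
        if len(vals):
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty saturation classes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each saturation class needs >= 2 members")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def hydroxylation_leading_edge_test(is_12a, in_leading_edge):
    """Fisher exact test: 12a-hydroxylation status vs leading-edge presence.

    Returns ``(odds_ratio, (ci_low, ci_high), p)`` — conditional-MLE odds
    ratio with exact 95% CI and the two-sided Fisher p.
    """
    is_12a = np.asarray(is_12a, dtype=bool)
    in_le = np.asarray(in_leading_edge, dtype=bool)
    if len(is_12a) != len(in_le):
        raise ValueError("inputs must align")
    a = int(np.sum(is_12a & in_le))
    b = int(np.sum(is_12a & ~in_le))
    c = int(np.sum(~is_12a & in_le))
    d = int(np.sum(~is_12a & ~in_le))
    table = np.array([[a, b], [c, d]])
    margins = {
        "12a-hydroxylated": a + b,
        "non-12a-hydroxylated": c + d,
        "leading edge": a + c,
        "outside leading edge": b + d,
    }
    zero = [k for k, v in margins.items() if v == 0]
    if zero:
        raise ValueError(f"zero margin: {zero[0]}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(p)


def lipid_stats(
    differential: pd.DataFrame,
    annotations: pd.DataFrame,
    leading_edge: set | None = None,
) -> pd.DataFrame:
    """Run the lipid structure-response battery; one row per test."""
    structures = annotate_structures(annotations)
    fc = differential.set_index("metabolite_id")["effect"]
    rows = []
    for cls in ("medium", "long", "very_long"):
        try:
            assoc = chainlength_response_correlation(fc, structures, cls)
        except ValueError:
            continue
        rows.append(
            {"test": f"chainlength_correlation_{cls}", "statistic": assoc.r, "df": assoc.n - 2,
             "p": assoc.p, "ci_low": assoc.ci_low, "ci_high": assoc.ci_high, "n": assoc.n}
        )
    try:
        h, df, p = saturation_class_test(fc, structures)
        rows.append({"test": "saturation_kruskal_wallis", "statistic": h, "df": df, "p": p,
                     "n": int(structures["metabolite_id"].isin(fc.index).sum())})
    except ValueError:
        pass
    if leading_edge is not None and "is_12a_hydroxylated" in annotations.columns:
        bile = annotations.dropna(subset=["is_12a_hydroxylated"])
        if len(bile):
            flags = bile["is_12a_hydroxylated"].astype(bool).to_numpy()
            in_le = bile["metabolite_id"].isin(leading_edge).to_numpy()
            try:
                orat, ci, p = hydroxylation_leading_edge_test(flags, in_le)
                rows.append({"test": "bile_acid_12a_leading_edge", "statistic": orat,
                             "p": p, "ci_low": ci[0], "ci_high": ci[1], "n": len(bile)})
            except ValueError:
                pass
    return pd.DataFrame(rows)
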