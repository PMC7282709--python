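"""Cross-study metabolite matching and fold-change concordance.

Two panels from the same vendor rarely share identifiers: biochemical names
carry asterisks, bracketed isomer qualifiers and punctuation that drift
between annotation versions.  Matching runs in three tiers — exact name,
normalized name, normalized name + sub-pathway agreement — and refuses
many-to-many candidates rather than guessing.  Concordance between two
studies' responses is summarized per sub-pathway as the fraction of shared
metabolites with the same fold-change sign and the Pearson correlation of
log10 fold changes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("leptomet")

_PAREN = re.compile(r"[\(\[][^()\[\]]*[\)\]]")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_name(name: str, strip_parenthetical: bool = True) -> str:
    """Canonical form of a biochemical name for cross-annotation matching.

    Lowercase, asterisks removed, bracketed/parenthesized qualifiers dropped
    (optional), runs of non-alphanumerics collapsed to single spaces.
    """
    s = str(name).lower().replace("*", " ")
    if strip_parenthetical:
        stripped = _PAREN.sub(" ", s)
        # Keep the qualifier when the name is nothing but a qualifier.
        if stripped.strip():
            s = stripped
    return _NON_ALNUM.sub(" ", s).strip()


@dataclass
class MatchTable:
    pairs: pd.DataFrame  # id_a, id_b, match_type
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)


def _unique_map(keys, ids):
    """key -> id for keys occurring exactly once; ambiguous keys -> None."""
    out: dict = {}
    for key, mid in zip(keys, ids):
        out[key] = None if key in out else mid
    return out


def match_metabolites(annot_a: pd.DataFrame, annot_b: pd.DataFrame) -> MatchTable:
    """Three-tier name matching between two annotation tables."""
    for name, ann in (("A", annot_a), ("B", annot_b)):
        if ann.empty:
            raise ValueError(f"annotation table {name} is empty")
        if not {"metabolite_id", "biochemical_name", "sub_pathway"} <= set(ann.columns):
            raise ValueError(f"annotation {name} needs metabolite_id, biochemical_name, sub_pathway")

    a = annot_a.reset_index(drop=True)
    b = annot_b.reset_index(drop=True)
    pairs = []
    used_a: set = set()
    used_b: set = set()

    def claim(id_a, id_b, tier):
        pairs.append({"id_a": id_a, "id_b": id_b, "match_type": tier})
        used_a.add(id_a)
        used_b.add(id_b)

    # Tier 1: exact biochemical name.
    exact_b = _unique_map(b["biochemical_name"], b["metabolite_id"])
    exact_a_counts = a["biochemical_name"].value_counts()
    for name, id_a in zip(a["biochemical_name"], a["metabolite_id"]):
        if exact_a_counts[name] > 1:
            continue
        id_b = exact_b.get(name)
        if id_b is not None and id_b not in used_b:
            claim(id_a, id_b, "exact_name")

    # Tier 2: normalized name, unique on both sides.
    a_rem = a[~a["metabolite_id"].isin(used_a)]
    b_rem = b[~b["metabolite_id"].isin(used_b)]
    norm_a = a_rem["biochemical_name"].map(normalize_name)
    norm_b = b_rem["biochemical_name"].map(normalize_name)
    map_b = _unique_map(norm_b, b_rem["metabolite_id"])
    counts_a = norm_a.value_counts()
    ambiguous = []
    for key, id_a in zip(norm_a, a_rem["metabolite_id"]):
        if counts_a[key] > 1 or map_b.get(key, "absent") is None:
            ambiguous.append((key, id_a))
            continue
        id_b = map_b.get(key)
        if id_b is not None and id_b not in used_b:
            claim(id_a, id_b, "name_normalized")

    # Tier 3: normalized name + sub-pathway agreement for leftover ambiguity.
    b_rem2 = b[~b["metabolite_id"].isin(used_b)]
    b_keyed: dict = {}
    for id_b, name, sub in zip(
        b_rem2["metabolite_id"], b_rem2["biochemical_name"], b_rem2["sub_pathway"]
    ):
        b_keyed.setdefault((normalize_name(name), str(sub)), []).append(id_b)
    a_rem2 = a[~a["metabolite_id"].isin(used_a)]
    for id_a, name, sub in zip(
        a_rem2["metabolite_id"], a_rem2["biochemical_name"], a_rem2["sub_pathway"]
    ):
        cands = b_keyed.get((normalize_name(name), str(sub)), [])
        cands = [c for c in cands if c not in used_b]
        if len(cands) == 1:
            claim(id_a, cands[0], "subpathway_assisted")
        elif len(cands) > 1:
            logger.warning("ambiguous cross-study match for %r left unmatched", name)

    pair_frame = pd.DataFrame(pairs, columns=["id_a", "id_b", "match_type"])
    return MatchTable(
        pairs=pair_frame,
        unmatched_a=[i for i in a["metabolite_id"] if i not in used_a],
        unmatched_b=[i for i in b["metabolite_id"] if i not in used_b],
    )


def concordance(
    fc_a: pd.Series,
    fc_b: pd.Series,
    matches: MatchTable,
    grouping: pd.Series,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-group agreement of log10 fold changes across two studies.

    ``fc_a``/``fc_b`` map metabolite ids to log10 fold changes; ``grouping``
    maps study-A ids to sub-pathways.  Groups with fewer than ``min_group``
    shared metabolites report n only.  Pearson r requires n >= 4 (Fisher-z).
    """
    from .scores import pearson_with_ci  # local import to avoid a cycle

    shared = matches.pairs[
        matches.pairs["id_a"].isin(fc_a.index) & matches.pairs["id_b"].isin(fc_b.index)
    ]
    rows = []
    groups = grouping.loc[shared["id_a"]].to_numpy()
    for group in sorted(pd.unique(groups).tolist()) + ["__all__"]:
        sub = shared if group == "__all__" else shared[groups == group]
        x = fc_a.loc[sub["id_a"]].to_numpy(dtype=float)
        y = fc_b.loc[sub["id_b"]].to_numpy(dtype=float)
        row = {"group": "all" if group == "__all__" else group, "n_shared": len(sub)}
        if len(sub) >= min_group:
            nonzero = (x != 0) & (y != 0)
            row["sign_agreement"] = float(np.mean(np.sign(x[nonzero]) == np.sign(y[nonzero])))
            if len(sub) >= 4 and x.std() > 0 and y.std() > 0:
                assoc = pearson_with_ci(x, y)
                row.update(pearson_r=assoc.r, ci_low=assoc.ci_low, ci_high=assoc.ci_high, p=assoc.p)
        rows.append(row)
    return pd.DataFrame(rows)
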