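"""Cluster-scale indicators: the observed variables of the factor stage.

Four schemes:

- ``triplet54`` — per facet, three 3-item parcels (positive identity,
  negative identity after orientation, self-efficacy): 54 indicators.
- ``identity18`` — per facet, one 6-item identity scale: 18 indicators.
- ``se18`` — per facet, one 3-item self-efficacy scale: 18 indicators.
- ``joint36`` — identity18 and se18 side by side: 36 indicators.

Input is an oriented real matrix (corrected-and-key-oriented, or raw with
negative items reversed as 6 - x): high always means high skill. Indicator
labels embed facet and framing, e.g. ``empathy/identity_neg``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blueprint import InstrumentBlueprint

SCHEMES = ("triplet54", "identity18", "se18", "joint36")


def reverse_raw(responses: pd.DataFrame, bp: InstrumentBlueprint) -> pd.DataFrame:
    """Raw-score reversal: identity_neg items mapped x -> 6 - x, all other
    items unchanged. Values must lie in 1..5; missing passes through."""
    vals = responses.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 1 or finite.max() > 5):
        raise ValueError("reverse_raw expects values in 1..5")
    out = responses.astype(float).copy()
    neg = [it.item_id for it in bp.items
           if it.framing == "identity_neg" and it.item_id in out.columns]
    out[neg] = 6.0 - out[neg]
    return out


def scheme_groups(bp: InstrumentBlueprint, scheme: str) -> list[tuple[str, list[str]]]:
    """(label, member item_ids) per indicator, in blueprint facet order."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    by_facet: dict[str, dict[str, list[str]]] = {}
    for it in bp.items:
        by_facet.setdefault(it.facet, {}).setdefault(it.framing, []).append(it.item_id)
    facet_order = [f.facet_id for f in bp.facets]
    groups: list[tuple[str, list[str]]] = []
    if scheme == "triplet54":
        for facet in facet_order:
            for framing in ("identity_neg", "identity_pos", "self_efficacy"):
                groups.append((f"{facet}/{framing}", by_facet[facet][framing]))
    elif scheme == "identity18":
        for facet in facet_order:
            groups.append(
                (f"{facet}/identity",
                 by_facet[facet]["identity_neg"] + by_facet[facet]["identity_pos"])
            )
    elif scheme == "se18":
        for facet in facet_order:
            groups.append((f"{facet}/self_efficacy", by_facet[facet]["self_efficacy"]))
    else:  # joint36
        for facet in facet_order:
            groups.append(
                (f"{facet}/identity",
                 by_facet[facet]["identity_neg"] + by_facet[facet]["identity_pos"])
            )
        for facet in facet_order:
            groups.append((f"{facet}/self_efficacy", by_facet[facet]["self_efficacy"]))
    return groups


def indicator_facet(label: str) -> str:
    return label.split("/")[0]


def indicator_framing(label: str) -> str:
    return label.split("/")[1]


def cluster_scores(
    matrix: pd.DataFrame,
    bp: InstrumentBlueprint,
    scheme: str = "triplet54",
    min_answered_frac: float = 2 / 3,
) -> pd.DataFrame:
    """Average item members into indicator scales.

    A respondent's indicator is missing when fewer than
    ``min_answered_frac`` of its member items were answered (default: at
    least 2 of 3, at least 4 of 6).
    """
    groups = scheme_groups(bp, scheme)
    missing_items = {i for _, ids in groups for i in ids} - set(matrix.columns)
    if missing_items:
        raise ValueError(
            f"matrix lacks blueprint items: {sorted(missing_items)[:5]}"
        )
    cols = {}
    for label, ids in groups:
        block = matrix[ids]
        n_ans = block.notna().sum(axis=1)
        mean = block.mean(axis=1)
        need = int(np.ceil(min_answered_frac * len(ids)))
        cols[label] = mean.where(n_ans >= need)
    return pd.DataFrame(cols, index=matrix.index)
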