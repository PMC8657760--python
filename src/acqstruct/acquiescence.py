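"""Per-respondent acquiescence estimation and within-person correction.

On a balanced scale — every facet pairing each positively keyed identity item
with a negative ("antonym") counterpart — a respondent answering with
symmetric pair profiles (1-5, 2-4, 3-3, 4-2, 5-1) averages exactly 3, the
scale midpoint. The acquiescence index (ACQ) is therefore the respondent's
mean over all identity items *before* any reversal: deviations from 3
measure content-blind agreement (ACQ > 3) or disagreement (ACQ < 3).

Correction subtracts each respondent's ACQ from every one of their item
scores, including the all-positively-keyed self-efficacy items that cannot
inform ACQ themselves. Order matters: centering happens on raw scores and
negatively keyed content is re-oriented afterwards by multiplying with the
key sign. Reversing first (6 - x) and centering second doubles the
acquiescence term on negative items instead of removing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blueprint import BlueprintError, InstrumentBlueprint

logger = logging.getLogger("acqstruct.acquiescence")


@dataclass
class AcquiescenceVector:
    """Per-respondent ACQ on the 1-5 response scale.

    ``balanced_flag`` is False when the estimate rests on too few identity
    items or too many broken antonym pairs (thresholds configurable in
    :func:`compute_acq`); such estimates mix content into ACQ.
    """

    table: pd.DataFrame  # index respondent_id; columns acq, n_items_used, balanced_flag

    @property
    def acq(self) -> pd.Series:
        return self.table["acq"]

    @property
    def respondent_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class CorrectedResponses:
    """Within-person centered item scores (reals, possibly negative)."""

    values: pd.DataFrame  # index respondent_id, columns item_id
    acq_used: AcquiescenceVector


def validate_responses(responses: pd.DataFrame, bp: InstrumentBlueprint) -> None:
    if responses.shape[0] == 0:
        raise ValueError("response matrix has no respondents")
    unknown = set(responses.columns) - set(bp.item_ids)
    if unknown:
        raise ValueError(f"response columns not in blueprint: {sorted(unknown)[:5]}")
    vals = responses.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 1 or finite.max() > 5
                        or np.any(finite != np.round(finite))):
        raise ValueError("responses must be integers in 1..5 (or missing)")


def compute_acq(
    responses: pd.DataFrame,
    bp: InstrumentBlueprint,
    min_identity_items: int = 54,
    max_incomplete_pair_frac: float = 0.25,
) -> AcquiescenceVector:
    """ACQ = mean of raw (un-reversed) identity-item responses per respondent.

    Missing responses are dropped from the mean. A respondent is flagged
    unbalanced when fewer than ``min_identity_items`` identity items were
    answered or more than ``max_incomplete_pair_frac`` of their answered
    pairs are incomplete (one member missing). Respondents with zero usable
    identity items keep a row with ``acq`` missing.
    """
    validate_responses(responses, bp)
    from .blueprint import antonym_pairs

    pairs = antonym_pairs(bp)
    if not pairs:
        raise BlueprintError("blueprint has no antonym pairs; ACQ undefined")

    id_items = [i for i in bp.identity_item_ids if i in responses.columns]
    if not id_items:
        raise ValueError("no identity items present in the response matrix")
    ident = responses[id_items].to_numpy(float)
    answered = np.isfinite(ident)
    n_used = answered.sum(axis=1)
    with np.errstate(invalid="ignore"):
        acq = np.nansum(ident, axis=1) / np.where(n_used > 0, n_used, np.nan)

    # pair completeness: among pairs with >= 1 answered member, fraction broken
    pos_idx, neg_idx, have = [], [], []
    col = {c: i for i, c in enumerate(id_items)}
    for p, n in pairs:
        if p.item_id in col and n.item_id in col:
            pos_idx.append(col[p.item_id])
            neg_idx.append(col[n.item_id])
    pos_idx = np.array(pos_idx, int)
    neg_idx = np.array(neg_idx, int)
    pos_ok = answered[:, pos_idx]
    neg_ok = answered[:, neg_idx]
    touched = pos_ok | neg_ok
    broken = touched & ~(pos_ok & neg_ok)
    with np.errstate(invalid="ignore"):
        broken_frac = np.where(
            touched.sum(axis=1) > 0,
            broken.sum(axis=1) / np.maximum(touched.sum(axis=1), 1),
            1.0,
        )
    balanced = (n_used >= min_identity_items) & (broken_frac <= max_incomplete_pair_frac)

    n_flagged = int((~balanced).sum())
    if n_flagged:
        logger.warning("ACQ: %d of %d respondents flagged unbalanced",
                       n_flagged, len(responses))
    table = pd.DataFrame(
        {"acq": acq, "n_items_used": n_used.astype(int), "balanced_flag": balanced},
        index=responses.index,
    )
    return AcquiescenceVector(table)


def center_responses(
    responses: pd.DataFrame,
    acq: AcquiescenceVector,
    bp: InstrumentBlueprint,
) -> CorrectedResponses:
    """Subtract each respondent's ACQ from every item score (identity and
    self-efficacy). Missing stays missing; respondents without an ACQ value
    are dropped (count logged)."""
    validate_responses(responses, bp)
    missing_ids = responses.index.difference(acq.respondent_ids)
    if len(missing_ids):
        raise ValueError(
            f"{len(missing_ids)} respondents have no ACQ entry (id mismatch)"
        )
    a = acq.acq.reindex(responses.index)
    usable = a.notna()
    dropped = int((~usable).sum())
    if dropped:
        logger.info("centering: dropped %d respondents without ACQ", dropped)
    centered = responses.loc[usable].astype(float).sub(a[usable], axis=0)
    kept = AcquiescenceVector(acq.table.loc[centered.index])
    return CorrectedResponses(values=centered, acq_used=kept)


def key_orient(corrected: CorrectedResponses, bp: InstrumentBlueprint) -> pd.DataFrame:
    """Multiply centered scores by the item key sign so high always means
    high skill. Applied AFTER centering; self-efficacy items (key +1) are
    unchanged."""
    keys = bp.keys().reindex(corrected.values.columns)
    if keys.isna().any():
        raise BlueprintError(
            f"items without blueprint keys: {list(keys.index[keys.isna()])[:5]}"
        )
    return corrected.values.mul(keys.astype(float), axis=1)
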