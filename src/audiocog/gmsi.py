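"""Scoring and simulation of the Goldsmiths Musical Sophistication Index (short form).

The short GMSI has 38 items answered on a 7-point scale, partitioned into five
domains (Active Engagement, Perceptual Abilities, Musical Training, Singing
Abilities, Emotions).  The total score is the sum of the five domain scores —
equivalently of all items — ranging from 38 (all minimum) to 266 (all maximum).

Scoring is independent of the particular item→domain partition: the partition
is a configuration artifact passed to :func:`score_gmsi`.  The default map is
a synthetic stand-in with the canonical domain sizes (9, 9, 7, 7, 6) assigning
consecutive item blocks to domains; it is not the published questionnaire key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "DOMAINS",
    "ITEM_MIN",
    "ITEM_MAX",
    "N_ITEMS",
    "MIN_TOTAL",
    "MAX_TOTAL",
    "GmsiScore",
    "default_domain_map",
    "score_gmsi",
    "simulate_gmsi_items",
    "items_with_total",
]

DOMAINS = (
    "active_engagement",
    "perceptual_abilities",
    "musical_training",
    "singing_abilities",
    "emotions",
)

#: number of items per domain in the short form (sums to 38)
DOMAIN_SIZES = (9, 9, 7, 7, 6)

N_ITEMS = sum(DOMAIN_SIZES)
ITEM_MIN, ITEM_MAX = 1, 7
MIN_TOTAL = N_ITEMS * ITEM_MIN
MAX_TOTAL = N_ITEMS * ITEM_MAX  # = 266


@dataclass(frozen=True)
class GmsiScore:
    total: int
    domain_scores: dict


def default_domain_map() -> tuple:
    """Synthetic item→domain assignment with the canonical domain sizes.

    Consecutive blocks of items are assigned to the five domains.  Scoring
    results that depend only on the total are invariant to the partition.
    """
    assignment = []
    for domain, size in zip(DOMAINS, DOMAIN_SIZES):
        assignment.extend([domain] * size)
    return tuple(assignment)


def score_gmsi(items, domain_map=None) -> GmsiScore:
    """Score a GMSI response vector.

    Parameters
    ----------
    items
        Sequence of integer responses, one per item, each in [1, 7].
    domain_map
        Item→domain assignment of the same length; defaults to
        :func:`default_domain_map`.

    Returns
    -------
    GmsiScore
        Domain sums and the total (= sum of domains = sum of items).
    """
    if domain_map is None:
        domain_map = default_domain_map()
    arr = np.asarray(items)
    if arr.ndim != 1 or arr.size != len(domain_map):
        raise ValidationError(
            f"expected {len(domain_map)} items, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.asarray(arr, dtype=float) == np.floor(np.asarray(arr, dtype=float))):
            raise ValidationError("item responses must be integers")
        arr = arr.astype(int)
    if np.any(arr < ITEM_MIN) or np.any(arr > ITEM_MAX):
        bad = arr[(arr < ITEM_MIN) | (arr > ITEM_MAX)]
        raise ValidationError(f"item responses outside [1, 7]: {bad.tolist()}")

    domain_scores = {d: 0 for d in dict.fromkeys(domain_map)}
    for value, domain in zip(arr.tolist(), domain_map):
        domain_scores[domain] += value
    return GmsiScore(total=int(arr.sum()), domain_scores=domain_scores)


def simulate_gmsi_items(propensity: float, item_sd: float, rng, n_items: int = N_ITEMS) -> np.ndarray:
    """Draw a raw item vector around a per-person propensity.

    Each item is ``clip(round(propensity + N(0, item_sd)), 1, 7)`` — Likert
    scatter around the person's mean endorsement level.
    """
    if item_sd < 0:
        raise ValidationError("item_sd must be >= 0")
    raw = propensity + rng.normal(0.0, item_sd, size=n_items)
    return np.clip(np.rint(raw), ITEM_MIN, ITEM_MAX).astype(int)


def items_with_total(total: float, item_sd: float, rng, n_items: int = N_ITEMS) -> np.ndarray:
    """Item vector with realistic scatter whose sum equals ``round(total)`` exactly.

    The target total is clipped into the attainable range [38, 266].  A raw
    vector is drawn with :func:`simulate_gmsi_items` around the implied mean
    endorsement, then single-point increments/decrements at random positions
    close the gap to the target, keeping every item inside [1, 7].  This makes
    the questionnaire total an exact function of the latent session value while
    preserving item-level variability.
    """
    target = int(np.clip(np.rint(total), n_items * ITEM_MIN, n_items * ITEM_MAX))
    items = simulate_gmsi_items(target / n_items, item_sd, rng, n_items=n_items)
    gap = target - int(items.sum())
    step = 1 if gap > 0 else -1
    limit = ITEM_MAX if gap > 0 else ITEM_MIN
    while gap != 0:
        movable = np.flatnonzero(items != limit)
        pick = movable[rng.integers(movable.size)]
        items[pick] += step
        gap -= step
    return items
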