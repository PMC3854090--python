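"""Compound-pair enumeration with censoring exclusions and potency deltas.

Every unordered pair of compounds yields two ordered pairs (a
transformation and its reverse), except pairs that carry no usable
information: both IC50s censored in the same direction (their true
difference is unknown), or identical fingerprints (no transformation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .chem_io import ActivityRecord, CensoredValue, Qualifier
from .fingerprints import (
    DEFAULT_DIAMETER,
    TransformationKey,
    compute_feature_multiset,
    difference_fingerprint,
)
from .lipophilicity import slogp

log = logging.getLogger(__name__)

__all__ = ["MolecularPair", "delta_log_ic50", "enumerate_pairs"]


@dataclass(frozen=True)
class MolecularPair:
    """An ordered compound pair with its transformation key and deltas.

    ``delta_log_ic50`` is log10(final IC50) − log10(initial IC50) in μM;
    positive means the final compound is the weaker hERG inhibitor.
    """

    initial: ActivityRecord
    final: ActivityRecord
    key: TransformationKey
    delta_log_ic50: float
    delta_slogp: float

    def reversed(self) -> "MolecularPair":
        from .fingerprints import reverse_key

        return MolecularPair(
            initial=self.final,
            final=self.initial,
            key=reverse_key(self.key),
            delta_log_ic50=-self.delta_log_ic50,
            delta_slogp=-self.delta_slogp,
        )


def delta_log_ic50(initial: CensoredValue, final: CensoredValue) -> float:
    """Difference in log10 IC50 (μM), final minus initial."""
    return math.log10(final.value_um) - math.log10(initial.value_um)


def _same_direction_censored(a: CensoredValue, b: CensoredValue) -> bool:
    return (
        a.qualifier is not Qualifier.EXACT and a.qualifier is b.qualifier
    )


def enumerate_pairs(
    records: Sequence[ActivityRecord],
    diameter: int = DEFAULT_DIAMETER,
    max_changed_features: int | None = None,
    compute_slogp: bool = True,
) -> list[MolecularPair]:
    """All ordered compound pairs that pass the censoring and key filters.

    Excluded: pairs whose IC50s are both off scale in the same
    direction; pairs with an empty transformation key (identical
    fingerprints); and, when ``max_changed_features`` is set, pairs
    whose key changes more feature occurrences than that cap. Both
    ordered directions of every retained unordered pair are emitted.
    """
    if len(records) < 2:
        log.warning("fewer than 2 records; no pairs to enumerate")
        return []

    multisets = [compute_feature_multiset(r.mol, diameter) for r in records]
    slogps = [slogp(r.mol).value if compute_slogp else 0.0 for r in records]

    pairs: list[MolecularPair] = []
    n_censored = n_empty = n_capped = 0
    for i, j in combinations(range(len(records)), 2):
        a, b = records[i], records[j]
        if _same_direction_censored(a.ic50, b.ic50):
            n_censored += 1
            continue
        key = difference_fingerprint(multisets[i], multisets[j])
        if key.is_empty:
            n_empty += 1
            continue
        if max_changed_features is not None and key.n_changed_features > max_changed_features:
            n_capped += 1
            continue
        forward = MolecularPair(
            initial=a,
            final=b,
            key=key,
            delta_log_ic50=delta_log_ic50(a.ic50, b.ic50),
            delta_slogp=slogps[j] - slogps[i],
        )
        pairs.append(forward)
        pairs.append(forward.reversed())
    log.info(
        "%d ordered pairs from %d records (excluded: %d both-censored, "
        "%d identical-fingerprint, %d over feature cap)",
        len(pairs), len(records), n_censored, n_empty, n_capped,
    )
    return pairs
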