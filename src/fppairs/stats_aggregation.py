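"""Aggregation of pairs by transformation key and exact small-sample tests.

An aggregate collects every pair that makes the same transformation
(identical difference fingerprint). Whether an aggregate's effect on
potency is consistent is judged against the null hypothesis that each
pair is equally likely to increase or decrease IC50, using two exact
nonparametric tests:

* the sign test — the binomial(n, 1/2) tail probability of a direction
  split at least as one-sided as observed; under the null, five pairs
  all moving one way occur 2 × (1/2)^5 = 6.25% of the time, which
  motivates the n ≥ 5 reporting threshold;
* the Wilcoxon signed-rank test — the exact tail of the signed-rank
  statistic over all 2^n equally likely sign assignments of the ranked
  absolute differences (for eight pairs with one discordant value of
  rank 4, the two-sided tail is 14/256 ≈ 5.47%).

Both are computed in closed form / by exact counting; no normal
approximation is used at the sample sizes where aggregates are judged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .fingerprints import (
    TransformationKey,
    canonical_orientation,
    key_string,
    reverse_key,
)
from .pairing import MolecularPair

log = logging.getLogger(__name__)

__all__ = [
    "Aggregate",
    "SignificanceConfig",
    "sign_test_exact",
    "signed_rank_exact",
    "geometric_mean_fold",
    "aggregate_pairs",
    "filter_significant",
    "size_histogram",
]

#: Largest n for which the signed-rank null is enumerated exactly.
EXACT_ENUMERATION_LIMIT = 20

#: ΔSlogP spread within an aggregate beyond which a warning is raised.
_SLOGP_TOL = 1e-6


def sign_test_exact(n_increase: int, n_decrease: int, sided: str = "two") -> float:
    """Exact binomial(n, 1/2) sign-test p-value; ties removed beforehand.

    One-sided: probability of at most ``min(n_increase, n_decrease)``
    minority outcomes. Two-sided: twice that, capped at 1.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    n = n_increase + n_decrease
    if n < 1:
        log.warning("all-tie aggregate: sign test undefined, returning 1")
        return 1.0
    k = min(n_increase, n_decrease)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2.0**n
    return tail if sided == "one" else min(1.0, 2.0 * tail)


def _signed_rank_tail(doubled_ranks: Sequence[int], w_doubled: int) -> float:
    """P(W ≤ w) over all 2^n sign assignments, ranks scaled by 2.

    Counts rank subsets by dynamic programming over achievable sums —
    equivalent to full enumeration of the 2^n assignments. Doubling
    makes mid-ranks (halves under ties) integral.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] += counts[: total + 1 - r].copy()
    w = min(w_doubled, total)
    return float(counts[: int(w) + 1].sum() / 2.0 ** len(doubled_ranks))


def signed_rank_exact(
    deltas: Sequence[float],
    sided: str = "two",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> float:
    """Exact Wilcoxon signed-rank p-value for paired differences.

    Ranks the absolute differences (average ranks on ties), computes
    the smaller of the positive- and negative-rank sums, and evaluates
    its exact null tail by counting sign assignments. Zero differences
    must be removed before calling. Beyond ``exact_limit`` observations
    a normal approximation with tie correction is used instead.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    d = np.asarray(list(deltas), dtype=float)
    if d.size == 0:
        raise ValueError("no nonzero differences")
    if np.any(d == 0):
        raise ValueError("zero differences must be removed before ranking")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_min = min(w_plus, w_minus)

    if n > exact_limit:
        log.info("n=%d exceeds exact limit %d; using normal approximation", n, exact_limit)
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        # continuity-corrected lower tail of the smaller rank sum
        z = (w_min - mean + 0.5) / math.sqrt(var)
        tail = float(norm.cdf(z))
        return tail if sided == "one" else min(1.0, 2.0 * tail)

    doubled = np.rint(2 * ranks).astype(int)
    tail = _signed_rank_tail(doubled.tolist(), int(round(2 * w_min)))
    return tail if sided == "one" else min(1.0, 2.0 * tail)


def geometric_mean_fold(deltas: Sequence[float]) -> float:
    """Geometric mean fold change: 10^|mean Δlog10 IC50|, always ≥ 1."""
    d = list(deltas)
    if not d:
        raise ValueError("cannot average an empty set of deltas")
    return 10.0 ** abs(sum(d) / len(d))


@dataclass
class SignificanceConfig:
    """Reporting thresholds for aggregates.

    ``min_examples`` is the membership threshold (ties count toward
    membership but are dropped by the tests); ``alpha`` is optional —
    by default p-values are reported, not filtered on.
    """

    min_examples: int = 5
    alpha: float | None = None
    test: str = "sign"  # sign | signed_rank | both

    def __post_init__(self) -> None:
        if self.min_examples < 1:
            raise ValueError("min_examples must be >= 1")
        if self.test not in ("sign", "signed_rank", "both"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class Aggregate:
    """All pairs sharing one canonically oriented transformation key."""

    key: TransformationKey
    pairs: list[MolecularPair]
    n: int
    n_increase: int
    n_decrease: int
    n_tie: int
    mean_delta_log: float
    fold_change: float
    p_sign_two_sided: float
    p_signed_rank_two_sided: float
    delta_slogp: float


def _build_aggregate(key: TransformationKey, pairs: list[MolecularPair]) -> Aggregate:
    deltas = [p.delta_log_ic50 for p in pairs]
    n_inc = sum(1 for d in deltas if d > 0)
    n_dec = sum(1 for d in deltas if d < 0)
    n_tie = len(deltas) - n_inc - n_dec
    mean = sum(deltas) / len(deltas)
    nonzero = [d for d in deltas if d != 0]
    p_signed_rank = signed_rank_exact(nonzero) if nonzero else 1.0
    slogps = [p.delta_slogp for p in pairs]
    if max(slogps) - min(slogps) > _SLOGP_TOL:
        log.warning(
            "ΔSlogP varies within aggregate %s (range %.3g); atom typing differs "
            "across member pairs", key_string(key), max(slogps) - min(slogps),
        )
    return Aggregate(
        key=key,
        pairs=pairs,
        n=len(pairs),
        n_increase=n_inc,
        n_decrease=n_dec,
        n_tie=n_tie,
        mean_delta_log=mean,
        fold_change=geometric_mean_fold(deltas),
        p_sign_two_sided=sign_test_exact(n_inc, n_dec, "two"),
        p_signed_rank_two_sided=p_signed_rank,
        delta_slogp=sum(slogps) / len(slogps),
    )


def aggregate_pairs(pairs: Iterable[MolecularPair]) -> list[Aggregate]:
    """Group ordered pairs by key and report one aggregate per transformation.

    The ordered-pair list contains each unordered pair in both
    directions, so aggregates arise in mirror-image couples; only the
    canonical orientation (mean Δlog ≤ 0, the inhibition-reducing
    direction) is reported, and each unordered pair contributes to
    exactly one reported aggregate. Output is sorted by key string for
    determinism.
    """
    by_key: dict[TransformationKey, list[MolecularPair]] = defaultdict(list)
    for p in pairs:
        by_key[p.key].append(p)

    aggregates: list[Aggregate] = []
    seen: set[TransformationKey] = set()
    for key in sorted(by_key, key=key_string):
        if key in seen:
            continue
        members = by_key[key]
        mean = sum(p.delta_log_ic50 for p in members) / len(members)
        oriented_key, direction = canonical_orientation(key, mean)
        seen.add(key)
        seen.add(reverse_key(key))
        oriented = members if direction == +1 else [p.reversed() for p in members]
        aggregates.append(_build_aggregate(oriented_key, oriented))
    aggregates.sort(key=lambda a: key_string(a.key))
    return aggregates


def filter_significant(
    aggregates: Iterable[Aggregate], config: SignificanceConfig | None = None
) -> list[Aggregate]:
    """Aggregates passing the size (and optional alpha) thresholds.

    Sorted by fold change, largest reduction first.
    """
    config = config or SignificanceConfig()
    out = [a for a in aggregates if a.n >= config.min_examples]
    if config.alpha is not None:
        def passes(a: Aggregate) -> bool:
            ps = []
            if config.test in ("sign", "both"):
                ps.append(a.p_sign_two_sided)
            if config.test in ("signed_rank", "both"):
                ps.append(a.p_signed_rank_two_sided)
            return all(p <= config.alpha for p in ps)

        out = [a for a in out if passes(a)]
    out.sort(key=lambda a: (-a.fold_change, key_string(a.key)))
    return out


def size_histogram(aggregates: Iterable[Aggregate]) -> dict[int, int]:
    """Aggregate-size frequency table (for the power-law size plot)."""
    return dict(sorted(Counter(a.n for a in aggregates).items()))
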