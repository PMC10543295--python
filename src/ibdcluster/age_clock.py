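"""Recombination-clock estimate of founder-allele age.

Model: under a star genealogy, every carrier pair coalesces in the founder
T generations back, so the shared segment around the focal variant is
truncated by recombination on two independent lineage paths of T meioses
each.  Each one-sided extent is exponential with rate 2T per Morgan, hence
the full spanning length L (in Morgans) is Gamma(shape 2, rate 2T).  For n
pairs the MLE is

    T_hat = 2n / (2 * sum L_i) = 100 n / sum L_i[cM],

and since 2T * sum(L_i) ~ Gamma(2n, 1) is a pivot, an exact equal-tailed
95% interval is [q_0.025 / (2 S), q_0.975 / (2 S)] with q the Gamma(2n, 1)
quantiles and S the summed length in Morgans.

This is a deliberately simple clock: it ignores chromosome-end truncation
(valid while 100/T is much shorter than the map), uses no mutation-clock
term, and treats pairs as independent, which overlapping pairs in one
cluster are not — ``select_disjoint_pairs`` offers a conservative subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["AgeEstimate", "estimate_age", "select_disjoint_pairs"]


@dataclass(frozen=True)
class AgeEstimate:
    """Allele age in generations with a 95% confidence interval."""

    t_hat: float
    n_pairs: int
    ci_low: float
    ci_high: float


def estimate_age(
    lengths_cm: Iterable[float],
    conf: float = 0.95,
    map_length_cm: float | None = None,
) -> AgeEstimate:
    """Estimate the founder-allele age from pairwise spanning-segment lengths.

    Parameters
    ----------
    lengths_cm
        One spanning-segment length (cM) per carrier pair; all must be > 0.
    conf
        Confidence level for the interval (default 0.95).
    map_length_cm
        Optional chromosome map length; a warning is logged when any segment
        exceeds a quarter of it, where end-truncation starts to bias the
        clock downward in length (hence upward in age).
    """
    lengths = np.asarray(list(lengths_cm), dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one pair length")
    if not (lengths > 0).all():
        raise ValueError("all lengths must be positive")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if map_length_cm is not None and lengths.max() > 0.25 * map_length_cm:
        logger.warning(
            "longest segment (%.2f cM) exceeds 25%% of the %.1f cM map; "
            "end truncation may bias the estimate",
            lengths.max(), map_length_cm,
        )
    n = lengths.size
    s_morgans = lengths.sum() / 100.0
    t_hat = n / s_morgans
    alpha = 1.0 - conf
    q_low, q_high = stats.gamma.ppf([alpha / 2.0, 1.0 - alpha / 2.0], a=2 * n)
    return AgeEstimate(
        t_hat=float(t_hat),
        n_pairs=int(n),
        ci_low=float(q_low / (2.0 * s_morgans)),
        ci_high=float(q_high / (2.0 * s_morgans)),
    )


def select_disjoint_pairs(
    pairs: Sequence[tuple[str, str, float]],
) -> list[float]:
    """Greedy selection of sample-disjoint pairs, in input order.

    Input is (sample1, sample2, length_cm) triples; each individual is used
    at most once, so the returned lengths are closer to independent draws
    of the pairwise clock than the full overlapping set.
    """
    used: set[str] = set()
    lengths = []
    for s1, s2, length in pairs:
        if s1 == s2:
            raise ValueError(f"pair with identical samples: {s1!r}")
        if s1 in used or s2 in used:
            continue
        used.update((s1, s2))
        lengths.append(length)
    return lengths
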