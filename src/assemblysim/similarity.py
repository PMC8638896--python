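"""Renkonen similarity and stochasticity summaries over replicate ensembles.

Renkonen similarity between two relative-abundance vectors is
``1 - 0.5 * sum_i |x_i - y_i|``, the complement of Bray-Curtis dissimilarity
on proportions: 1 means identical composition, 0 complete turnover.  A
replicate group is summarised by all unordered pairwise similarities; a
"pattern" occurred in a group when at least one pair is at or above a
similarity threshold (default 0.9), i.e. a similar community appeared more
than once among replicates.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["renkonen_similarity", "pairwise_similarity", "pattern_occurrence",
           "SimilarityReport", "summarize_ensemble", "PATTERN_THRESHOLD"]

log = logging.getLogger(__name__)

PATTERN_THRESHOLD = 0.9
_NORM_TOL = 1e-6


def _check_composition(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D relative-abundance vector")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > _NORM_TOL:
        raise ValueError(
            f"{name} sums to {v.sum():.6g}, not 1: normalise to relative "
            "abundances before computing Renkonen similarity")
    return v


def renkonen_similarity(x, y) -> float:
    """Renkonen similarity ``1 - 0.5 * sum |x_i - y_i|`` of two compositions.

    Inputs must already be relative abundances (each summing to 1 within
    1e-6) over the same, aligned taxa; unnormalised input is an error rather
    than silently renormalised.
    """
    x = _check_composition(x, "x")
    y = _check_composition(y, "y")
    if x.shape != y.shape:
        raise ValueError("compositions must have equal length (taxa aligned)")
    return float(1.0 - 0.5 * np.abs(x - y).sum())


def pairwise_similarity(compositions) -> list[float]:
    """Renkonen similarity of all unordered pairs, lexicographic by index."""
    comps = [ _check_composition(c, f"composition {k}")
              for k, c in enumerate(compositions) ]
    if len(comps) < 2:
        raise ValueError("need at least 2 compositions to form pairs")
    return [renkonen_similarity(comps[i], comps[j])
            for i, j in itertools.combinations(range(len(comps)), 2)]


def pattern_occurrence(compositions,
                       threshold: float = PATTERN_THRESHOLD
                       ) -> tuple[bool, int]:
    """Whether a similar community appeared more than once among replicates.

    Returns ``(occurred, n_patterned_replicates)``: ``occurred`` is True iff
    some unordered pair reaches the threshold; the count is the number of
    replicates with at least one partner at or above it.
    """
    comps = list(compositions)
    n = len(comps)
    if n < 2:
        raise ValueError("need at least 2 compositions")
    sims = pairwise_similarity(comps)
    patterned = np.zeros(n, dtype=bool)
    for (i, j), s in zip(itertools.combinations(range(n), 2), sims):
        if s >= threshold:
            patterned[i] = patterned[j] = True
    return bool(patterned.any()), int(patterned.sum())


@dataclass
class SimilarityReport:
    """Pairwise Renkonen values per parameter set plus ensemble aggregates."""

    per_set_pairs: list[list[float]]
    pattern_flags: list[bool]
    patterned_replicate_counts: list[int]
    n_dropped_sets: int = 0
    threshold: float = PATTERN_THRESHOLD

    @property
    def pooled(self) -> np.ndarray:
        return np.array([s for pairs in self.per_set_pairs for s in pairs])

    @property
    def mean(self) -> float:
        return float(self.pooled.mean())

    @property
    def sd(self) -> float:
        return float(self.pooled.std(ddof=1)) if self.pooled.size > 1 else 0.0

    @property
    def pattern_probability(self) -> float:
        """Fraction of parameter sets whose replicate group shows a pattern."""
        return float(np.mean(self.pattern_flags))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (parameter set, replicate pair)."""
        rows = [(p, k, s)
                for p, pairs in enumerate(self.per_set_pairs)
                for k, s in enumerate(pairs)]
        return pd.DataFrame(rows, columns=["param_set", "pair", "similarity"])

    def summary(self) -> dict:
        return {
            "n_param_sets": len(self.per_set_pairs),
            "n_pairs": int(self.pooled.size),
            "mean_similarity": self.mean,
            "sd_similarity": self.sd,
            "pattern_threshold": self.threshold,
            "pattern_probability": self.pattern_probability,
            "patterned_replicate_counts": self.patterned_replicate_counts,
            "n_dropped_sets": self.n_dropped_sets,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def summarize_ensemble(composition_groups,
                       threshold: float = PATTERN_THRESHOLD
                       ) -> SimilarityReport:
    """Build a :class:`SimilarityReport` from grouped final compositions.

    Groups with fewer than two valid compositions (e.g. all replicates went
    extinct) are dropped with a logged count, never imputed.
    """
    per_set_pairs, flags, counts = [], [], []
    dropped = 0
    for group in composition_groups:
        comps = [c for c in group if c is not None]
        if len(comps) < 2:
            dropped += 1
            continue
        per_set_pairs.append(pairwise_similarity(comps))
        occurred, n_pat = pattern_occurrence(comps, threshold)
        flags.append(occurred)
        counts.append(n_pat)
    if dropped:
        log.warning("dropped %d parameter sets with < 2 valid compositions",
                    dropped)
    if not per_set_pairs:
        raise ValueError("no parameter set had >= 2 valid compositions")
    return SimilarityReport(per_set_pairs=per_set_pairs, pattern_flags=flags,
                            patterned_replicate_counts=counts,
                            n_dropped_sets=dropped, threshold=threshold)
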