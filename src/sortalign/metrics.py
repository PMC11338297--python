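"""Categoricality, pairwise alignment, dyad bridging, and data-quality filters.

Two statistics drive the analysis:

*Categoricality* of a single sort is ``log(mean between-category distance /
mean within-category distance)`` over all item pairs — positive when
same-category items sit closer together, and invariant to how much of the
canvas a participant used (uniform rescaling cancels in the ratio).

*Alignment* of two sorts is the Fisher-z-transformed Spearman rank
correlation between their pairwise item-distance vectors, computed over the
same canonically ordered pairs.  It is blind to category identity and
invariant under independent translation, rotation, reflection, and uniform
scaling of either sort.  Since alignment is dyadic while categoricality is
individual, dyad "bridging" converts the two members' categoricality scores
into one dyad-level covariate (minimum, maximum, or absolute difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from sortalign.simulate import CohortError, SortRecord

#: rho is clipped to +/-(1 - RHO_CLIP_EPS) before atanh so that identical
#: sorts get a large but finite, comparable z.
RHO_CLIP_EPS = 1e-6


class DataError(ValueError):
    """Malformed sort data (e.g. duplicate item ids)."""


class ComparabilityError(ValueError):
    """Two sorts cannot be compared (different item sets or pair order)."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class DistanceVector:
    """All pairwise Euclidean item distances of one sort, in canonical
    (lexicographic-by-id) pair order; 190 pairs for 20 items."""

    participant_id: str
    pair_ids: tuple[tuple[str, str], ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pair_ids) != len(self.distances):
            raise DataError("pair_ids and distances length mismatch")


@dataclass(frozen=True)
class CategoricalityScore:
    participant_id: str
    mean_between: float
    mean_within: float
    score: float  # log(mean_between / mean_within)


@dataclass(frozen=True)
class DyadSummary:
    """One within-condition dyad: alignment plus bridged categoricality."""

    id_i: str
    id_j: str
    rho: float
    z_alignment: float
    cat_min: float
    cat_max: float
    cat_absdiff: float


def canonical_pairs(item_ids: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Unordered pairs of the lexicographically sorted ids, in the order
    produced by combinations (matches scipy's condensed-distance order)."""
    return tuple(combinations(sorted(item_ids), 2))


def pairwise_distances(sort: SortRecord) -> DistanceVector:
    """Euclidean distance between every unordered item pair of one sort."""
    if len(sort.item_ids) < 2:
        raise DataError("need at least 2 items")
    if len(set(sort.item_ids)) != len(sort.item_ids):
        raise DataError(f"duplicate item ids in sort {sort.participant_id!r}")
    order = np.argsort(np.asarray(sort.item_ids, dtype=object))
    xy = sort.xy[order]
    return DistanceVector(
        participant_id=sort.participant_id,
        pair_ids=canonical_pairs(sort.item_ids),
        distances=pdist(xy),
    )


def categoricality(
    sort: SortRecord, category_of: Mapping[str, str]
) -> CategoricalityScore:
    """log(mean between-category / mean within-category pairwise distance).

    Requires at least 2 items per category; undefined when all same-category
    items coincide (zero mean within-distance).
    """
    dv = pairwise_distances(sort)
    cats = np.array([category_of[i] for i in sorted(sort.item_ids)], dtype=object)
    counts = pd.Series(cats).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise DataError("need at least 2 items in each of two categories")
    ii, jj = np.triu_indices(len(cats), k=1)
    between = cats[ii] != cats[jj]
    mean_between = float(dv.distances[between].mean())
    mean_within = float(dv.distances[~between].mean())
    if mean_within <= 0:
        raise UndefinedStatisticError("all same-category items coincide; score undefined")
    return CategoricalityScore(
        participant_id=sort.participant_id,
        mean_between=mean_between,
        mean_within=mean_within,
        score=float(np.log(mean_between / mean_within)),
    )


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """atanh with rho clipped to +/-(1 - 1e-6) so it stays finite."""
    clipped = np.clip(rho, -(1 - RHO_CLIP_EPS), 1 - RHO_CLIP_EPS)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(rho) or np.ndim(rho) == 0 else out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties (rank, then Pearson)."""
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx = np.linalg.norm(rx)
    ny = np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        raise UndefinedStatisticError("zero-variance distance vector; rho undefined")
    return float(rx @ ry / (nx * ny))


def alignment(d1: DistanceVector, d2: DistanceVector) -> tuple[float, float]:
    """(rho, z): Spearman rank correlation of two distance vectors and its
    Fisher-z transform.  Symmetric in its arguments."""
    if d1.pair_ids != d2.pair_ids:
        raise ComparabilityError("sorts cover different item sets or pair orders")
    rho = _spearman(d1.distances, d2.distances)
    return rho, fisher_z(rho)


def subset_alignment(
    d1: DistanceVector,
    d2: DistanceVector,
    subset: str,
    category_of: Mapping[str, str],
) -> tuple[float, float]:
    """Alignment restricted to same-category pairs (``"within_category"``)
    or cross-category pairs (``"between_category"``)."""
    if d1.pair_ids != d2.pair_ids:
        raise ComparabilityError("sorts cover different item sets or pair orders")
    same = np.array([category_of[a] == category_of[b] for a, b in d1.pair_ids])
    if subset == "within_category":
        mask = same
    elif subset == "between_category":
        mask = ~same
    else:
        raise ValueError(f"subset must be within_category or between_category, got {subset!r}")
    if mask.sum() < 3:
        raise UndefinedStatisticError("fewer than 3 pairs in subset; rho undefined")
    rho = _spearman(d1.distances[mask], d2.distances[mask])
    return rho, fisher_z(rho)


def dyad_bridge(cat_i: float, cat_j: float) -> tuple[float, float, float]:
    """Bridge two individual categoricality scores to the dyad level:
    (minimum, maximum, absolute difference)."""
    lo, hi = sorted((float(cat_i), float(cat_j)))
    return lo, hi, hi - lo


@dataclass(frozen=True)
class AlignmentResult:
    """All within-condition dyadic alignments of a cohort.

    ``z`` is the full symmetric Fisher-z matrix in cohort order (NaN on the
    diagonal and across conditions); ``mean_z`` is each participant's mean
    alignment to the others in their condition — the paper-style outcome
    variable.
    """

    participant_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    rho: np.ndarray
    z: np.ndarray
    mean_z: np.ndarray
    dyads: tuple[DyadSummary, ...]


def rank_normalize(distances: np.ndarray) -> np.ndarray:
    """Row-wise rank, center, and L2-normalize, so that Spearman rho
    between any two rows is a plain dot product."""
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    ranks = np.apply_along_axis(rankdata, 1, d)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise UndefinedStatisticError("zero-variance distance vector; rho undefined")
    return ranks / norms


def alignment_matrix(
    cohort: Sequence[SortRecord],
    category_of: Mapping[str, str] | None = None,
    by_condition: bool = True,
) -> AlignmentResult:
    """All within-condition pairwise alignments, per-participant means, and
    dyad summaries (bridged categoricality when ``category_of`` is given).

    Rank vectors are precomputed once per sorter so the dyadic rho matrix is
    a single matrix product per condition.
    """
    n = len(cohort)
    ids = tuple(r.participant_id for r in cohort)
    if len(set(ids)) != n:
        raise DataError("duplicate participant ids in cohort")
    conditions = tuple(r.condition for r in cohort)
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(conditions):
        groups.setdefault(c if by_condition else "all", []).append(i)
    for c, members in groups.items():
        if len(members) < 2:
            raise CohortError(f"condition {c!r} has a single participant; alignment undefined")

    dvs = [pairwise_distances(r) for r in cohort]
    ref_pairs = dvs[0].pair_ids
    for dv in dvs[1:]:
        if dv.pair_ids != ref_pairs:
            raise ComparabilityError("all sorts must cover the same item set")
    cats = (
        {r.participant_id: categoricality(r, category_of).score for r in cohort}
        if category_of is not None
        else None
    )

    rho = np.full((n, n), np.nan)
    for members in groups.values():
        idx = np.asarray(members)
        normed = rank_normalize(np.vstack([dvs[i].distances for i in idx]))
        block = normed @ normed.T
        rho[np.ix_(idx, idx)] = np.clip(block, -1.0, 1.0)
    np.fill_diagonal(rho, np.nan)
    z = np.where(np.isnan(rho), np.nan, fisher_z(np.nan_to_num(rho)))
    mean_z = np.nanmean(z, axis=1)

    dyads = []
    for members in groups.values():
        for a, b in combinations(members, 2):
            ci, cj = (
                (cats[ids[a]], cats[ids[b]]) if cats is not None else (np.nan, np.nan)
            )
            lo, hi, diff = dyad_bridge(ci, cj) if cats is not None else (np.nan, np.nan, np.nan)
            dyads.append(
                DyadSummary(
                    id_i=ids[a], id_j=ids[b], rho=float(rho[a, b]),
                    z_alignment=float(z[a, b]), cat_min=lo, cat_max=hi, cat_absdiff=diff,
                )
            )
    return AlignmentResult(
        participant_ids=ids, conditions=conditions, rho=rho, z=z,
        mean_z=mean_z, dyads=tuple(dyads),
    )


def rt_filter(rts: Sequence[float]) -> list[float]:
    """Keep reaction times that are >= 150 ms and not more than 2 SDs above
    the subject's mean (mean/SD computed before any exclusion)."""
    arr = np.asarray(list(rts), dtype=float)
    if arr.size == 0:
        return []
    upper = arr.mean() + 2 * arr.std(ddof=1) if arr.size > 1 else np.inf
    return [float(v) for v in arr if 150.0 <= v <= upper]


def participant_filter(
    records: Sequence[SortRecord],
    logs: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[SortRecord], dict[str, str]]:
    """Apply the participant exclusion rules where the relevant data exist.

    Rules: incomplete sort (``moved_all`` false) → ``sort-incomplete``;
    match-to-sample accuracy below 80% → ``low-accuracy``; fewer than 7/9
    correct catch trials → ``catch-fail``.  ``logs`` maps participant id to
    an optional dict with keys ``accuracy`` and/or ``catch_correct``.
    Returns (kept records, per-participant reason codes; ``"ok"`` if kept).
    """
    logs = logs or {}
    kept: list[SortRecord] = []
    reasons: dict[str, str] = {}
    for rec in records:
        log = logs.get(rec.participant_id, {})
        if not rec.moved_all:
            reasons[rec.participant_id] = "sort-incomplete"
        elif "accuracy" in log and log["accuracy"] < 0.80:
            reasons[rec.participant_id] = "low-accuracy"
        elif "catch_correct" in log and log["catch_correct"] < 7:
            reasons[rec.participant_id] = "catch-fail"
        else:
            reasons[rec.participant_id] = "ok"
            kept.append(rec)
    return kept, reasons
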