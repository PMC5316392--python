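"""Vascular-density matching across groups.

Transporter expression is confounded by local microvessel density (several
GLUT isoforms are endothelial), so expression comparisons are run on
density-matched specimen sets: specimens are dropped until every pair of
group median V/EVTI values differs by at most a tolerance (5% by default,
measured relative to the pair mean).

The achieved property — not the selection procedure — is the constraint, so
the algorithm is a deterministic, auditable convention built on two facts
about medians of subsets of a sorted list:

* an odd-sized selection has median ``x[i]`` whenever at least ``k``
  retained specimens sit on each side of ``i``;
* an even-sized selection has median ``(x[i] + x[j]) / 2`` for *any* pair
  ``i < j`` with at least one spare specimen below ``i`` and above ``j``
  (the specimens strictly between ``i`` and ``j`` are excluded).

Every subset median is of one of these forms, so enumerating "centered
blocks with one interior gap" reaches exactly the medians reachable by any
subset selection — the matcher is feasibility-complete.  All pairwise
medians are within relative tolerance ``t`` exactly when the largest and
smallest group medians have ratio at most ``r = (2 + t) / (2 - t)``; the
matcher therefore slides a window ``[m, r*m]`` over the achievable medians
and, among feasible windows, maximizes first the minimum retained fraction
per group (protecting the smallest group) and then the total retained
count.  Every exclusion is logged with its reason.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, MatchingError


@dataclass
class Exclusion:
    specimen_id: str
    group: str
    vevti: float
    reason: str


@dataclass
class MatchedCohort:
    """Result of density matching: who stays, who left, and how close the
    group medians ended up."""

    included: dict[str, list[str]]  # group -> specimen ids
    excluded: list[Exclusion]
    group_medians: dict[str, float]
    max_pairwise_relative_difference: float
    tolerance: float

    def included_ids(self) -> set[str]:
        return {sid for ids in self.included.values() for sid in ids}


def pairwise_median_difference(medians: Mapping[str, float], mode: str = "relative") -> float:
    """Largest pairwise difference between group medians (relative to the
    pair mean, or absolute)."""
    worst = 0.0
    for a, b in itertools.combinations(medians, 2):
        m1, m2 = medians[a], medians[b]
        if mode == "relative":
            denom = (m1 + m2) / 2.0
            d = abs(m1 - m2) / denom if denom > 0 else (0.0 if m1 == m2 else float("inf"))
        else:
            d = abs(m1 - m2)
        worst = max(worst, d)
    return worst


@dataclass
class _GroupSelections:
    """Achievable (median, max retained) selections for one group's sorted
    specimens.  ``i``/``j`` are the order-stat indices defining the median
    (``j == -1`` marks an odd selection centered on ``i``)."""

    ids: list[str]  # sorted by (vevti, id) ascending
    values: np.ndarray
    medians: np.ndarray
    retained: np.ndarray
    i: np.ndarray
    j: np.ndarray


def _enumerate_selections(ids_sorted: list[str], values: np.ndarray, min_keep: int) -> _GroupSelections:
    n = len(ids_sorted)
    med, ret, ii, jj = [], [], [], []
    # odd selections: median x[i], up to 2*min(i, n-1-i)+1 retained
    for i in range(n):
        r = 2 * min(i, n - 1 - i) + 1
        if r >= min_keep:
            med.append(values[i])
            ret.append(r)
            ii.append(i)
            jj.append(-1)
    # even selections: median (x[i]+x[j])/2, up to 2*(1+min(i, n-1-j)) retained
    for i in range(n - 1):
        for j in range(i + 1, n):
            r = 2 * (1 + min(i, n - 1 - j))
            if r >= min_keep:
                med.append((values[i] + values[j]) / 2.0)
                ret.append(r)
                ii.append(i)
                jj.append(j)
    return _GroupSelections(
        ids=ids_sorted,
        values=values,
        medians=np.array(med),
        retained=np.array(ret),
        i=np.array(ii),
        j=np.array(jj),
    )


def _kept_indices(sel: _GroupSelections, k: int) -> list[int]:
    """Retained specimen indices for selection ``k``: a centered block, with
    the interior between the median pair excluded for even selections."""
    i, j, r = int(sel.i[k]), int(sel.j[k]), int(sel.retained[k])
    if j < 0:
        half = (r - 1) // 2
        return list(range(i - half, i + half + 1))
    half = r // 2
    return list(range(i - half + 1, i + 1)) + list(range(j, j + half))


def match_by_density(
    specimens: Mapping[str, Mapping[str, float]],
    tolerance: float = 0.05,
    min_group_size: int = 4,
    mode: str = "relative",
) -> MatchedCohort:
    """Select per-group specimen subsets whose median V/EVTI values all agree
    within ``tolerance``.

    ``specimens`` maps group -> {specimen_id: vevti}.  Groups already smaller
    than ``min_group_size`` are retained whole if possible but never required
    to shrink below their size; other groups are never trimmed below the
    minimum.  The search is deterministic (ties in vevti order break on the
    specimen id) and feasibility-complete: if no subset combination can
    satisfy the constraint above the minimum sizes, a :class:`MatchingError`
    is raised carrying the best achievable pairwise difference — the matcher
    never silently returns an unmatched cohort.
    """
    if not specimens or any(len(v) == 0 for v in specimens.values()):
        raise ConfigurationError("every group must contain at least one specimen")
    if mode not in ("relative", "absolute"):
        raise ConfigurationError(f"unknown matching mode {mode!r}")
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")

    groups = sorted(specimens)
    sels: dict[str, _GroupSelections] = {}
    for g in groups:
        items = sorted(specimens[g].items(), key=lambda kv: (kv[1], kv[0]))
        ids_sorted = [k for k, _ in items]
        values = np.array([v for _, v in items], dtype=float)
        min_keep = min(min_group_size, len(ids_sorted))
        sels[g] = _enumerate_selections(ids_sorted, values, min_keep)

    if mode == "relative":
        ratio = (2.0 + tolerance) / (2.0 - tolerance)
        in_window = lambda med, m: ((med >= m) & (med <= m * ratio)) if m > 0 else (med == 0.0)
    else:
        in_window = lambda med, m: (med >= m) & (med <= m + tolerance)

    anchors = np.unique(np.concatenate([sels[g].medians for g in groups]))

    best_key = None
    best_choice = None
    for m in anchors:
        choice = {}
        feasible = True
        for g in groups:
            s = sels[g]
            mask = in_window(s.medians, m)
            if not mask.any():
                feasible = False
                break
            idx = np.flatnonzero(mask)
            # max retained; ties -> contiguous (smallest gap), lowest start
            gap = s.j[idx] - s.i[idx]
            order = np.lexsort((s.i[idx], gap, -s.retained[idx]))
            choice[g] = int(idx[order[0]])
        if not feasible:
            continue
        medians = {g: float(sels[g].medians[choice[g]]) for g in groups}
        retained = {g: int(sels[g].retained[choice[g]]) for g in groups}
        key = (
            min(retained[g] / len(sels[g].ids) for g in groups),
            sum(retained.values()),
            -pairwise_median_difference(medians, mode),
        )
        if best_key is None or key > best_key:
            best_key = key
            best_choice = (dict(choice), medians)

    if best_choice is None:
        best_diff = _best_achievable_difference(sels, groups, mode)
        raise MatchingError(
            f"density matching unsatisfiable above min group size {min_group_size}; "
            f"best achievable pairwise difference {best_diff:.4f}",
            best_difference=best_diff,
        )

    choice, medians = best_choice
    included: dict[str, list[str]] = {}
    excluded: list[Exclusion] = []
    for g in groups:
        s = sels[g]
        kept = set(_kept_indices(s, choice[g]))
        included[g] = sorted(s.ids[k] for k in kept)
        lo_edge, hi_edge = min(kept), max(kept)
        for k, sid in enumerate(s.ids):
            if k in kept:
                continue
            if k < lo_edge:
                reason = "low-extreme V/EVTI outside the matched window"
            elif k > hi_edge:
                reason = "high-extreme V/EVTI outside the matched window"
            else:
                reason = "interior V/EVTI excluded to center the group median"
            excluded.append(Exclusion(sid, g, specimens[g][sid], reason))
    return MatchedCohort(
        included=included,
        excluded=excluded,
        group_medians=medians,
        max_pairwise_relative_difference=pairwise_median_difference(medians, mode),
        tolerance=tolerance,
    )


def _best_achievable_difference(sels: Mapping[str, _GroupSelections], groups, mode: str) -> float:
    """Smallest worst-pair difference achievable (for the error report)."""
    best = float("inf")
    anchors = np.unique(np.concatenate([sels[g].medians for g in groups]))
    for m in anchors:
        medians = {}
        for g in groups:
            meds = sels[g].medians
            medians[g] = float(meds[np.argmin(np.abs(meds - m))])
        best = min(best, pairwise_median_difference(medians, mode))
    return best
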