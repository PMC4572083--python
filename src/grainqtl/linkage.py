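"""Linkage-map construction for selfed RIL populations.

Pipeline: estimate pairwise observed recombinant fractions R between
markers, group markers into chromosomes (by anchor assignments, or de novo
by a linkage threshold), order each group to minimize the sum of adjacent
recombination fractions (SARF) with a nearest-neighbor start improved by
2-opt segment reversals, fine-tune with a rippling pass (exhaustive
re-permutation inside a sliding window), and convert adjacent fractions to
cM via the RIL correction and a map function.

For selfed RILs the observed fraction of recombinant lines between two
loci relates to the per-meiosis recombination fraction r by

    R = 2r / (1 + 2r)        (inverse: r = R / (2 (1 - R)))

because recombinants keep accumulating over the selfing generations.
Distances use Haldane (d = -50 ln(1 - 2r), no interference — matching the
simulator) or Kosambi (d = 25 ln((1+2r)/(1-2r))) map functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix

__all__ = [
    "RecFracMatrix",
    "pairwise_recfrac",
    "ril_correction",
    "map_distance",
    "inverse_map_distance",
    "group_markers",
    "sarf",
    "order_nn_two_opt",
    "ripple",
    "build_map",
    "construct_map",
]


@dataclass
class RecFracMatrix:
    """Symmetric marker x marker observed RIL recombinant fractions."""

    markers: list[str]
    R: np.ndarray = field(repr=False)  # NaN where unknown
    counts: np.ndarray = field(repr=False)  # informative line counts

    def index_of(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker not in matrix: {marker}") from None

    def submatrix(self, markers: list[str]) -> np.ndarray:
        idx = [self.index_of(m) for m in markers]
        return self.R[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.markers, columns=self.markers)


def pairwise_recfrac(
    genotypes: GenotypeMatrix, min_informative: int = 30
) -> RecFracMatrix:
    """Observed recombinant fraction for every marker pair.

    R = (# lines with different parental alleles) / (# lines with both
    calls present).  Pairs with fewer than ``min_informative`` informative
    lines, and all pairs of a monomorphic marker, are NaN.
    """
    c = genotypes.codes.astype(np.int32)
    present = (c != 0).astype(np.int32)
    informative = present.T @ present  # both non-missing
    dot = c.T @ c  # concordant - discordant
    discordant = (informative - dot) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(informative > 0, discordant / informative, np.nan)
    R[informative < min_informative] = np.nan
    mono = np.array(
        [len(np.unique(col[col != 0])) < 2 for col in genotypes.codes.T]
    )
    R[mono, :] = np.nan
    R[:, mono] = np.nan
    np.fill_diagonal(R, 0.0)
    return RecFracMatrix(list(genotypes.markers), R, informative)


def ril_correction(R, return_flags: bool = False):
    """Per-meiosis r from the observed RIL fraction R: r = R / (2 (1 - R)).

    Results are clamped to [0, 0.5]; entries with R > 0.5 (clamped) or
    R = 1 (undefined) are flagged when ``return_flags`` is set.
    """
    R = np.asarray(R, dtype=float)
    flags = R > 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(R < 1.0, R / (2.0 * (1.0 - R)), np.inf)
    r = np.clip(r, 0.0, 0.5)
    r = r if r.ndim else float(r)
    if return_flags:
        return r, (flags if np.ndim(flags) else bool(flags))
    return r


def map_distance(r, function: str = "haldane"):
    """Map distance in cM from a per-meiosis recombination fraction.

    r >= 0.5 maps to +inf (unlinked).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        if function == "haldane":
            d = np.where(r < 0.5, -50.0 * np.log(1.0 - 2.0 * r), np.inf)
        elif function == "kosambi":
            d = np.where(r < 0.5, 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r)),
                         np.inf)
        else:
            raise ValueError("map function must be 'haldane' or 'kosambi'")
    return d if d.ndim else float(d)


def inverse_map_distance(d, function: str = "haldane"):
    """Recombination fraction from a cM distance (exact inverse)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    elif function == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    else:
        raise ValueError("map function must be 'haldane' or 'kosambi'")
    return r if r.ndim else float(r)


def group_markers(
    recfrac: RecFracMatrix,
    anchors: dict[str, str] | None = None,
    threshold: float = 0.35,
) -> tuple[dict[str, list[str]], list[str]]:
    """Partition markers into linkage groups.

    Anchored markers go to their anchor chromosome.  Unanchored markers
    join the group with the smallest mean R to its members, provided that
    mean is below ``threshold``; otherwise they are reported unplaced.
    With no anchors at all, groups are formed de novo by single-linkage
    joining of pairs with R < threshold (groups named G1, G2, ... by first
    marker appearance).

    Returns (groups, unplaced).
    """
    markers = recfrac.markers
    anchors = anchors or {}
    groups: dict[str, list[str]] = {}
    unanchored = [m for m in markers if m not in anchors]

    if not anchors:
        parent = list(range(len(markers)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(markers)):
            for j in range(i + 1, len(markers)):
                rij = recfrac.R[i, j]
                if np.isfinite(rij) and rij < threshold:
                    parent[find(j)] = find(i)
        roots: dict[int, str] = {}
        for i, m in enumerate(markers):
            root = find(i)
            if root not in roots:
                roots[root] = f"G{len(roots) + 1}"
            groups.setdefault(roots[root], []).append(m)
        return groups, []

    for m in markers:
        if m in anchors:
            groups.setdefault(str(anchors[m]), []).append(m)
    unplaced: list[str] = []
    for m in unanchored:
        i = recfrac.index_of(m)
        best_group, best_mean = None, np.inf
        for g, members in groups.items():
            vals = [
                recfrac.R[i, recfrac.index_of(x)]
                for x in members
                if np.isfinite(recfrac.R[i, recfrac.index_of(x)])
            ]
            if vals:
                mean = float(np.mean(vals))
                if mean < best_mean:
                    best_group, best_mean = g, mean
        if best_group is not None and best_mean < threshold:
            groups[best_group].append(m)
        else:
            unplaced.append(m)
    return groups, unplaced


def sarf(order: list[int] | np.ndarray, R: np.ndarray) -> float:
    """Sum of adjacent recombination fractions for an order (indices)."""
    order = np.asarray(order)
    return float(R[order[:-1], order[1:]].sum())


def _orient(order: list[int], markers: list[str]) -> list[int]:
    # report orders up to reversal: first marker id precedes the last
    if markers[order[0]] > markers[order[-1]]:
        return order[::-1]
    return order


def order_nn_two_opt(R: np.ndarray, markers: list[str]) -> list[str]:
    """Order markers by SARF: best nearest-neighbor tour, then 2-opt.

    Nearest-neighbor paths are grown from every start marker (ties toward
    the lexicographically smaller marker id); the best-SARF path is then
    improved by 2-opt segment reversals until no reversal reduces SARF.
    The returned orientation puts the smaller first/last marker id first.
    Raises ValueError on unknown (NaN) pairwise entries.
    """
    n = len(markers)
    if n < 2:
        return list(markers)
    if R.shape != (n, n):
        raise ValueError("recombination submatrix shape mismatch")
    off_diag = ~np.eye(n, dtype=bool)
    if np.isnan(R[off_diag]).any():
        raise ValueError("unknown pairwise recombination fractions in group")

    name_rank = np.argsort(np.argsort(markers))  # lexicographic rank per index

    def nn_path(start: int) -> list[int]:
        path = [start]
        remaining = set(range(n)) - {start}
        while remaining:
            last = path[-1]
            cand = sorted(remaining, key=lambda j: (R[last, j], name_rank[j]))
            path.append(cand[0])
            remaining.discard(cand[0])
        return path

    best_order, best_cost = None, np.inf
    for start in sorted(range(n), key=lambda i: name_rank[i]):
        path = nn_path(start)
        cost = sarf(path, R)
        if cost < best_cost - 1e-15:
            best_order, best_cost = path, cost
    order = list(best_order)

    improved = True
    while improved:
        improved = False
        best_delta, best_move = 1e-12, None  # strict improvement only
        cur = sarf(order, R)
        for i in range(n - 1):
            for j in range(i + 1, n):
                new = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                delta = cur - sarf(new, R)
                if delta > best_delta:
                    best_delta, best_move = delta, new
        if best_move is not None:
            order = best_move
            improved = True
    return [markers[i] for i in _orient(order, markers)]


def ripple(order: list[str], R: np.ndarray, markers: list[str],
           window: int = 8) -> list[str]:
    """Fine-tune a marker order by exhaustive window re-permutation.

    Slides a window of ``window`` markers one position at a time over the
    order; within each window every permutation (flanks fixed) is scored
    by the SARF of the whole order and the best kept.  Passes repeat until
    a full pass makes no improvement.  SARF never increases.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(order)
    if n < 2:
        return list(order)
    w = min(window, n)
    idx_of = {m: i for i, m in enumerate(markers)}
    cur = [idx_of[m] for m in order]
    perms = np.array(list(itertools.permutations(range(w))))

    improved = True
    while improved:
        improved = False
        for s in range(n - w + 1):
            win = np.array(cur[s:s + w])
            sub = R[np.ix_(win, win)]
            internal = sub[perms[:, :-1], perms[:, 1:]].sum(axis=1)
            cost = internal
            if s > 0:
                cost = cost + R[cur[s - 1], win[perms[:, 0]]]
            if s + w < n:
                cost = cost + R[win[perms[:, -1]], cur[s + w]]
            best = int(np.argmin(cost))
            # identity permutation is row 0; replace only on strict gain
            if cost[best] < cost[0] - 1e-12:
                cur[s:s + w] = [int(win[k]) for k in perms[best]]
                improved = True
    return [markers[i] for i in _orient(cur, markers)]


def build_map(
    groups: dict[str, list[str]],
    recfrac: RecFracMatrix,
    map_function: str = "haldane",
    cap_cm: float = 50.0,
) -> tuple[GeneticMap, dict]:
    """Convert ordered groups to cM positions and summarise interval lengths.

    Adjacent observed fractions pass through the RIL correction and the
    chosen map function; adjacent R > 0.5 yields an infinite distance that
    is capped at ``cap_cm`` and counted in the summary.
    """
    rows = []
    intervals: list[float] = []
    capped = 0
    for chrom, order in groups.items():
        pos = 0.0
        for k, m in enumerate(order):
            if k > 0:
                i = recfrac.index_of(order[k - 1])
                j = recfrac.index_of(m)
                Rij = recfrac.R[i, j]
                if not np.isfinite(Rij):
                    raise ValueError(
                        f"unknown adjacent recombination fraction "
                        f"{order[k - 1]}-{m} in group {chrom}"
                    )
                r = ril_correction(Rij)
                d = map_distance(r, map_function)
                if not np.isfinite(d) or d > cap_cm:
                    d = cap_cm
                    capped += 1
                intervals.append(d)
                pos += d
            rows.append((m, chrom, pos))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]))
    iv = np.asarray(intervals)
    n_markers = sum(len(v) for v in groups.values())
    summary = {
        "total_length_cm": float(iv.sum()) if len(iv) else 0.0,
        "n_markers": n_markers,
        "n_groups": len(groups),
        "n_intervals": len(iv),
        "mean_interval_cm": float(iv.mean()) if len(iv) else 0.0,
        # convention dividing by marker count rather than interval count
        "mean_per_marker_cm": float(iv.sum() / n_markers) if n_markers else 0.0,
        "min_interval_cm": float(iv.min()) if len(iv) else 0.0,
        "max_interval_cm": float(iv.max()) if len(iv) else 0.0,
        "n_under_10cm": int((iv < 10.0).sum()),
        "n_over_25cm": int((iv > 25.0).sum()),
        "n_capped": capped,
    }
    return gmap, summary


def _chrom_key(name: str):
    try:
        return (0, int(name))
    except (TypeError, ValueError):
        return (1, str(name))


def construct_map(
    genotypes: GenotypeMatrix,
    anchors: dict[str, str] | None = None,
    min_informative: int = 30,
    window: int = 8,
    map_function: str = "haldane",
    threshold: float = 0.35,
) -> tuple[GeneticMap, dict]:
    """Full map pipeline: recfrac -> group -> order -> ripple -> cM map."""
    rec = pairwise_recfrac(genotypes, min_informative=min_informative)
    groups, unplaced = group_markers(rec, anchors, threshold=threshold)
    ordered: dict[str, list[str]] = {}
    for chrom in sorted(groups, key=_chrom_key):
        members = groups[chrom]
        if len(members) < 2:
            ordered[chrom] = list(members)
            continue
        sub = rec.submatrix(members)
        order = order_nn_two_opt(sub, members)
        ordered[chrom] = ripple(order, sub, members, window=window)
    gmap, summary = build_map(ordered, rec, map_function=map_function)
    summary["unplaced"] = unplaced
    return gmap, summary
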