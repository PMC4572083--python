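"""Inclusive composite interval mapping (ICIM) for additive QTL in RILs.

ICIM scans a genome for additive QTL in two phases:

1. **Cofactor selection** — stepwise regression of the line-mean phenotype
   on all marker covariates (forward inclusion at ``p_entry``, backward
   elimination at ``p_removal``) picks a sparse marker model capturing the
   genetic background.
2. **Interval scan** — at every grid position (default 1 cM step) the
   phenotype is first adjusted by the selected cofactors *excluding the
   two markers flanking the scanned interval*, then a two-component
   normal mixture is fitted by EM, mixing over the putative homozygous
   QTL classes with per-line prior probabilities computed from the
   flanking marker calls.  The evidence is

       LOD = log10 [ L(two components) / L(single normal) ].

The additive effect is a = (mu_B - mu_A) / 2, so a > 0 means the
B-parent allele increases the trait; PVE% = 100 a^2 / s2_y with s2_y the
variance of the unadjusted line means (with +/-1 genotype coding, a^2 is
the additive variance contributed by the locus).

A genome-wide LOD threshold comes from permutation: line labels of the
phenotype are shuffled, the full scan (including cofactor reselection)
is re-run, and the (1 - alpha) quantile of the per-permutation maximum
LOD is taken; maxima can be pooled across traits.

Peaks are called per *marker interval*: an interval hosts a QTL if at
least one environment shows a supra-threshold local LOD maximum inside
it, and the record then carries every environment's own within-interval
peak (including sub-threshold ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneticMap, GenotypeMatrix
from .linkage import inverse_map_distance

__all__ = [
    "CofactorModel",
    "ScanGrid",
    "encode_genotypes",
    "stepwise_select",
    "adjust_phenotype",
    "qtl_genotype_probs",
    "precompute_scan_grid",
    "em_scan",
    "icim_scan",
    "permutation_threshold",
    "call_qtl",
    "consolidate_qtl",
]

_LN10 = np.log(10.0)


def encode_genotypes(genotypes: GenotypeMatrix) -> np.ndarray:
    """Numeric design values for the regression phase.

    A -> +1, B -> -1, missing -> 0 (the mean under the 1:1 expectation).
    """
    return genotypes.codes.astype(float)


@dataclass
class CofactorModel:
    """Stepwise-selected marker cofactors and their fitted coefficients."""

    markers: list[str]
    coefficients: dict[str, float]
    intercept: float
    p_entry: float
    p_removal: float


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefs incl. intercept, SSE)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def stepwise_select(
    y: np.ndarray,
    X: np.ndarray,
    markers: list[str],
    p_entry: float = 0.001,
    p_removal: float = 0.002,
) -> CofactorModel:
    """Forward-selection / backward-elimination marker regression.

    At each step the candidate with the smallest partial-F p-value enters
    if p <= p_entry; any retained marker whose drop-one p-value exceeds
    p_removal is then removed.  Iterates to convergence.  Ties (identical
    p, e.g. duplicated columns) resolve to the leftmost column, so a
    collinear duplicate is never co-selected (its residualized column
    vanishes).  Columns must be in map order for the leftmost-position
    tie-break to apply.
    """
    if p_entry > p_removal:
        raise ValueError("p_entry must be <= p_removal")
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(markers) != p:
        raise ValueError("marker names inconsistent with design matrix")

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    col_norms = np.einsum("ij,ij->j", Xc, Xc)
    Xres = Xc.copy()
    yres = yc.copy()
    selected: list[int] = []

    def forward() -> bool:
        nonlocal Xres, yres
        q = len(selected)
        df = n - q - 2
        if df < 1:
            return False
        norms = np.einsum("ij,ij->j", Xres, Xres)
        valid = norms > 1e-10 * np.maximum(col_norms, 1e-30)
        valid[selected] = False
        if not valid.any():
            return False
        sse = float(yres @ yres)
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(valid, (Xres.T @ yres) ** 2 / np.where(valid, norms, 1.0), -np.inf)
        rem = np.maximum(sse - gain, 0.0)
        # a perfect fit (rem ~ 0 with positive gain) must yield p -> 0
        tiny = 1e-12 * max(sse, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(
                rem > tiny, gain / (rem / df), np.where(gain > tiny, np.inf, 0.0)
            )
        pvals = np.where(valid, stats.f.sf(np.where(np.isfinite(F), F, 1e300), 1, df),
                         np.inf)
        best = int(np.argmin(pvals))  # ties -> leftmost map position
        if pvals[best] > p_entry:
            return False
        qvec = Xres[:, best] / np.sqrt(norms[best])
        selected.append(best)
        Xres -= np.outer(qvec, qvec @ Xres)
        yres -= qvec * (qvec @ yres)
        return True

    def backward() -> bool:
        if not selected:
            return False
        Xs = Xc[:, selected]
        beta, sse = _ols(yc, Xs)
        df = n - len(selected) - 1
        if df < 1:
            return False
        G = np.column_stack([np.ones(n), Xs])
        cov = np.linalg.pinv(G.T @ G) * (sse / df)
        se = np.sqrt(np.maximum(np.diag(cov)[1:], 1e-300))
        tvals = beta[1:] / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_removal:
            return False
        selected.pop(worst)
        return True

    changed = True
    while changed:
        changed = forward()
        while backward():
            changed = True
            # residualized candidates must be rebuilt after a removal
        if changed and selected:
            Xres = Xc.copy()
            yres = yc.copy()
            rebuilt: list[int] = []
            for k in selected:
                norm = float(Xres[:, k] @ Xres[:, k])
                if norm <= 0:
                    continue
                qvec = Xres[:, k] / np.sqrt(norm)
                Xres -= np.outer(qvec, qvec @ Xres)
                yres -= qvec * (qvec @ yres)
                rebuilt.append(k)
            selected = rebuilt

    if selected:
        beta, _ = _ols(y, X[:, selected])
        intercept = float(beta[0])
        coefs = {markers[k]: float(b) for k, b in zip(selected, beta[1:])}
    else:
        intercept = float(y.mean())
        coefs = {}
    return CofactorModel(
        markers=[markers[k] for k in selected],
        coefficients=coefs,
        intercept=intercept,
        p_entry=p_entry,
        p_removal=p_removal,
    )


def adjust_phenotype(
    y: np.ndarray,
    model: CofactorModel,
    X: np.ndarray,
    markers: list[str],
    exclude: tuple[str, ...] = (),
) -> np.ndarray:
    """Background-adjusted phenotype for one scanned interval.

    Subtracts every selected cofactor's contribution except the markers in
    ``exclude`` (the scanned interval's flanks).  The intercept is left in
    place — the mixture fit estimates class means freely.
    """
    y = np.asarray(y, dtype=float)
    dy = y.copy()
    index = {m: k for k, m in enumerate(markers)}
    for m in model.markers:
        if m in exclude:
            continue
        dy -= model.coefficients[m] * X[:, index[m]]
    return dy


def _transition_prob_A(calls: np.ndarray, R: float) -> np.ndarray:
    """P(flanking call -> QTL class A) across lines; missing -> 0.5."""
    return np.where(calls == 1, 1.0 - R, np.where(calls == -1, R, 0.5))


def _flank_probs(
    left: np.ndarray, right: np.ndarray, R_left: float, R_right: float
) -> tuple[np.ndarray, np.ndarray]:
    wa = _transition_prob_A(left, R_left) * _transition_prob_A(right, R_right)
    wb = (1.0 - _transition_prob_A(left, R_left)) * (
        1.0 - _transition_prob_A(right, R_right)
    )
    total = wa + wb
    return wa / total, wb / total


def qtl_genotype_probs(
    left_call: int,
    right_call: int,
    r_left: float,
    r_right: float,
    r_interval: float,
) -> tuple[float, float]:
    """(P(QQ), P(qq)) for a putative QTL between two flanking markers.

    All three fractions are on the RIL (observed recombinant fraction)
    scale.  Probabilities use the two-state Markov conditioning
    P(Q|M_L, M_R) proportional to P(Q|M_L) P(M_R|Q) — the
    no-double-crossover normalization — so the interval fraction enters
    only through the consistency requirement
    r_interval ~ r_left + r_right - 2 r_left r_right (checked to 0.02,
    the Markov chain approximation slack).  A missing flank (call 0)
    conditions on the other flank alone; two missing flanks give (0.5,
    0.5).  QQ is the A-parent class.
    """
    for r in (r_left, r_right, r_interval):
        if not (0.0 <= r < 1.0):
            raise ValueError("recombinant fractions must be in [0, 1)")
    composed = r_left + r_right - 2.0 * r_left * r_right
    if abs(composed - r_interval) > 0.02:
        raise ValueError(
            f"inconsistent fractions: left {r_left} + right {r_right} "
            f"compose to {composed:.4f}, interval says {r_interval}"
        )
    pa, pb = _flank_probs(
        np.asarray([left_call]), np.asarray([right_call]), r_left, r_right
    )
    return float(pa[0]), float(pb[0])


# ---------------------------------------------------------------------------
# scan grid


@dataclass
class ScanGrid:
    """Precomputed scan positions and per-line QTL class probabilities.

    Probability arrays depend only on genotypes and map, so one grid
    serves every trait, environment and permutation of a study.
    """

    table: pd.DataFrame  # chromosome, cm, interval, left_marker, right_marker
    prob_a: np.ndarray = field(repr=False)  # (positions, lines)
    prob_b: np.ndarray = field(repr=False)
    interval_flanks: list[tuple[str, ...]] = field(default_factory=list)
    step: float = 1.0

    @property
    def n_positions(self) -> int:
        return len(self.table)


def _ril_scale(d_cm: float, map_function: str) -> float:
    r = inverse_map_distance(d_cm, map_function)
    return 2.0 * r / (1.0 + 2.0 * r)


def precompute_scan_grid(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    step: float = 1.0,
    map_function: str = "haldane",
) -> ScanGrid:
    """Build the genome scan grid at ``step`` cM and its class probabilities."""
    if step <= 0:
        raise ValueError("step must be > 0")
    rows = []
    pa_rows: list[np.ndarray] = []
    pb_rows: list[np.ndarray] = []
    flanks: list[tuple[str, ...]] = []
    interval_id = 0
    for chrom in gmap.chromosomes:
        names = gmap.chrom_markers(chrom)
        pos = gmap.positions(chrom)
        if len(names) == 1:
            calls = genotypes.column(names[0])
            wa = _transition_prob_A(calls, 0.0)
            rows.append((chrom, float(pos[0]), interval_id, names[0], names[0]))
            pa_rows.append(wa)
            pb_rows.append(1.0 - wa)
            flanks.append((names[0],))
            interval_id += 1
            continue
        grid = np.arange(pos[0], pos[-1] + step / 2.0, step)
        if grid[-1] < pos[-1] - 1e-9:
            grid = np.append(grid, pos[-1])
        grid = np.minimum(grid, pos[-1])
        for k in range(len(names) - 1):
            left, right = names[k], names[k + 1]
            lcalls = genotypes.column(left)
            rcalls = genotypes.column(right)
            lo, hi = pos[k], pos[k + 1]
            in_iv = (grid >= lo - 1e-9) & (
                (grid < hi - 1e-9) if k < len(names) - 2 else (grid <= hi + 1e-9)
            )
            for g in grid[in_iv]:
                R1 = _ril_scale(float(g - lo), map_function)
                R2 = _ril_scale(float(hi - g), map_function)
                pa, pb = _flank_probs(lcalls, rcalls, R1, R2)
                rows.append((chrom, float(g), interval_id, left, right))
                pa_rows.append(pa)
                pb_rows.append(pb)
            flanks.append((left, right))
            interval_id += 1
    table = pd.DataFrame(
        rows, columns=["chromosome", "cm", "interval", "left_marker", "right_marker"]
    )
    return ScanGrid(
        table=table,
        prob_a=np.vstack(pa_rows),
        prob_b=np.vstack(pb_rows),
        interval_flanks=flanks,
        step=step,
    )


# ---------------------------------------------------------------------------
# EM mixture scan


def em_scan(
    dy: np.ndarray,
    prob_a: np.ndarray,
    prob_b: np.ndarray,
    s2y: float,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-component normal-mixture EM at every scan position (vectorized).

    ``dy``, ``prob_a``, ``prob_b`` are (positions, lines) arrays: the
    background-adjusted phenotype and the per-line prior probabilities of
    the two homozygous QTL classes (A first).  Returns per-position
    ``lod``, ``add`` (= (mu_B - mu_A)/2) and ``pve`` (= 100 add^2/s2y).
    """
    dy = np.atleast_2d(np.asarray(dy, dtype=float))
    pa = np.atleast_2d(np.asarray(prob_a, dtype=float))
    pb = np.atleast_2d(np.asarray(prob_b, dtype=float))
    P, n = dy.shape
    if n < 10:
        raise ValueError("need at least 10 lines with data")

    mean0 = dy.mean(axis=1, keepdims=True)
    var0 = dy.var(axis=1, keepdims=True)
    degenerate = var0[:, 0] <= 0
    var0 = np.where(var0 > 0, var0, 1.0)
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * var0[:, 0]) + 1.0)
    var_floor = 1e-12 * var0[:, 0]

    sa = pa.sum(axis=1, keepdims=True)
    sb = pb.sum(axis=1, keepdims=True)
    mu1 = np.where(sa > 0, (pa * dy).sum(axis=1, keepdims=True) / np.maximum(sa, 1e-12), mean0)
    mu2 = np.where(sb > 0, (pb * dy).sum(axis=1, keepdims=True) / np.maximum(sb, 1e-12), mean0)
    sig2 = np.maximum(
        ((pa * (dy - mu1) ** 2 + pb * (dy - mu2) ** 2).sum(axis=1) / n),
        var_floor,
    )[:, None]

    ll = np.full(P, -np.inf)
    active = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pa = np.log(pa)
        log_pb = np.log(pb)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        y_a = dy[idx]
        la = log_pa[idx] - (y_a - mu1[idx]) ** 2 / (2.0 * sig2[idx])
        lb = log_pb[idx] - (y_a - mu2[idx]) ** 2 / (2.0 * sig2[idx])
        m = np.maximum(la, lb)
        ea = np.exp(la - m)
        eb = np.exp(lb - m)
        denom = ea + eb
        ll_new = (m + np.log(denom)).sum(axis=1) - 0.5 * n * np.log(
            2.0 * np.pi * sig2[idx, 0]
        )
        w = ea / denom
        sw = w.sum(axis=1, keepdims=True)
        svw = ((1.0 - w)).sum(axis=1, keepdims=True)
        mu1[idx] = np.where(sw > 1e-12, (w * y_a).sum(axis=1, keepdims=True) / np.maximum(sw, 1e-12), mu1[idx])
        mu2[idx] = np.where(svw > 1e-12, ((1.0 - w) * y_a).sum(axis=1, keepdims=True) / np.maximum(svw, 1e-12), mu2[idx])
        sig2[idx] = np.maximum(
            ((w * (y_a - mu1[idx]) ** 2 + (1.0 - w) * (y_a - mu2[idx]) ** 2).sum(axis=1) / n),
            var_floor[idx],
        )[:, None]
        converged = np.abs(ll_new - ll[idx]) < tol * (np.abs(ll_new) + 1.0)
        ll[idx] = ll_new
        active[idx[converged]] = False

    lod = np.where(degenerate, 0.0, np.maximum((ll - ll0) / _LN10, 0.0))
    add = np.where(degenerate, 0.0, (mu2[:, 0] - mu1[:, 0]) / 2.0)
    pve = 100.0 * add**2 / s2y if s2y > 0 else np.zeros(P)
    return pd.DataFrame({"lod": lod, "add": add, "pve": pve})


def icim_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    step: float = 1.0,
    p_entry: float = 0.001,
    p_removal: float = 0.002,
    map_function: str = "haldane",
    grid: ScanGrid | None = None,
    model: CofactorModel | None = None,
) -> pd.DataFrame:
    """Full single-trait, single-environment ICIM scan.

    ``y`` holds one line-mean phenotype per line, ordered as
    ``genotypes.lines``.  Returns the scan profile: chromosome, cm,
    flanking markers, lod, add, pve.  A precomputed ``grid`` (and
    optionally a fixed cofactor ``model``) can be supplied to amortize
    work across traits, environments and permutations.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != genotypes.n_lines:
        raise ValueError("phenotype length does not match genotype lines")
    sub = genotypes.subset_markers([m for m in gmap.markers])
    X = encode_genotypes(sub)
    if model is None:
        model = stepwise_select(y, X, sub.markers, p_entry, p_removal)
    if grid is None:
        grid = precompute_scan_grid(sub, gmap, step=step, map_function=map_function)

    s2y = float(np.var(y, ddof=1))
    P = grid.n_positions
    dy = np.empty((P, len(y)))
    interval_ids = grid.table["interval"].to_numpy()
    for iv, flank in enumerate(grid.interval_flanks):
        rows = interval_ids == iv
        if not rows.any():
            continue
        dy[rows] = adjust_phenotype(y, model, X, sub.markers, exclude=flank)
    result = em_scan(dy, grid.prob_a, grid.prob_b, s2y)
    profile = pd.concat([grid.table.reset_index(drop=True), result], axis=1)
    return profile


def permutation_threshold(
    ys: np.ndarray | list[np.ndarray],
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    step: float = 1.0,
    p_entry: float = 0.001,
    p_removal: float = 0.002,
    reselect_cofactors: bool = True,
    grid: ScanGrid | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold by phenotype permutation.

    ``ys`` is one line-mean vector, or a list of them (one per trait) whose
    per-permutation genome-wide maxima are pooled before taking the
    empirical (1 - alpha) quantile.  By default cofactor selection is
    re-run inside every permutation (the conservative, literal procedure);
    ``reselect_cofactors=False`` is an approximate fast mode that scans
    with no cofactors.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y_list = [np.asarray(ys, dtype=float)] if isinstance(ys, np.ndarray) else [
        np.asarray(v, dtype=float) for v in ys
    ]
    sub = genotypes.subset_markers([m for m in gmap.markers])
    if grid is None:
        grid = precompute_scan_grid(sub, gmap, step=step)
    empty = CofactorModel([], {}, 0.0, p_entry, p_removal)
    maxima: list[float] = []
    for y in y_list:
        n = len(y)
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            model = None if reselect_cofactors else empty
            profile = icim_scan(
                yp, sub, gmap, step=step, p_entry=p_entry,
                p_removal=p_removal, grid=grid, model=model,
            )
            maxima.append(float(profile["lod"].max()))
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    if return_maxima:
        return threshold, np.asarray(maxima)
    return threshold


# ---------------------------------------------------------------------------
# peak calling and consolidation


def _local_peak_indices(lod) -> list[int]:
    """Positional indices of local maxima along one chromosome's profile.

    A plateau counts once, at its first position; chromosome ends count
    when strictly above the inner neighbor.
    """
    out = []
    k = len(lod)
    i = 0
    while i < k:
        j = i
        while j + 1 < k and lod[j + 1] == lod[i]:
            j += 1
        left_ok = i == 0 or lod[i] > lod[i - 1]
        right_ok = j == k - 1 or lod[j + 1] < lod[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return out


def _prune_shallow_peaks(lod, peaks: list[int], min_drop: float) -> list[int]:
    """Merge consecutive peaks unless the valley between them drops by at
    least ``min_drop`` below the lower peak (keep the higher)."""
    peaks = sorted(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for a, b in zip(peaks, peaks[1:]):
            valley = lod[a:b + 1].min()
            if valley > min(lod[a], lod[b]) - min_drop:
                peaks.remove(a if lod[a] <= lod[b] else b)
                changed = True
                break
    return peaks


def call_qtl(
    profiles: dict[str, pd.DataFrame],
    threshold: float,
    trait: str,
    min_peak_drop: float = 1.0,
) -> pd.DataFrame:
    """Declare QTL from per-environment scan profiles of one trait.

    A marker interval hosts a QTL if at least one environment has a local
    LOD maximum >= ``threshold`` inside it.  Two refinements keep one
    locus from being reported twice when its peak straddles a marker:
    consecutive local maxima separated by a LOD dip shallower than
    ``min_peak_drop`` merge into the higher peak, and significant
    intervals sharing a flanking marker merge into one region, reported
    at the interval holding the best peak.  Each record row carries one
    environment's own within-region peak (position, LOD, PVE, additive
    effect) with a significance flag, sub-threshold environments
    included; QTL are named q<trait><chromosome>, with -1/-2... ordinal
    suffixes (by position) when one chromosome hosts several for the
    trait.

    Returns a long DataFrame: qtl, trait, chromosome, left_marker,
    right_marker, env, pos_cm, lod, pve, add, significant.
    """
    columns = ["qtl", "trait", "chromosome", "left_marker", "right_marker",
               "env", "pos_cm", "lod", "pve", "add", "significant"]
    if not profiles:
        return pd.DataFrame(columns=columns)

    any_profile = next(iter(profiles.values()))
    chroms = list(dict.fromkeys(any_profile["chromosome"]))
    records = []
    for chrom in chroms:
        sig_ivs: set[int] = set()
        for env, profile in profiles.items():
            sub = profile[profile["chromosome"] == chrom].reset_index(drop=True)
            lod = sub["lod"].to_numpy()
            peaks = _prune_shallow_peaks(lod, _local_peak_indices(lod),
                                         min_peak_drop)
            for i in peaks:
                if lod[i] >= threshold:
                    sig_ivs.add(int(sub.loc[i, "interval"]))
        if not sig_ivs:
            continue
        # runs of adjacent intervals form one QTL region
        ordered = sorted(sig_ivs)
        regions: list[list[int]] = [[ordered[0]]]
        for iv in ordered[1:]:
            if iv == regions[-1][-1] + 1:
                regions[-1].append(iv)
            else:
                regions.append([iv])
        for region in regions:
            per_env = {}
            for env, profile in profiles.items():
                sub = profile[
                    (profile["chromosome"] == chrom)
                    & profile["interval"].isin(region)
                ]
                if len(sub) == 0:
                    continue
                per_env[env] = sub.loc[sub["lod"].idxmax()]
            if not per_env:
                continue
            best = max(per_env.values(), key=lambda r: r["lod"])
            records.append((chrom, best["left_marker"], best["right_marker"],
                            per_env))

    # ordinal naming per chromosome, ordered by position
    by_chrom: dict[str, list] = {}
    for rec in records:
        by_chrom.setdefault(rec[0], []).append(rec)
    rows = []
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: np.mean([b["cm"] for b in r[3].values()]))
        for k, (c, left, right, per_env) in enumerate(recs, start=1):
            name = f"q{trait}{c}" + (f"-{k}" if len(recs) > 1 else "")
            for env, best in per_env.items():
                rows.append(
                    {
                        "qtl": name,
                        "trait": trait,
                        "chromosome": c,
                        "left_marker": left,
                        "right_marker": right,
                        "env": env,
                        "pos_cm": float(best["cm"]),
                        "lod": float(best["lod"]),
                        "pve": float(best["pve"]),
                        "add": float(best["add"]),
                        "significant": bool(best["lod"] >= threshold),
                    }
                )
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def consolidate_qtl(records: pd.DataFrame) -> pd.DataFrame:
    """Cluster QTL records sharing a flanking-marker interval.

    Records (across traits) with identical (chromosome, left_marker,
    right_marker) merge into one row listing, per environment, the QTL
    significant there.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["chromosome", "left_marker", "right_marker",
                                     "n_qtl"])
    envs = sorted(records["env"].unique())
    rows = []
    grouped = records.groupby(["chromosome", "left_marker", "right_marker"],
                              sort=False)
    for (chrom, left, right), sub in grouped:
        row = {"chromosome": chrom, "left_marker": left, "right_marker": right,
               "n_qtl": sub["qtl"].nunique()}
        for env in envs:
            names = sub[(sub["env"] == env) & sub["significant"]]["qtl"].unique()
            row[env] = ", ".join(sorted(names))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["chromosome", "left_marker"], key=lambda s: s.map(str)
    ).reset_index(drop=True)
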