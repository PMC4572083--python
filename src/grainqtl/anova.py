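"""Combined multi-environment ANOVA, variance components and heritability.

For a balanced multi-location trial of n inbred lines grown in e
environments with r replications (randomized complete blocks within each
environment), the observation model is

    y_ijk = mu + R_k/j + G_i + E_j + GE_ij + eps_ijk,   eps ~ N(0, s2_eps)

with sources: replication-within-environment R, genotype G, environment E,
genotype-by-environment GE and residual error.  Sums of squares come from
the marginal means of the balanced layout, so the decomposition is exact
(total SS = sum of component SS).

Variance components are estimated by the method of moments as

    s2_G  = (MS_G  - MS_eps) / (e r)
    s2_GE = (MS_GE - MS_eps) / r
    s2_eps = MS_eps

(the genotype mean square is contrasted against the pooled error; the
textbook EMS estimator using MS_GE in the genotype numerator is available
via ``ems="standard"``).  Broad-sense heritability excludes the
environment main effect from the phenotypic variance and is reported at
plot level and on line means:

    H2_plot = s2_G / (s2_G + s2_GE + s2_eps)
    H2_mean = s2_G / (s2_G + s2_GE / e + s2_eps / (e r))

Negative component estimates are preserved (with a flag) rather than
truncated, so heritabilities remain reconstructible from the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "HeritabilityResult",
    "fit_anova",
    "variance_components",
    "heritability",
]


SOURCES = ("environment", "rep_within_env", "genotype", "gxe", "error")


@dataclass
class AnovaTable:
    """Per-source df / SS / MS / F / p plus the design dimensions."""

    table: pd.DataFrame  # index: SOURCES + 'total'
    n_lines: int
    n_envs: int
    n_reps: int

    def ms(self, source: str) -> float:
        return float(self.table.loc[source, "MS"])


@dataclass
class VarianceComponents:
    var_g: float
    var_ge: float
    var_error: float
    n_envs: int
    n_reps: int
    negative_flagged: bool  # any raw estimate below zero


@dataclass
class HeritabilityResult:
    h2_plot: float
    h2_mean: float
    var_p_plot: float
    var_p_mean: float


def _check_balanced(sub: pd.DataFrame) -> tuple[list, list, list]:
    counts = sub.pivot_table(index="line", columns=["env", "rep"],
                             values="value", aggfunc="count")
    if counts.isna().any().any() or (counts != 1).any().any():
        bad = counts[(counts != 1) | counts.isna()].stack(future_stack=True).dropna()
        raise ValueError(
            "unbalanced design: every line x environment x replication cell "
            f"must hold exactly one observation; offending cells:\n{bad.head(20)}"
        )
    lines = counts.index.tolist()
    envs = sorted({e for e, _ in counts.columns})
    reps = sorted({r for _, r in counts.columns})
    return lines, envs, reps


def fit_anova(phenotypes: pd.DataFrame, trait: str) -> AnovaTable:
    """Combined ANOVA over environments for one trait (balanced data only).

    F statistics test each source against the residual mean square.
    Raises ValueError with a per-cell report for unbalanced input.
    """
    sub = phenotypes[phenotypes["trait"] == trait]
    if len(sub) == 0:
        raise KeyError(f"trait not in phenotype table: {trait}")
    lines, envs, reps = _check_balanced(sub)
    n, e, r = len(lines), len(envs), len(reps)

    y = (
        sub.set_index(["line", "env", "rep"])["value"]
        .unstack(["env", "rep"])
        .loc[lines]
        .to_numpy()
        .reshape(n, e, r)
    )
    grand = y.mean()
    m_env = y.mean(axis=(0, 2))          # (e,)
    m_rep = y.mean(axis=0)               # (e, r)
    m_gen = y.mean(axis=(1, 2))          # (n,)
    m_ge = y.mean(axis=2)                # (n, e)

    ss_env = n * r * np.sum((m_env - grand) ** 2)
    ss_rep = n * np.sum((m_rep - m_env[:, None]) ** 2)
    ss_gen = e * r * np.sum((m_gen - grand) ** 2)
    ss_ge = r * np.sum((m_ge - m_gen[:, None] - m_env[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_env - ss_rep - ss_gen - ss_ge

    df = {
        "environment": e - 1,
        "rep_within_env": e * (r - 1),
        "genotype": n - 1,
        "gxe": (n - 1) * (e - 1),
        "error": (n - 1) * e * (r - 1),
    }
    ss = {
        "environment": ss_env,
        "rep_within_env": ss_rep,
        "genotype": ss_gen,
        "gxe": ss_ge,
        "error": ss_err,
    }
    rows = []
    ms_err = ss_err / df["error"] if df["error"] > 0 else np.nan
    for src in SOURCES:
        ms = ss[src] / df[src] if df[src] > 0 else np.nan
        if src != "error" and df[src] > 0 and df["error"] > 0 and ms_err > 0:
            f_stat = ms / ms_err
            p = stats.f.sf(f_stat, df[src], df["error"])
        else:
            f_stat, p = np.nan, np.nan
        rows.append((src, df[src], ss[src], ms, f_stat, p))
    rows.append(("total", n * e * r - 1, ss_total, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["source", "df", "SS", "MS", "F", "p"]
    ).set_index("source")
    return AnovaTable(table=table, n_lines=n, n_envs=e, n_reps=r)


def variance_components(
    table: AnovaTable, ems: str = "as-printed"
) -> VarianceComponents:
    """Method-of-moments variance components from the ANOVA mean squares.

    ``ems="as-printed"`` contrasts MS_G against the pooled error
    (s2_G = (MS_G - MS_eps)/(e r)); ``ems="standard"`` uses the textbook
    expected-mean-squares ladder (s2_G = (MS_G - MS_GE)/(e r)).
    """
    if ems not in ("as-printed", "standard"):
        raise ValueError("ems must be 'as-printed' or 'standard'")
    e, r = table.n_envs, table.n_reps
    ms_g = table.ms("genotype")
    ms_ge = table.ms("gxe")
    ms_err = table.ms("error")
    if ems == "as-printed":
        var_g = (ms_g - ms_err) / (e * r)
    else:
        var_g = (ms_g - ms_ge) / (e * r)
    var_ge = (ms_ge - ms_err) / r
    return VarianceComponents(
        var_g=var_g,
        var_ge=var_ge,
        var_error=ms_err,
        n_envs=e,
        n_reps=r,
        negative_flagged=bool(var_g < 0 or var_ge < 0),
    )


def heritability(vc: VarianceComponents) -> HeritabilityResult:
    """Broad-sense heritability at plot level and on line means."""
    e, r = vc.n_envs, vc.n_reps
    var_p_plot = vc.var_g + vc.var_ge + vc.var_error
    var_p_mean = vc.var_g + vc.var_ge / e + vc.var_error / (e * r)
    if var_p_plot == 0 or var_p_mean == 0:
        return HeritabilityResult(np.nan, np.nan, var_p_plot, var_p_mean)
    return HeritabilityResult(
        h2_plot=vc.var_g / var_p_plot,
        h2_mean=vc.var_g / var_p_mean,
        var_p_plot=var_p_plot,
        var_p_mean=var_p_mean,
    )
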