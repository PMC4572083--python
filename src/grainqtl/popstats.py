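"""Marker- and line-level diagnostics for a biparental RIL population.

Three checks routinely reported for an inbred mapping population:

* **Parental contribution** — per line, the fraction of non-missing marker
  calls carrying a given parent's allele.  In a drift-free RIL population
  the expectation is 0.5; SSD populations show substantial spread.
* **Segregation distortion** — per marker, a chi-square test of the
  observed A:B call counts against the Mendelian 1:1 ratio (df = 1).
  Tests are reported at a raw significance level (no multiple-testing
  correction), matching common practice for marker QC.
* **Trait correlations** — Pearson correlations between trait line means
  with two-sided t-test significance stars at 0.05 / 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CODE_A, CODE_B, GenotypeMatrix

__all__ = [
    "parental_contribution",
    "contribution_histogram",
    "segregation_test",
    "trait_correlations",
]


def parental_contribution(genotypes: GenotypeMatrix, parent: str = "A") -> pd.Series:
    """Per-line fraction of non-missing calls matching ``parent`` (A or B).

    Lines with no non-missing call get NaN.
    """
    if parent not in ("A", "B"):
        raise ValueError("parent must be 'A' or 'B'")
    code = CODE_A if parent == "A" else CODE_B
    codes = genotypes.codes
    matches = (codes == code).sum(axis=1).astype(float)
    informative = (codes != 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative > 0, matches / informative, np.nan)
    return pd.Series(frac, index=pd.Index(genotypes.lines, name="line"),
                     name=f"contribution_{parent}")


def contribution_histogram(contribution: pd.Series, bin_width: float = 0.05) -> pd.Series:
    """Binned counts of per-line contributions (undefined lines excluded)."""
    values = contribution.dropna().to_numpy()
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    labels = [f"[{edges[i]:.2f},{edges[i + 1]:.2f})" for i in range(len(counts))]
    return pd.Series(counts, index=labels, name="lines")


def segregation_test(genotypes: GenotypeMatrix, alpha: float = 0.001) -> pd.DataFrame:
    """Chi-square 1:1 segregation test per marker.

    chi2 = (n_A - n/2)^2/(n/2) + (n_B - n/2)^2/(n/2) with n the number of
    non-missing calls; p from the chi-square distribution with 1 df.
    Markers with no non-missing call are flagged untestable (NaN
    statistics, ``distorted=False``).
    """
    codes = genotypes.codes
    n_a = (codes == CODE_A).sum(axis=0).astype(float)
    n_b = (codes == CODE_B).sum(axis=0).astype(float)
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n > 0, (n_a - n_b) ** 2 / n, np.nan)
        freq_a = np.where(n > 0, n_a / n, np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(chi2, df=1))
    return pd.DataFrame(
        {
            "marker": genotypes.markers,
            "n_A": n_a.astype(int),
            "n_B": n_b.astype(int),
            "freq_A": freq_a,
            "chi2": chi2,
            "p": p,
            "testable": n > 0,
            "distorted": np.where(np.isnan(p), False, p < alpha),
        }
    )


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_correlations(
    phenotypes: pd.DataFrame,
    traits: list[str] | None = None,
    env: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between trait line means.

    Line means are taken over environments and replications (or within a
    single ``env`` if given).  Returns ``(r, stars)``: the correlation
    matrix and a matching matrix of significance markers ('' / '*' / '**'
    at 0.05 / 0.01, two-sided t-test).  Pairs involving a constant trait
    are NaN.  Requires at least 3 lines.
    """
    sub = phenotypes if env is None else phenotypes[phenotypes["env"] == env]
    means = sub.pivot_table(index="line", columns="trait", values="value",
                            aggfunc="mean")
    if traits is not None:
        missing = [t for t in traits if t not in means.columns]
        if missing:
            raise KeyError(f"traits not in phenotype table: {missing}")
        means = means[traits]
    if len(means) < 3:
        raise ValueError("need at least 3 lines for correlations")
    cols = list(means.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    x = means.to_numpy()
    for i in range(k):
        for j in range(i, k):
            xi, xj = x[:, i], x[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    stars_df = pd.DataFrame(
        [[_stars(p[i, j]) if i != j else "" for j in range(k)] for i in range(k)],
        index=cols, columns=cols,
    )
    return r_df, stars_df
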