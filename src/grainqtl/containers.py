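"""Shared data containers: genetic map, genotype matrix, phenotype table.

Conventions used throughout the package:

* Genotype calls are the two parental homozygote classes of a recombinant
  inbred line (RIL) population — ``A`` (the first parent's allele, e.g. the
  *japonica* parent) and ``B`` (the second parent's, e.g. the *indica*
  parent) — or missing.  Internally calls are stored as an int8 matrix with
  ``+1 = A``, ``-1 = B``, ``0 = missing``.
* Map positions are centimorgans (cM) within a chromosome, starting at 0.
* Phenotypes live in a long-format DataFrame with columns
  ``line, env, rep, trait, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CODE_A: int = 1
CODE_B: int = -1
CODE_MISSING: int = 0

PHENOTYPE_COLUMNS = ("line", "env", "rep", "trait", "value")

__all__ = [
    "CODE_A",
    "CODE_B",
    "CODE_MISSING",
    "PHENOTYPE_COLUMNS",
    "GeneticMap",
    "GenotypeMatrix",
    "line_means",
]


@dataclass
class GeneticMap:
    """Ordered markers with chromosome assignment and cM positions."""

    frame: pd.DataFrame  # columns: marker, chromosome, cm

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "cm"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"map frame needs columns {sorted(required)}")
        if self.frame["marker"].duplicated().any():
            dup = self.frame.loc[self.frame["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker ids in map: {list(dup)}")
        self.frame = self.frame.reset_index(drop=True)
        for _, sub in self.frame.groupby("chromosome", sort=False):
            if (np.diff(sub["cm"].to_numpy(dtype=float)) < 0).any():
                raise ValueError("cM positions must be non-decreasing per chromosome")

    @property
    def markers(self) -> list[str]:
        return self.frame["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def chromosome_table(self, chrom) -> pd.DataFrame:
        sub = self.frame[self.frame["chromosome"] == chrom]
        if len(sub) == 0:
            raise KeyError(f"no such chromosome: {chrom}")
        return sub.reset_index(drop=True)

    def positions(self, chrom) -> np.ndarray:
        return self.chromosome_table(chrom)["cm"].to_numpy(dtype=float)

    def chrom_markers(self, chrom) -> list[str]:
        return self.chromosome_table(chrom)["marker"].tolist()

    def length(self, chrom) -> float:
        pos = self.positions(chrom)
        return float(pos[-1] - pos[0])

    def total_length(self) -> float:
        return float(sum(self.length(c) for c in self.chromosomes))

    def position_of(self, marker: str) -> tuple[str, float]:
        row = self.frame[self.frame["marker"] == marker]
        if len(row) == 0:
            raise KeyError(f"marker not in map: {marker}")
        return row.iloc[0]["chromosome"], float(row.iloc[0]["cm"])


@dataclass
class GenotypeMatrix:
    """lines x markers RIL genotype calls (A / B / missing)."""

    lines: list[str]
    markers: list[str]
    codes: np.ndarray = field(repr=False)  # int8, +1=A, -1=B, 0=missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if not np.isin(self.codes, (CODE_A, CODE_B, CODE_MISSING)).all():
            raise ValueError("genotype codes must be in {+1, -1, 0}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker not in genotype matrix: {marker}") from None

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.marker_index(marker)]

    def subset_markers(self, markers: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in markers]
        return GenotypeMatrix(list(self.lines), list(markers), self.codes[:, idx])

    def to_frame(self) -> pd.DataFrame:
        """Calls as strings: 'A', 'B', '-' (missing); lines as index."""
        mapping = np.array(["B", "-", "A"])  # index by code+1
        data = mapping[self.codes.astype(int) + 1]
        return pd.DataFrame(data, index=pd.Index(self.lines, name="line"),
                            columns=self.markers)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        codes = np.zeros(frame.shape, dtype=np.int8)
        values = frame.to_numpy()
        for (code, symbols) in (
            (CODE_A, {"A", "a"}),
            (CODE_B, {"B", "b"}),
        ):
            mask = np.isin(values, list(symbols))
            codes[mask] = code
        # anything else (-, '', NaN) stays missing; reject unexpected symbols
        known = np.isin(values, ["A", "a", "B", "b", "-", ""]) | pd.isna(values)
        if not known.all():
            i, j = np.argwhere(~known)[0]
            raise ValueError(
                f"unrecognised genotype call {values[i, j]!r} at "
                f"line {frame.index[i]!r}, marker {frame.columns[j]!r}"
            )
        return cls(list(frame.index.astype(str)), list(frame.columns), codes)


def line_means(
    phenotypes: pd.DataFrame, trait: str, by_env: bool = False
) -> pd.Series | pd.DataFrame:
    """Per-line phenotype means for one trait.

    With ``by_env=False`` averages over environments and replications
    (one value per line); with ``by_env=True`` returns a line x env
    DataFrame of within-environment means over replications.
    """
    sub = phenotypes[phenotypes["trait"] == trait]
    if len(sub) == 0:
        raise KeyError(f"trait not in phenotype table: {trait}")
    if by_env:
        return sub.pivot_table(index="line", columns="env", values="value",
                               aggfunc="mean")
    return sub.groupby("line")["value"].mean()
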