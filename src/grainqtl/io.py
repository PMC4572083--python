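"""File formats, run configuration and the end-to-end pipeline.

All tables are plain CSV/TSV:

* ``genotype.csv`` — lines as rows (first column ``line``), markers as
  columns, calls ``A`` / ``B`` / ``-`` (missing; case-insensitive, empty
  cells also count as missing).
* ``map.csv`` — columns ``marker, chromosome, cm``.
* ``phenotype.csv`` — long format, columns ``line, env, rep, trait,
  value``.

``run_pipeline`` executes simulate (optional) -> marker/line diagnostics
-> ANOVA + heritability -> map construction -> ICIM scans -> QTL calling
and consolidation, writing one table per stage plus a JSON manifest with
the seed, parameters and row counts.  Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import fit_anova, heritability, variance_components
from .containers import GeneticMap, GenotypeMatrix, line_means
from .icim import call_qtl, consolidate_qtl, icim_scan, permutation_threshold, precompute_scan_grid
from .linkage import construct_map
from .popstats import contribution_histogram, parental_contribution, segregation_test, trait_correlations
from .simulate import simulate_study, study_config

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
    "load_config",
    "save_config",
    "run_pipeline",
]


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype CSV (rows = lines, columns = markers)."""
    # pandas mangles duplicate headers, so check the raw header line first
    with open(path) as fh:
        header = next(csv.reader(fh))
    dup_header = {h for h in header if header.count(h) > 1}
    if dup_header:
        raise ValueError(f"{path}: duplicate marker ids: {sorted(dup_header)}")
    frame = pd.read_csv(path, dtype=str)
    if frame.columns[0].lower() != "line":
        raise ValueError(
            f"{path}: first column must be 'line', got {frame.columns[0]!r}"
        )
    frame = frame.set_index(frame.columns[0])
    dup = frame.columns[frame.columns.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate marker ids: {sorted(set(dup))}")
    dup_lines = frame.index[frame.index.duplicated()]
    if len(dup_lines):
        raise ValueError(f"{path}: duplicate line ids: {sorted(set(dup_lines))}")
    return GenotypeMatrix.from_frame(frame)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    genotypes.to_frame().to_csv(path)


def read_map(path) -> GeneticMap:
    frame = pd.read_csv(path, dtype={"marker": str, "chromosome": str})
    required = {"marker", "chromosome", "cm"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: map needs columns {sorted(required)}")
    bad = frame[pd.to_numeric(frame["cm"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric cM position for marker {bad.iloc[0]['marker']!r}"
        )
    frame["cm"] = frame["cm"].astype(float)
    return GeneticMap(frame[["marker", "chromosome", "cm"]])


def write_map(gmap: GeneticMap, path) -> None:
    out = gmap.frame.copy()
    out["cm"] = out["cm"].round(2)
    out.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"line": str, "env": str, "trait": str})
    required = {"line", "env", "rep", "trait", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: phenotypes need columns {sorted(required)}")
    numeric = pd.to_numeric(frame["value"], errors="coerce")
    bad = frame[numeric.isna() & frame["value"].notna()]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: non-numeric phenotype value {row['value']!r} at line "
            f"{row['line']!r}, env {row['env']!r}, rep {row['rep']!r}, "
            f"trait {row['trait']!r}"
        )
    frame["value"] = numeric
    return frame[["line", "env", "rep", "trait", "value"]]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see module docstring for formats."""

    outdir: str
    genotypes: str | None = None
    map: str | None = None
    phenotypes: str | None = None
    traits: list[str] = field(default_factory=list)  # empty = all in table
    p_entry: float = 0.001
    p_removal: float = 0.002
    step_cm: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    distortion_alpha: float = 0.001
    map_function: str = "haldane"
    ripple_window: int = 8
    min_informative: int = 30
    seed: int = 0
    simulate: bool = False
    sim_n_lines: int = 215

    def __post_init__(self) -> None:
        if not (0 < self.p_entry <= self.p_removal < 1):
            raise ValueError("need 0 < p_entry <= p_removal < 1")
        if self.step_cm <= 0:
            raise ValueError("step_cm must be > 0")
        if not self.simulate:
            for name in ("genotypes", "map", "phenotypes"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(
                        f"config error: {name} path required unless simulate=true"
                    )
                if not Path(value).exists():
                    raise ValueError(f"config error: {name} file not found: {value}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def _stage(outdir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / f"failed_{name}.txt").write_text(
                    f"stage {name} failed: {exc}\n"
                )
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "grainqtl_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "row_counts": {},
    }

    with _stage(outdir, "load"):
        if config.simulate:
            sim = simulate_study(
                study_config(n_lines=config.sim_n_lines), seed=config.seed
            )
            genotypes, gmap_in, phenotypes = sim.genotypes, sim.gmap, sim.phenotypes
            write_genotypes(genotypes, outdir / "genotype.csv")
            write_map(gmap_in, outdir / "map.csv")
            write_phenotypes(phenotypes, outdir / "phenotype.csv")
        else:
            genotypes = read_genotypes(config.genotypes)
            gmap_in = read_map(config.map)
            phenotypes = read_phenotypes(config.phenotypes)
            missing = [m for m in genotypes.markers if m not in set(gmap_in.markers)]
            if missing:
                raise ValueError(f"markers absent from map: {missing[:10]}")
    traits = config.traits or sorted(phenotypes["trait"].unique())
    envs = sorted(phenotypes["env"].unique())

    with _stage(outdir, "popstats"):
        contrib = parental_contribution(genotypes, "A")
        contrib.to_frame().assign(
            histogram_bin=pd.cut(contrib, bins=np.arange(0, 1.05, 0.05))
        ).to_csv(outdir / "contribution.tsv", sep="\t")
        contribution_histogram(contrib).to_csv(
            outdir / "contribution_histogram.tsv", sep="\t"
        )
        distortion = segregation_test(genotypes, alpha=config.distortion_alpha)
        distortion.to_csv(outdir / "distortion.tsv", sep="\t", index=False)
        corr, corr_stars = trait_correlations(phenotypes, traits)
        corr.round(3).to_csv(outdir / "correlations.tsv", sep="\t")
        corr_stars.to_csv(outdir / "correlation_stars.tsv", sep="\t")
        manifest["row_counts"]["markers"] = genotypes.n_markers
        manifest["row_counts"]["lines"] = genotypes.n_lines
        manifest["row_counts"]["distorted_markers"] = int(
            distortion["distorted"].sum()
        )

    with _stage(outdir, "anova"):
        herit_rows = []
        for trait in traits:
            table = fit_anova(phenotypes, trait)
            table.table.to_csv(outdir / f"anova_{trait}.tsv", sep="\t")
            vc = variance_components(table)
            h2 = heritability(vc)
            herit_rows.append(
                {
                    "trait": trait,
                    "var_G": vc.var_g,
                    "var_GE": vc.var_ge,
                    "var_error": vc.var_error,
                    "H2_plot": h2.h2_plot,
                    "H2_mean": h2.h2_mean,
                    "negative_flagged": vc.negative_flagged,
                }
            )
        pd.DataFrame(herit_rows).to_csv(
            outdir / "heritability.tsv", sep="\t", index=False
        )

    with _stage(outdir, "map"):
        anchors = dict(zip(gmap_in.frame["marker"], gmap_in.frame["chromosome"]))
        gmap, map_summary = construct_map(
            genotypes,
            anchors=anchors,
            min_informative=config.min_informative,
            window=config.ripple_window,
            map_function=config.map_function,
        )
        write_map(gmap, outdir / "map_built.csv")
        pd.Series(map_summary).to_csv(outdir / "map_summary.tsv", sep="\t")
        manifest["row_counts"]["map_total_length_cm"] = round(
            map_summary["total_length_cm"], 2
        )

    with _stage(outdir, "scan"):
        grid = precompute_scan_grid(
            genotypes.subset_markers(gmap.markers), gmap, step=config.step_cm,
            map_function=config.map_function,
        )
        trait_env_means: dict[str, pd.DataFrame] = {
            t: line_means(phenotypes, t, by_env=True).loc[genotypes.lines]
            for t in traits
        }
        pooled = [
            trait_env_means[t].mean(axis=1).to_numpy() for t in traits
        ]
        threshold = permutation_threshold(
            pooled, genotypes, gmap, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, step=config.step_cm, p_entry=config.p_entry,
            p_removal=config.p_removal, grid=grid,
        )
        manifest["lod_threshold"] = threshold
        all_records = []
        for trait in traits:
            profiles = {}
            for env in envs:
                y = trait_env_means[trait][env].to_numpy()
                profile = icim_scan(
                    y, genotypes, gmap, step=config.step_cm,
                    p_entry=config.p_entry, p_removal=config.p_removal,
                    grid=grid,
                )
                profile.to_csv(
                    outdir / f"scan_{trait}_{env}.tsv", sep="\t", index=False
                )
                profiles[env] = profile
            records = call_qtl(profiles, threshold, trait)
            records.to_csv(outdir / f"qtl_{trait}.tsv", sep="\t", index=False)
            all_records.append(records)
        qtl = pd.concat(all_records, ignore_index=True)
        clusters = consolidate_qtl(qtl)
        clusters.to_csv(outdir / "qtl_clusters.tsv", sep="\t", index=False)
        manifest["row_counts"]["qtl"] = int(qtl["qtl"].nunique()) if len(qtl) else 0
        manifest["row_counts"]["qtl_clusters"] = len(clusters)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
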