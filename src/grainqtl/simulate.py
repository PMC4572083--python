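"""Synthetic RIL study generator.

Generates recombinant inbred line (RIL) genotypes by simulated meiosis and
single seed descent (SSD), and multi-environment phenotypes from planted
QTL under the standard combined-trial linear model

    y_ijk = mu + R_k/j + G_i + E_j + GE_ij + eps_ijk

where G_i = sum_q a_q x_iq is the additive genetic value of line i over
the planted QTL (x = +1 for the B-parent allele, -1 for the A-parent
allele), E_j is a fixed environment shift, R_k/j a random
replication-within-environment (block) effect, GE_ij a random
line-by-environment interaction and eps_ijk the plot residual.

Meiosis places crossovers as a Poisson process on the Morgan scale (no
interference), i.e. adjacent loci d cM apart recombine with the Haldane
probability r = (1 - exp(-2d/100)) / 2.  Lines descend from an F1 between
two fully homozygous parents by ``selfing_generations`` rounds of SSD;
residual heterozygous calls are recorded as missing, since downstream
statistics treat the population as two homozygous classes.

The default study configuration mirrors a 215-line, 143-marker,
12-chromosome rice population grown in 4 environments with 2 replications:
grain length (GL) and grain width (GW) carry planted QTL (one major plus
several minor each, over a weak polygenic background), and the other five
shape characters are derived from (GL, GW) per observation through the
ellipse model, which induces pleiotropy between the seven characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CODE_A, CODE_B, GeneticMap, GenotypeMatrix
from .geometry import derive_traits

__all__ = [
    "PlantedQTL",
    "TraitModel",
    "SimConfig",
    "StudyData",
    "default_map",
    "study_config",
    "null_config",
    "haldane_recomb_prob",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "simulate_study",
    "distort_segregation",
]


def haldane_recomb_prob(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Per-meiosis recombination probability for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class PlantedQTL:
    """A simulated causal locus: chromosome, cM position, additive effect.

    ``effect`` follows the convention that a positive value means the
    B-parent allele increases the trait.
    """

    chromosome: str
    cm: float
    effect: float


@dataclass
class TraitModel:
    """Generative model for one directly simulated trait."""

    mean: float
    env_effects: tuple[float, ...]  # fixed shift per environment
    var_ge: float = 0.0  # sigma^2 of line x environment interaction
    var_rep: float = 0.0  # sigma^2 of replication (block) within environment
    var_resid: float = 0.0  # sigma^2 of the plot residual
    qtl: tuple[PlantedQTL, ...] = ()

    def __post_init__(self) -> None:
        for name in ("var_ge", "var_rep", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimConfig:
    """Full study configuration: map, population and trait models."""

    gmap: GeneticMap
    n_lines: int = 215
    selfing_generations: int = 11  # F1 -> F12
    n_envs: int = 4
    n_reps: int = 2
    traits: dict[str, TraitModel] = field(default_factory=dict)
    derive_shape_traits: bool = True  # derive LW/GC/GA/GD/GR from GL, GW

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if self.n_envs < 1 or self.n_reps < 1:
            raise ValueError("need at least one environment and one replication")
        for trait, model in self.traits.items():
            if len(model.env_effects) != self.n_envs:
                raise ValueError(
                    f"trait {trait}: {len(model.env_effects)} env effects for "
                    f"{self.n_envs} environments"
                )
            for q in model.qtl:
                if q.chromosome not in self.gmap.chromosomes:
                    raise ValueError(f"QTL chromosome {q.chromosome} not in map")
                pos = self.gmap.positions(q.chromosome)
                if not (pos[0] <= q.cm <= pos[-1]):
                    raise ValueError(
                        f"QTL at {q.cm} cM outside chromosome {q.chromosome} "
                        f"span [{pos[0]}, {pos[-1]}]"
                    )
        if self.derive_shape_traits and self.traits and not (
            {"GL", "GW"} <= set(self.traits)
        ):
            raise ValueError("derive_shape_traits requires GL and GW models")

    @property
    def planted_qtl(self) -> list[tuple[str, PlantedQTL]]:
        return [(t, q) for t, m in self.traits.items() for q in m.qtl]

    @property
    def envs(self) -> list[str]:
        return [f"E{j + 1}" for j in range(self.n_envs)]


# ---------------------------------------------------------------------------
# default study conditions


_CHROM_MARKER_COUNTS = (15, 14, 14, 12, 12, 12, 11, 12, 10, 9, 11, 11)  # 143
_TOTAL_MAP_LENGTH = 1474.31  # cM across 131 intervals


def default_map() -> GeneticMap:
    """12-chromosome, 143-marker map, ~1474 cM, evenly spaced markers."""
    spacing = _TOTAL_MAP_LENGTH / (sum(_CHROM_MARKER_COUNTS) - len(_CHROM_MARKER_COUNTS))
    rows = []
    for c, count in enumerate(_CHROM_MARKER_COUNTS, start=1):
        for j in range(count):
            rows.append((f"C{c:02d}M{j + 1:02d}", str(c), round(j * spacing, 2)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]))


def _background(effect: float, frac: float, gmap: GeneticMap) -> tuple[PlantedQTL, ...]:
    """One small-effect locus per chromosome, alternating sign."""
    out = []
    for i, chrom in enumerate(gmap.chromosomes):
        pos = gmap.positions(chrom)
        cm = pos[0] + frac * (pos[-1] - pos[0])
        out.append(PlantedQTL(chrom, round(cm, 2), effect * (1 if i % 2 == 0 else -1)))
    return tuple(out)


def study_config(gmap: GeneticMap | None = None, n_lines: int = 215) -> SimConfig:
    """Default synthetic study: grain length and width with planted QTL.

    GL carries one major QTL (a = +0.43 mm on chromosome 3, PVE ~ 50%) and
    four minor QTL (PVE ~ 6-10%); GW one major (a = -0.12 mm on chromosome
    5, PVE ~ 30%) and three minor.  Both traits add a weak polygenic
    background (|a| ~ 0.05-0.07, one locus per chromosome) so genotypic
    variances land near 0.35 (GL) and 0.045 (GW) mm^2 — the magnitudes a
    high-heritability multi-location grain trial exhibits.  Environment,
    G-by-E, block and residual variances are small relative to the
    genotypic variance.  The other five shape characters are derived from
    (GL, GW) per observation.
    """
    if gmap is None:
        gmap = default_map()
    gl_qtl = (
        PlantedQTL("3", 112.0, +0.43),  # major
        PlantedQTL("2", 87.0, +0.18),
        PlantedQTL("7", 80.0, +0.17),
        PlantedQTL("8", 92.0, +0.16),
        PlantedQTL("6", 95.0, +0.15),
    ) + _background(0.065, 0.45, gmap)
    gw_qtl = (
        PlantedQTL("5", 15.0, -0.12),  # major
        PlantedQTL("3", 112.0, -0.06),
        PlantedQTL("2", 70.0, -0.05),
        PlantedQTL("6", 58.0, -0.05),
    ) + _background(0.047, 0.55, gmap)
    traits = {
        "GL": TraitModel(
            mean=5.8,
            env_effects=(-0.15, -0.05, 0.05, 0.15),
            var_ge=0.0139,
            var_rep=0.002,
            var_resid=0.0111,
            qtl=gl_qtl,
        ),
        "GW": TraitModel(
            mean=2.8,
            env_effects=(-0.03, -0.01, 0.01, 0.03),
            var_ge=0.0021,
            var_rep=0.0005,
            var_resid=0.0026,
            qtl=gw_qtl,
        ),
    }
    return SimConfig(gmap=gmap, n_lines=n_lines, traits=traits)


def null_config(
    gmap: GeneticMap,
    n_lines: int,
    var_resid: float = 0.0111,
    var_ge: float = 0.0139,
    n_envs: int = 4,
    n_reps: int = 2,
) -> SimConfig:
    """A no-QTL configuration (pure noise trait 'Y') for calibration runs."""
    traits = {
        "Y": TraitModel(
            mean=0.0,
            env_effects=tuple(0.0 for _ in range(n_envs)),
            var_ge=var_ge,
            var_rep=0.001,
            var_resid=var_resid,
            qtl=(),
        )
    }
    return SimConfig(
        gmap=gmap, n_lines=n_lines, n_envs=n_envs, n_reps=n_reps,
        traits=traits, derive_shape_traits=False,
    )


# ---------------------------------------------------------------------------
# meiosis / SSD


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_lines: int,
    selfing_generations: int = 11,
    seed: int | np.random.Generator = 0,
    extra_loci: list[tuple[str, float, str]] | None = None,
) -> GenotypeMatrix:
    """Simulate RIL genotypes by SSD from an F1 of two homozygous parents.

    Parameters
    ----------
    gmap : GeneticMap
        Marker map; positions must be non-decreasing per chromosome.
    n_lines : int
        Number of independent lines (each traces back to its own F2 plant).
    selfing_generations : int
        Rounds of selfing applied to the F1 (11 -> F12).  Residual
        heterozygosity halves each round; leftover heterozygous calls are
        recorded as missing.
    seed : int or numpy Generator
        Randomness source.
    extra_loci : optional list of (chromosome, cM, name)
        Additional (QTL) loci simulated through the same meioses and
        returned as extra columns after the markers.

    Returns
    -------
    GenotypeMatrix with one row per line; marker columns in map order,
    then any extra loci in the order given.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if selfing_generations < 1:
        raise ValueError("selfing_generations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    extras = extra_loci or []
    marker_cols: dict[str, np.ndarray] = {}

    for chrom in gmap.chromosomes:
        names = gmap.chrom_markers(chrom)
        pos = list(gmap.positions(chrom))
        for (c, cm, qname) in extras:
            if c == chrom:
                names.append(qname)
                pos.append(float(cm))
        order = np.argsort(pos, kind="stable")
        names = [names[i] for i in order]
        pos_arr = np.asarray(pos, dtype=float)[order]
        d = np.diff(pos_arr)
        if (d < 0).any():
            raise ValueError("negative map distances")
        rec = haldane_recomb_prob(d)

        L = len(names)
        # haplotypes: 0 = A allele, 1 = B allele
        hap = np.zeros((n_lines, 2, L), dtype=np.int8)
        hap[:, 1, :] = 1  # F1: one full A haplotype, one full B haplotype
        for _ in range(selfing_generations):
            new = np.empty_like(hap)
            for h in range(2):
                start = rng.integers(0, 2, size=(n_lines, 1), dtype=np.int8)
                if L > 1:
                    switch = (rng.random((n_lines, L - 1)) < rec).astype(np.int8)
                    chooser = np.cumsum(
                        np.concatenate([start, switch], axis=1), axis=1
                    ) % 2
                else:
                    chooser = start
                new[:, h, :] = np.take_along_axis(
                    hap, chooser[:, None, :], axis=1
                )[:, 0, :]
            hap = new
        calls = np.where(
            hap[:, 0, :] == hap[:, 1, :],
            np.where(hap[:, 0, :] == 0, CODE_A, CODE_B),
            0,
        ).astype(np.int8)
        for j, name in enumerate(names):
            marker_cols[name] = calls[:, j]

    ordered = gmap.markers + [name for (_, _, name) in extras]
    codes = np.column_stack([marker_cols[m] for m in ordered]).astype(np.int8)
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(lines, ordered, codes)


@dataclass
class StudyData:
    """One simulated study: genotypes, causal-locus genotypes, phenotypes."""

    gmap: GeneticMap
    genotypes: GenotypeMatrix  # markers only
    qtl_genotypes: GenotypeMatrix  # planted causal loci
    phenotypes: pd.DataFrame  # long format
    config: SimConfig


def simulate_phenotypes(
    qtl_genotypes: GenotypeMatrix,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the long-format phenotype table from causal-locus calls.

    ``qtl_genotypes`` must contain one column per planted QTL named
    ``"{trait}:{chromosome}@{cM}"`` (as produced by :func:`simulate_study`).
    Setting every random variance to zero makes
    ``y = mean + sum_q a_q x_q + E_j`` exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = qtl_genotypes.n_lines
    e, r = config.n_envs, config.n_reps
    envs = config.envs

    base_values: dict[str, np.ndarray] = {}  # trait -> (n, e, r)
    for trait, model in config.traits.items():
        genetic = np.zeros(n)
        for q in model.qtl:
            col = qtl_genotypes.column(_qtl_name(trait, q))
            # internal code +1 = A; design x = +1 for the B allele
            genetic += q.effect * (-col.astype(float))
        rep_eff = rng.normal(0.0, np.sqrt(model.var_rep), size=(e, r))
        ge_eff = rng.normal(0.0, np.sqrt(model.var_ge), size=(n, e))
        resid = rng.normal(0.0, np.sqrt(model.var_resid), size=(n, e, r))
        env_eff = np.asarray(model.env_effects, dtype=float)
        y = (
            model.mean
            + genetic[:, None, None]
            + env_eff[None, :, None]
            + rep_eff[None, :, :]
            + ge_eff[:, :, None]
            + resid
        )
        base_values[trait] = y

    tables: dict[str, np.ndarray] = dict(base_values)
    if config.derive_shape_traits and {"GL", "GW"} <= set(base_values):
        derived = derive_traits(
            base_values["GL"].ravel(), base_values["GW"].ravel()
        )
        for t in ("LW", "GC", "GA", "GD", "GR"):
            tables[t] = derived[t].to_numpy().reshape(n, e, r)

    line_ids = np.asarray(qtl_genotypes.lines)
    records = []
    for trait, y in tables.items():
        li, ej, rk = np.meshgrid(
            np.arange(n), np.arange(e), np.arange(r), indexing="ij"
        )
        records.append(
            pd.DataFrame(
                {
                    "line": line_ids[li.ravel()],
                    "env": np.asarray(envs)[ej.ravel()],
                    "rep": rk.ravel() + 1,
                    "trait": trait,
                    "value": y.ravel(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def _qtl_name(trait: str, q: PlantedQTL) -> str:
    return f"{trait}:{q.chromosome}@{q.cm:g}"


def simulate_study(config: SimConfig, seed: int | np.random.Generator = 0) -> StudyData:
    """Simulate genotypes and phenotypes for a full study configuration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extra = [
        (q.chromosome, q.cm, _qtl_name(trait, q))
        for trait, q in config.planted_qtl
    ]
    # deduplicate loci shared across traits at identical positions
    seen: dict[str, tuple[str, float]] = {}
    unique_extra = []
    for c, cm, name in extra:
        if name not in seen:
            seen[name] = (c, cm)
            unique_extra.append((c, cm, name))
    full = simulate_ril_genotypes(
        config.gmap, config.n_lines, config.selfing_generations, rng,
        extra_loci=unique_extra,
    )
    markers = config.gmap.markers
    genotypes = full.subset_markers(markers)
    qtl_names = [name for (_, _, name) in unique_extra]
    qtl_genotypes = (
        full.subset_markers(qtl_names)
        if qtl_names
        else GenotypeMatrix(full.lines, [], np.zeros((full.n_lines, 0), dtype=np.int8))
    )
    phenotypes = simulate_phenotypes(qtl_genotypes, config, rng)
    return StudyData(config.gmap, genotypes, qtl_genotypes, phenotypes, config)


def distort_segregation(
    genotypes: GenotypeMatrix,
    markers: list[str],
    target_freq: float,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Resample calls at the named markers to a target A-allele frequency.

    Non-missing calls at each named marker are redrawn i.i.d. with
    P(A) = ``target_freq``; other markers and missing calls are untouched.
    Emulates the segregation distortion a fraction of markers shows in
    real biparental populations.
    """
    if not (0.0 < target_freq < 1.0):
        raise ValueError("target frequency must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = genotypes.codes.copy()
    for m in markers:
        j = genotypes.marker_index(m)
        observed = codes[:, j] != 0
        draws = np.where(
            rng.random(int(observed.sum())) < target_freq, CODE_A, CODE_B
        ).astype(np.int8)
        codes[observed, j] = draws
    return GenotypeMatrix(list(genotypes.lines), list(genotypes.markers), codes)
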