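"""Synthetic single-cell data with programmed MES/EPITH/STEM structure.

The generator emulates the statistical shape of droplet/nucleus single-cell
expression data: per-gene negative-binomial counts with a log-normal
library-size factor and Bernoulli dropout, normalized to CP10K + log1p —
the same (already normalized) representation the scoring pipeline consumes.

Two scenarios are built in:

* ``adult_tissue`` — six populations (mature and stem/precursor pairs in an
  epithelial, a skeletal-muscle and a connective lineage).  Stem populations
  get programmed log-scale shifts on the MES/EPITH panels and on their own
  organ-specific STEM panel: basal epithelium shifts MES up and EPITH down,
  while satellite and connective precursors shift both up.
* ``development`` — five pre-implantation stages (zygote through
  trophectoderm) in which MES-panel expression is non-increasing and
  EPITH-panel expression non-decreasing after the eight-cell stage.

All population differences are expressed as shifts from a single shared
baseline, so zeroing every shift makes the populations statistically
exchangeable (the null configuration used for test calibration).  Synthetic
STEM marker panels (canonical basal/satellite/stromal markers) are shipped
here because organ-specific stem panels are dataset-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model_io import CellMetadata, ExpressionMatrix, ValidationError
from .panels import DEFAULT_EPITH_GENES, DEFAULT_MES_GENES, GenePanel, default_panels

# synthetic organ-specific stem marker panels (field-standard markers)
STEM_PANEL_GENES = {
    ("epithelial", "lung"): ("TP63", "KRT5", "SOX2", "ITGA6", "NGFR"),
    ("skeletal_muscle", "muscle"): ("PAX7", "MYF5", "CD34", "VCAM1", "CALCR"),
    ("connective", "skin"): ("PDGFRA", "LEPR", "GREM1", "CXCL12"),
}

#: population -> (tissue_class, organ, truth_state)
ADULT_POPULATIONS = {
    "epithelial_mature": ("epithelial", "lung", "mature"),
    "epithelial_basal": ("epithelial", "lung", "stem"),
    "muscle_mature": ("skeletal_muscle", "muscle", "mature"),
    "muscle_satellite": ("skeletal_muscle", "muscle", "stem"),
    "connective_mature": ("connective", "skin", "mature"),
    "connective_stem": ("connective", "skin", "stem"),
}

DEVELOPMENT_STAGES = ("zygote", "four_cell", "eight_cell", "morula",
                      "blastocyst_TE")

# log-scale shifts from the shared baseline, per population.
# Stem-vs-mature contrasts: basal epithelium MES +1.0 / EPITH -0.5 /
# STEM +1.5; satellite and connective stem +0.8 on both MES and EPITH and
# STEM +1.5 relative to their mature counterparts.
ADULT_SHIFTS = {
    "epithelial_mature": {"MES": -0.7, "EPITH": 1.4, "STEM": 0.0},
    "epithelial_basal": {"MES": 0.3, "EPITH": 0.9, "STEM": 1.5},
    "muscle_mature": {"MES": 0.4, "EPITH": -0.2, "STEM": 0.0},
    "muscle_satellite": {"MES": 1.2, "EPITH": 0.6, "STEM": 1.5},
    "connective_mature": {"MES": 1.1, "EPITH": -0.9, "STEM": 0.0},
    "connective_stem": {"MES": 1.9, "EPITH": -0.1, "STEM": 1.5},
}

# MES declines and EPITH rises after the eight-cell stage
DEVELOPMENT_SHIFTS = {
    "zygote": {"MES": 1.1, "EPITH": -0.9, "STEM": 0.0},
    "four_cell": {"MES": 1.1, "EPITH": -0.9, "STEM": 0.0},
    "eight_cell": {"MES": 1.1, "EPITH": -0.2, "STEM": 0.0},
    "morula": {"MES": 0.4, "EPITH": 0.7, "STEM": 0.0},
    "blastocyst_TE": {"MES": -0.5, "EPITH": 1.4, "STEM": 0.0},
}

# shared baseline mean counts before shifts / library size
BASELINE_MES = 1.0
BASELINE_EPITH = 1.0
BASELINE_STEM = 0.3
BACKGROUND_LOG_MEAN = np.log(0.5)
BACKGROUND_LOG_SD = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation run.

    n_cells may be a single integer (every population) or a mapping
    population -> count.  ``shifts`` overrides the scenario's default
    per-population log-scale shifts; a population omitted from the override
    keeps its default.  ``theta`` is the negative-binomial dispersion
    (variance = mu + mu^2/theta), ``libsize_sigma`` the log-normal sigma of
    the per-cell library-size factor, ``dropout`` the Bernoulli zeroing
    probability.
    """

    scenario: str = "adult_tissue"
    n_cells: int | Mapping[str, int] = 500
    shifts: Mapping[str, Mapping[str, float]] | None = None
    theta: float = 10.0
    libsize_sigma: float = 0.3
    dropout: float = 0.1
    n_background_genes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("adult_tissue", "development"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.theta <= 0:
            raise ValidationError("dispersion theta must be > 0")
        if self.libsize_sigma < 0:
            raise ValidationError("libsize_sigma must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be >= 0")
        for n in self.population_sizes().values():
            if n < 1:
                raise ValidationError("population sizes must be >= 1")
        self.resolved_shifts()  # validates any shift overrides

    def populations(self) -> list[str]:
        if self.scenario == "adult_tissue":
            return list(ADULT_POPULATIONS)
        return list(DEVELOPMENT_STAGES)

    def population_sizes(self) -> dict[str, int]:
        pops = self.populations()
        if isinstance(self.n_cells, Mapping):
            missing = set(pops) - set(self.n_cells)
            if missing:
                raise ValidationError(
                    f"n_cells mapping missing populations {sorted(missing)}")
            return {p: int(self.n_cells[p]) for p in pops}
        return {p: int(self.n_cells) for p in pops}

    def resolved_shifts(self) -> dict[str, dict[str, float]]:
        defaults = (ADULT_SHIFTS if self.scenario == "adult_tissue"
                    else DEVELOPMENT_SHIFTS)
        out = {p: dict(defaults[p]) for p in self.populations()}
        for pop, override in (self.shifts or {}).items():
            if pop not in out:
                raise ValidationError(f"shift override for unknown population "
                                      f"{pop!r}")
            for cat, value in override.items():
                if cat not in ("MES", "EPITH", "STEM"):
                    raise ValidationError(f"unknown shift category {cat!r}")
                if not np.isfinite(value):
                    raise ValidationError("shift values must be finite")
                out[pop][cat] = float(value)
        return out


def null_config(base: ScenarioConfig) -> ScenarioConfig:
    """The zero-effect version of a config: every shift set to 0."""
    zeros = {p: {"MES": 0.0, "EPITH": 0.0, "STEM": 0.0}
             for p in base.populations()}
    return replace(base, shifts=zeros)


def scenario_panels(scenario: str = "adult_tissue") -> list[GenePanel]:
    """Score panels matching a scenario's genes.

    Adult tissue adds the synthetic organ-specific STEM panels to the
    default MES/EPITH panels; the development scenario uses the defaults.
    """
    panels = default_panels()
    if scenario == "adult_tissue":
        for (tissue, organ), genes in STEM_PANEL_GENES.items():
            panels.append(GenePanel(
                name=f"STEM_{tissue}_{organ}", category="STEM",
                genes=genes, key=(tissue, organ)))
    return panels


def _gene_table(config: ScenarioConfig, rng: np.random.Generator
                ) -> pd.DataFrame:
    """Gene ids, categories and baseline mean counts for one run."""
    rows: list[tuple[str, str, str, float]] = []
    for g in DEFAULT_MES_GENES:
        rows.append((g, "MES", "", BASELINE_MES))
    for g in DEFAULT_EPITH_GENES:
        rows.append((g, "EPITH", "", BASELINE_EPITH))
    if config.scenario == "adult_tissue":
        for (tissue, organ), genes in STEM_PANEL_GENES.items():
            for g in genes:
                rows.append((g, "STEM", f"{tissue}|{organ}", BASELINE_STEM))
    bg_means = np.exp(rng.normal(BACKGROUND_LOG_MEAN, BACKGROUND_LOG_SD,
                                 size=config.n_background_genes))
    for i, m in enumerate(bg_means):
        rows.append((f"BG{i + 1:04d}", "BG", "", float(m)))
    return pd.DataFrame(rows, columns=["gene", "category", "stem_key",
                                       "baseline"])


def _population_means(genes: pd.DataFrame, pop: str, shifts: dict[str, float],
                      tissue: str, organ: str) -> np.ndarray:
    mu = genes["baseline"].to_numpy(dtype=float).copy()
    log_shift = np.zeros(len(genes))
    log_shift[genes["category"] == "MES"] = shifts["MES"]
    log_shift[genes["category"] == "EPITH"] = shifts["EPITH"]
    own_stem = (genes["category"] == "STEM") & \
        (genes["stem_key"] == f"{tissue}|{organ}")
    log_shift[own_stem.to_numpy()] = shifts["STEM"]
    return mu * np.exp(log_shift)


def simulate_counts(config: ScenarioConfig
                    ) -> tuple[ExpressionMatrix, CellMetadata]:
    """Draw the raw count matrix (genes x cells) plus metadata.

    Counts are NegBin(mean = s_c * mu_{p,g}, dispersion theta) with s_c
    log-normal, then Bernoulli dropout.  Exposed separately so the noise
    model itself (mean-variance relation) can be checked on counts.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    sizes = config.population_sizes()
    shifts = config.resolved_shifts()

    blocks: list[np.ndarray] = []
    meta_rows: list[dict[str, str]] = []
    for pop in config.populations():
        n = sizes[pop]
        if config.scenario == "adult_tissue":
            tissue, organ, truth = ADULT_POPULATIONS[pop]
            stage = ""
        else:
            tissue, organ, truth = "other", "embryo", ""
            stage = pop
        mu = _population_means(genes, pop, shifts[pop], tissue, organ)
        s = (np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
             if config.libsize_sigma > 0 else np.ones(n))
        mean = np.outer(mu, s)  # genes x cells
        p = config.theta / (config.theta + mean)
        counts = rng.negative_binomial(config.theta, p).astype(float)
        if config.dropout > 0:
            keep = rng.random(mean.shape) >= config.dropout
            counts *= keep
        blocks.append(counts)
        for i in range(n):
            meta_rows.append({
                "cell_id": f"{pop}_{i + 1:05d}",
                "cell_type": pop,
                "tissue_class": tissue,
                "organ": organ,
                "embryonic_origin": "unassigned",
                "stage": stage,
                "truth_state": truth,
            })
    values = np.concatenate(blocks, axis=1)
    meta = CellMetadata(pd.DataFrame(meta_rows))
    matrix = ExpressionMatrix(list(genes["gene"]),
                              [r["cell_id"] for r in meta_rows], values)
    return matrix, meta


def cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10K library normalization followed by log(1 + x)."""
    totals = counts.sum(axis=0, keepdims=True)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    return np.log1p(counts * scale)


def simulate(config: ScenarioConfig) -> tuple[ExpressionMatrix, CellMetadata]:
    """Generate a normalized (CP10K + log1p) matrix with ground-truth labels.

    Deterministic: the same config (including seed) yields a bit-identical
    matrix.
    """
    counts, meta = simulate_counts(config)
    values = cp10k_log1p(counts.dense())
    return ExpressionMatrix(counts.gene_ids, counts.cell_ids, values), meta


def truth_report(meta: CellMetadata, config: ScenarioConfig) -> pd.DataFrame:
    """Table of populations with cell counts and programmed shifts.

    The recovery-test key: echoes what the generator programmed so analyses
    can be checked against ground truth.
    """
    shifts = config.resolved_shifts()
    counts = meta.column("cell_type").value_counts()
    rows = []
    for pop in config.populations():
        rows.append({
            "population": pop,
            "n": int(counts.get(pop, 0)),
            "mes_shift": shifts[pop]["MES"],
            "epith_shift": shifts[pop]["EPITH"],
            "stem_shift": shifts[pop]["STEM"],
        })
    return pd.DataFrame(rows).set_index("population")
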