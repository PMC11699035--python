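"""Synthetic data with planted ground truth for every pipeline stage.

Four generators:

* :func:`generate_event_cohort` — multi-sample cytometry cohorts of
  Gaussian populations *on the transformed (arcsinh) scale*, mapped back to
  the raw scale through the inverse transform so the pipeline's own
  transform step is exercised.  Emulates CD45-enriched single-cell
  suspensions: canonical archetypes (microglia, monocyte-derived
  macrophages, neutrophils, T cells), a CD45-low debris population,
  optional doublet artifacts (channel-wise sums of two events) and rare
  noncanonical spikes co-expressing myeloid and lymphoid markers.
* :func:`generate_bulk_mixtures` — bulk expression as linear mixtures of
  cell-type reference profiles with known weights; Gaussian noise is added
  on the log2 scale (the downstream analysis scale).
* :func:`generate_sc_matrix` — single-cell matrices with per-cell-type
  mean-shift expression programs for immune-gene clusters, plus planted
  mitochondrial fractions.
* :func:`generate_planted_graph` — planted-partition graphs as a
  community-detection oracle fixture.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTable
from .expression import ExpressionMatrix
from .graph import KnnGraph

__all__ = [
    "PopulationSpec",
    "SyntheticCohortConfig",
    "SyntheticBulkConfig",
    "SyntheticSCConfig",
    "generate_event_cohort",
    "generate_bulk_mixtures",
    "generate_sc_matrix",
    "generate_planted_graph",
    "default_panel",
    "default_populations",
    "default_cohort_config",
    "make_reference_profiles",
    "default_sc_config",
    "write_cohort",
]

DEFAULT_COFACTOR = 150.0  # arcsinh cofactor of the fluorescence-mode transform


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian population in transformed marker space."""

    name: str
    mean_by_channel: dict
    sd_by_channel: dict
    fraction: float
    is_debris: bool = False
    truth_label: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0,1], got {self.fraction}")
        for ch, sd in self.sd_by_channel.items():
            if sd <= 0:
                raise ValueError(f"sd for channel {ch} must be > 0")
        if self.truth_label is None:
            object.__setattr__(self, "truth_label", self.name)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort layout: samples, panel, doublet rate, seed.

    ``samples`` is a list of ``(sample_id, n_events, fraction_overrides)``
    where ``fraction_overrides`` maps population name to fraction; the
    overridden fractions of each sample must sum to 1.
    """

    samples: list
    panel: tuple
    doublet_rate: float = 0.0
    seed: int = 0
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self):
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("channel names must be unique")
        if not 0.0 <= self.doublet_rate <= 0.2:
            raise ValueError("doublet_rate must lie in [0, 0.2]")
        for sid, n_events, _ in self.samples:
            if n_events < 1:
                raise ValueError(f"sample {sid}: n_events must be >= 1")


def _sample_fractions(populations, overrides):
    fracs = {p.name: p.fraction for p in populations}
    if overrides:
        unknown = set(overrides) - set(fracs)
        if unknown:
            raise ValueError(f"fraction overrides for unknown populations {sorted(unknown)}")
        fracs.update(overrides)
    total = sum(fracs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total}, expected 1")
    return fracs


def generate_event_cohort(config: SyntheticCohortConfig, populations: list[PopulationSpec]):
    """Generate one EventTable per sample, with per-event truth labels.

    Events are drawn per population from independent per-channel Gaussians
    on the arcsinh scale, then mapped through ``sinh(z) * cofactor`` to the
    raw scale.  Doublets (``doublet_rate`` of each sample's events) replace
    singlet draws with the channel-wise sum of two parent events and are
    truth-labeled ``"doublet"``; parent indices are stored on the table as
    ``doublet_parents`` for auditability.
    """
    for p in populations:
        unknown = set(p.mean_by_channel) - set(config.panel)
        if unknown:
            raise ValueError(
                f"population {p.name}: unknown channels {sorted(unknown)}"
            )
    _sample_fractions(populations, None)  # validates base fractions

    rng = np.random.default_rng(config.seed)
    tables = []
    for sample_id, n_events, overrides in config.samples:
        fracs = _sample_fractions(populations, overrides)
        names = [p.name for p in populations]
        counts = rng.multinomial(n_events, [fracs[n] for n in names])
        zs, labels = [], []
        for p, c in zip(populations, counts):
            if c == 0:
                continue
            mean = np.array([p.mean_by_channel.get(ch, 0.0) for ch in config.panel])
            sd = np.array([p.sd_by_channel.get(ch, 0.3) for ch in config.panel])
            zs.append(rng.normal(mean, sd, size=(c, len(config.panel))))
            labels.extend([p.truth_label] * c)
        Z = np.vstack(zs)
        labels = np.asarray(labels, dtype=object)
        perm = rng.permutation(len(Z))
        Z = Z[perm]
        labels = labels[perm]
        raw = np.sinh(Z) * config.cofactor

        doublet_parents = None
        n_doublets = int(round(config.doublet_rate * n_events))
        if n_doublets > 0:
            targets = rng.choice(n_events, size=n_doublets, replace=False)
            singlets = np.setdiff1d(np.arange(n_events), targets)
            parents = rng.choice(singlets, size=(n_doublets, 2))
            raw[targets] = raw[parents[:, 0]] + raw[parents[:, 1]]
            labels[targets] = "doublet"
            doublet_parents = {int(t): (int(a), int(b)) for t, (a, b) in zip(targets, parents)}

        table = EventTable(
            sample_id=sample_id,
            data=pd.DataFrame(raw, columns=list(config.panel)),
            truth_labels=labels,
        )
        table.doublet_parents = doublet_parents
        tables.append(table)
    return tables


@dataclass(frozen=True)
class SyntheticBulkConfig:
    """Bulk mixtures: nonnegative reference profiles, mixing weights, noise."""

    reference_profiles: pd.DataFrame  # genes x cell types, linear scale
    mixing_weights: pd.DataFrame  # samples x cell types
    noise_sd: float = 0.1  # on the log2 scale
    seed: int = 0

    def __post_init__(self):
        if (self.reference_profiles.to_numpy() < 0).any():
            raise ValueError("reference profiles must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if list(self.mixing_weights.columns) != list(self.reference_profiles.columns):
            raise ValueError("mixing weight columns must match reference cell types")
        W = self.mixing_weights.to_numpy()
        if (W < 0).any():
            raise ValueError("mixing weights must be >= 0")
        sums = W.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("each sample's mixing weights must sum to 1")


def generate_bulk_mixtures(config: SyntheticBulkConfig) -> ExpressionMatrix:
    """Per-sample expression = weights . profiles (linear scale), then
    Gaussian noise of sd ``noise_sd`` added after log2(x + 1).

    The returned matrix is on the log2 scale with the truth weights attached
    as ``truth_weights``.
    """
    P = config.reference_profiles.to_numpy(dtype=float)  # genes x types
    W = config.mixing_weights.to_numpy(dtype=float)  # samples x types
    linear = P @ W.T  # genes x samples
    rng = np.random.default_rng(config.seed)
    values = np.log2(linear + 1.0)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    data = pd.DataFrame(
        values,
        index=config.reference_profiles.index,
        columns=config.mixing_weights.index,
    )
    m = ExpressionMatrix(data=data, norm_state=("log2",))
    m.truth_weights = config.mixing_weights.copy()
    return m


@dataclass(frozen=True)
class SyntheticSCConfig:
    """Single-cell matrix layout.

    ``cell_types`` maps type name to cell count; ``programs`` maps gene
    cluster name to ``(up_types, shift)`` where ``up_types`` lists the cell
    types in which the program's genes are mean-shifted upward by ``shift``
    on the working (log-normalized-like) scale.  ``genes_per_program`` genes
    are created per program plus ``n_background_genes`` background genes and
    five ``MT-`` mitochondrial genes whose per-cell totals realize a
    fraction drawn uniformly from ``mito_fraction_range``.
    """

    cell_types: dict
    programs: dict
    genes_per_program: int = 30
    n_background_genes: int = 500
    baseline_mean: float = 1.0
    baseline_sd: float = 0.5
    mito_fraction_range: tuple = (0.005, 0.04)
    seed: int = 0

    def __post_init__(self):
        for t, c in self.cell_types.items():
            if c < 1:
                raise ValueError(f"cell count for {t} must be >= 1")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must be an interval within [0, 1]")
        for name, (types, shift) in self.programs.items():
            if not np.isfinite(shift):
                raise ValueError(f"program {name}: shift must be finite")
            unknown = set(types) - set(self.cell_types)
            if unknown:
                raise ValueError(f"program {name}: unknown cell types {sorted(unknown)}")


def generate_sc_matrix(config: SyntheticSCConfig):
    """Generate a genes x cells matrix, cell-type labels, mito fractions
    and the planted gene-cluster membership.

    Returns ``(matrix, cell_types, mito_fractions, gene_clusters)`` where
    ``matrix`` is an :class:`ExpressionMatrix` (working scale), the two
    Series are indexed by cell id, and ``gene_clusters`` maps program name
    to its gene list.
    """
    rng = np.random.default_rng(config.seed)
    cells = []
    types = []
    for t, c in config.cell_types.items():
        ids = [f"{t}_{i}" for i in range(c)]
        cells.extend(ids)
        types.extend([t] * c)
    type_arr = np.asarray(types)
    n_cells = len(cells)

    gene_clusters = {}
    gene_names = []
    for name in config.programs:
        genes = [f"{name}_g{i}" for i in range(config.genes_per_program)]
        gene_clusters[name] = genes
        gene_names.extend(genes)
    gene_names.extend(f"BG_g{i}" for i in range(config.n_background_genes))
    mito_genes = [f"MT-{i}" for i in range(5)]

    X = rng.normal(
        config.baseline_mean, config.baseline_sd, size=(len(gene_names), n_cells)
    )
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for name, (up_types, shift) in config.programs.items():
        rows = [gene_index[g] for g in gene_clusters[name]]
        col_mask = np.isin(type_arr, list(up_types))
        X[np.ix_(rows, col_mask)] += shift

    lo, hi = config.mito_fraction_range
    mito_frac = rng.uniform(lo, hi, size=n_cells)
    nonmito_sum = np.clip(X, 0.0, None).sum(axis=0)
    mito_total = mito_frac / (1.0 - mito_frac) * nonmito_sum
    M = np.tile(mito_total / len(mito_genes), (len(mito_genes), 1))

    data = pd.DataFrame(
        np.vstack([X, M]), index=gene_names + mito_genes, columns=cells
    )
    # the working scale emulates log-normalized expression (may dip negative)
    matrix = ExpressionMatrix(data=data, norm_state=("log2",))
    return (
        matrix,
        pd.Series(type_arr, index=cells, name="cell_type"),
        pd.Series(mito_frac, index=cells, name="mito_fraction"),
        gene_clusters,
    )


def generate_planted_graph(
    n_communities: int, size: int, p_in: float, p_out: float, seed: int = 0
):
    """Planted-partition graph; returns ``(KnnGraph, labels)``.

    Within-community edges appear with probability ``p_in``, between-
    community edges with ``p_out``; requires ``0 <= p_out < p_in <= 1``.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError(f"require 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    n = n_communities * size
    labels = np.repeat(np.arange(n_communities), size)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    mask = rng.random(len(p)) < p
    edges = np.stack([iu[mask], ju[mask]], axis=1)
    graph = KnnGraph(
        n_nodes=n, k=0, edges=edges, weights=np.ones(len(edges))
    )
    return graph, labels


# ---------------------------------------------------------------------------
# Default study conditions

def default_panel():
    """Default fluorescence panel: lineage markers, size/granularity
    proxies, and the viability stain (a separate clustering dimension;
    dead cells and debris take up the stain)."""
    return (
        "CD45", "CD3", "CD4", "CD8", "CD14", "CD19", "CD66b",
        "FSC_A", "SSC_A", "Viability",
    )


def _pop(name, fraction, is_debris=False, **means):
    sd = {ch: 0.3 for ch in default_panel()}
    mean = {ch: 0.4 for ch in default_panel()}
    mean.update(means)
    return PopulationSpec(
        name=name,
        mean_by_channel=mean,
        sd_by_channel=sd,
        fraction=fraction,
        is_debris=is_debris,
    )


def default_populations():
    """Default CD45-enriched tumor-suspension archetypes.

    Means are on the arcsinh display scale (cofactor 150); populations are
    separated by several SD on their defining markers.  The archetype set
    mirrors the phenotype granularity reported for brain-tumor immune
    infiltrates: microglia occur as two subpopulations (homeostatic and
    activated, differing in CD45/CD14 intensity and size/granularity),
    T cells as distinct CD4+ and CD8+ subsets, plus monocyte-derived
    macrophages, neutrophils, a CD45-low viability-stain-high debris
    population, and a rare (2%) noncanonical CD3+CD14+CD66b+ myeloid
    spike.  Base fractions are the cohort-wide averages; per-sample
    composition is varied by :func:`default_cohort_config`.
    """
    return [
        _pop("mg_homeostatic", 0.14, CD45=2.3, CD14=3.8, FSC_A=3.3, SSC_A=2.8),
        _pop("mg_activated", 0.10, CD45=3.0, CD14=4.6, FSC_A=4.0, SSC_A=3.6),
        _pop("mdm", 0.19, CD45=4.5, CD14=4.4, CD66b=0.5, FSC_A=3.8, SSC_A=3.2),
        _pop("neutrophil", 0.20, CD45=4.0, CD66b=4.5, CD14=1.5, FSC_A=3.2, SSC_A=4.5),
        _pop("t_cd4", 0.12, CD45=4.6, CD3=4.5, CD4=3.5, CD8=0.4, FSC_A=2.5, SSC_A=1.5),
        _pop("t_cd8", 0.08, CD45=4.6, CD3=4.5, CD4=0.4, CD8=3.5, FSC_A=2.5, SSC_A=1.5),
        _pop("debris", 0.15, is_debris=True, CD45=0.15, CD3=0.2, CD4=0.2, CD8=0.2,
             CD14=0.3, CD19=0.2, CD66b=0.3, FSC_A=1.5, SSC_A=1.2, Viability=2.5),
        _pop("cd3_myeloid", 0.02, CD45=4.2, CD3=4.3, CD14=4.0, CD66b=4.2,
             FSC_A=3.6, SSC_A=3.4),
    ]


# Per-sample immune compositions loosely mirroring reported tumor-type
# gradients: a microglia-dominated low-grade-like sample, three
# infiltration-dominated samples, and a lymphocyte-rich sample.  Debris
# (0.15) and the noncanonical spike (0.02) are constant across samples.
_DEFAULT_SAMPLE_FRACTIONS = {
    "S1": {"mg_homeostatic": 0.36, "mg_activated": 0.22, "mdm": 0.06,
           "neutrophil": 0.06, "t_cd4": 0.08, "t_cd8": 0.05},
    "S2": {"mg_homeostatic": 0.12, "mg_activated": 0.08, "mdm": 0.22,
           "neutrophil": 0.28, "t_cd4": 0.08, "t_cd8": 0.05},
    "S3": {"mg_homeostatic": 0.10, "mg_activated": 0.06, "mdm": 0.24,
           "neutrophil": 0.26, "t_cd4": 0.09, "t_cd8": 0.08},
    "S4": {"mg_homeostatic": 0.08, "mg_activated": 0.05, "mdm": 0.22,
           "neutrophil": 0.11, "t_cd4": 0.19, "t_cd8": 0.18},
    "S5": {"mg_homeostatic": 0.10, "mg_activated": 0.07, "mdm": 0.20,
           "neutrophil": 0.30, "t_cd4": 0.10, "t_cd8": 0.06},
}


def default_cohort_config(
    n_samples: int = 5, n_events: int = 5000, doublet_rate: float = 0.0, seed: int = 0
) -> SyntheticCohortConfig:
    """Default cohort: 5 samples x 5,000 events with per-sample
    composition differences (required for sample-correlation analyses)."""
    ids = list(_DEFAULT_SAMPLE_FRACTIONS)
    samples = []
    for i in range(n_samples):
        sid = ids[i % len(ids)]
        overrides = dict(_DEFAULT_SAMPLE_FRACTIONS[sid])
        samples.append((f"S{i + 1}", n_events, overrides))
    return SyntheticCohortConfig(
        samples=samples, panel=default_panel(), doublet_rate=doublet_rate, seed=seed
    )


def make_reference_profiles(
    cell_types=("CD45neg", "MG", "MDM", "neutrophil", "T_CD4", "T_CD8"),
    n_genes: int = 300,
    markers_per_type: int = 30,
    marker_boost: float = 16.0,
    seed: int = 0,
):
    """Synthetic cell-type reference profiles and matching gene clusters.

    Each type gets ``markers_per_type`` marker genes boosted
    ``marker_boost``-fold over a shared lognormal baseline (linear,
    TPM-like units).  Returns ``(profiles, gene_clusters)``: the profiles a
    genes x types DataFrame, and one immune gene cluster per cell type
    consisting of its marker genes.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, len(cell_types)))
    profiles = pd.DataFrame(base, index=genes, columns=list(cell_types))
    clusters = {}
    for t_idx, t in enumerate(cell_types):
        lo = t_idx * markers_per_type
        hi = lo + markers_per_type
        if hi > n_genes:
            raise ValueError("not enough genes for the requested marker blocks")
        profiles.iloc[lo:hi, t_idx] *= marker_boost
        clusters[f"IC{t_idx + 1}"] = genes[lo:hi]
    return profiles, clusters


def default_sc_config(seed: int = 0) -> SyntheticSCConfig:
    """Default single-cell conditions: 3,000 cells over five types, one
    up-shifted program per major type (shift +2 on the working scale)."""
    return SyntheticSCConfig(
        cell_types={
            "cancer": 1000,
            "myeloid": 800,
            "t_lymphocyte": 600,
            "dendritic": 350,
            "plasmablast": 250,
        },
        programs={
            "IC1": (("myeloid",), 2.0),
            "IC2": (("cancer",), 2.0),
            "IC3": (("t_lymphocyte",), 2.0),
            "IC4": (("plasmablast",), 2.0),
            "IC5": (("dendritic",), 2.0),
        },
        seed=seed,
    )


def write_cohort(tables: list[EventTable], out_dir, seed: int | None = None, fcs: bool = False):
    """Write a cohort as one CSV per sample, truth labels, and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"samples": [], "seed": seed, "panel": None}
    for t in tables:
        csv_path = out_dir / f"{t.sample_id}.csv"
        t.data.to_csv(csv_path, index=False)
        entry = {"sample_id": t.sample_id, "events": csv_path.name, "n_events": t.n_events}
        if t.truth_labels is not None:
            truth_path = out_dir / f"{t.sample_id}.truth.tsv"
            pd.Series(t.truth_labels, name="truth_label").to_csv(
                truth_path, sep="\t", index_label="event"
            )
            entry["truth_labels"] = truth_path.name
        if fcs:
            from .fcs import write_fcs

            fcs_path = out_dir / f"{t.sample_id}.fcs"
            write_fcs(fcs_path, t.channels, t.values())
            entry["fcs"] = fcs_path.name
        manifest["samples"].append(entry)
        manifest["panel"] = t.channels
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"
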