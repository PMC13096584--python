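"""Synthetic liver-lobule data with known ground truth.

Two generators feed the downstream analyses:

``simulate_spatial``
    Spot-level data on a rectangular grid.  A latent zonation coordinate
    ``z`` in [0, 1] (0 = pericentral / central vein, 1 = periportal /
    portal vein) varies as a smooth sinusoid across grid columns with at
    least two full periods, so every sample spans both zones — the same
    statistical structure a field of lobules produces once space is
    collapsed to score quantiles.  Pericentral (CV) marker genes have
    negative-binomial counts with mean ``base * exp(-beta * z)``,
    periportal (PV) markers ``base * exp(+beta * z)``, background genes a
    constant mean.  Per-type spatial abundance surfaces are logistic in
    ``z`` (``pv_graded`` increasing, ``cv_graded`` decreasing, ``flat``
    constant) scaled by a per-group amplitude; the observed abundance
    matrix adds multiplicative gamma noise (10% coefficient of variation)
    standing in for deconvolution uncertainty.

``simulate_single_cell``
    Two-group (young / old) cell-level data.  Cells are drawn per group
    with a multinomial cell-type composition; each type has its own set
    of elevated marker genes; designated effect genes are shifted by a
    configured log2 fold in old-group cells of one type.

All randomness flows from ``cfg.seed`` through a single
``numpy.random.Generator``; identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import CountMatrix

__all__ = [
    "CellTypeSpec",
    "GroupSpec",
    "SynthConfig",
    "SynthTruth",
    "simulate_spatial",
    "simulate_single_cell",
]

PROFILES = ("pv_graded", "cv_graded", "flat")
LOGISTIC_SLOPE = 8.0  # steepness of the abundance gradient in z
ABUNDANCE_NOISE_CV = 0.10


@dataclass
class CellTypeSpec:
    """Spatial abundance profile of one cell type.

    ``profile`` may be a single profile name or a per-group mapping
    (e.g. ``{"young": "flat", "old": "pv_graded"}``) for types whose
    zonation is group-dependent.
    """

    name: str
    profile: str | dict[str, str] = "flat"
    amplitude: dict[str, float] = field(default_factory=lambda: {"young": 1.0, "old": 1.0})

    def __post_init__(self) -> None:
        profiles = (self.profile.values() if isinstance(self.profile, dict)
                    else [self.profile])
        for p in profiles:
            if p not in PROFILES:
                raise ValueError(f"profile must be one of {PROFILES}, got {p!r}")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError(f"amplitudes must be >= 0 for type {self.name!r}")

    def profile_for(self, group: str) -> str:
        if isinstance(self.profile, dict):
            return self.profile.get(group, "flat")
        return self.profile


@dataclass
class GroupSpec:
    """Single-cell composition and expression effects for one group."""

    composition: dict[str, float]
    # cell_type -> {gene_id: log2 fold shift applied in this group}
    effect_genes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1 (got {total!r})")


@dataclass
class SynthConfig:
    n_spots: int = 2000
    grid_shape: tuple[int, int] = (40, 50)
    n_genes: int = 1000
    n_cv_markers: int = 30
    n_pv_markers: int = 30
    zonation_beta: float = 1.0
    nb_dispersion: float = 10.0     # NB size parameter; var = mu + mu^2 / size
    base_mean: float = 20.0
    samples: dict[str, str] = field(
        default_factory=lambda: {"Y1": "young", "Y2": "young", "O1": "old", "O2": "old"}
    )
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("Tex", {"young": "flat", "old": "pv_graded"},
                         {"young": 0.2, "old": 1.0}),
            CellTypeSpec("PP_hepatocyte", "pv_graded", {"young": 1.0, "old": 1.0}),
            CellTypeSpec("PC_hepatocyte", "cv_graded", {"young": 1.0, "old": 1.0}),
            CellTypeSpec("Kupffer", "flat", {"young": 1.0, "old": 1.0}),
        ]
    )
    # single-cell block
    sc_n_cells_per_group: int = 2000
    sc_groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "young": GroupSpec({"T": 0.25, "B": 0.25, "NK": 0.25, "Mac": 0.25}),
            "old": GroupSpec({"T": 0.25, "B": 0.25, "NK": 0.25, "Mac": 0.25}),
        }
    )
    sc_markers_per_type: int = 5
    sc_marker_log2fc: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] * self.grid_shape[1] < self.n_spots:
            raise ValueError(
                f"grid {self.grid_shape} holds {self.grid_shape[0] * self.grid_shape[1]} "
                f"spots, fewer than requested n_spots={self.n_spots}"
            )
        if self.n_cv_markers + self.n_pv_markers > self.n_genes:
            raise ValueError("marker genes exceed n_genes")
        groups = set(self.sc_groups)
        if groups and groups != {"young", "old"}:
            raise ValueError("sc_groups must define exactly 'young' and 'old'")


@dataclass
class SynthTruth:
    """Serializable ground truth sufficient to check every downstream stage."""

    z: pd.Series | None = None                  # spot -> latent zonation coordinate
    true_abundance: pd.DataFrame | None = None  # spots x cell types, noise-free
    cv_markers: list[str] = field(default_factory=list)
    pv_markers: list[str] = field(default_factory=list)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)  # sc type markers
    true_effect_genes: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    group_compositions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "z": None if self.z is None else self.z.to_dict(),
            "true_abundance": None if self.true_abundance is None
            else self.true_abundance.to_dict(orient="index"),
            "cv_markers": self.cv_markers,
            "pv_markers": self.pv_markers,
            "marker_genes": self.marker_genes,
            "true_effect_genes": self.true_effect_genes,
            "group_compositions": self.group_compositions,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            z=None if d["z"] is None else pd.Series(d["z"], name="z"),
            true_abundance=None if d["true_abundance"] is None
            else pd.DataFrame.from_dict(d["true_abundance"], orient="index"),
            cv_markers=d["cv_markers"],
            pv_markers=d["pv_markers"],
            marker_genes=d["marker_genes"],
            true_effect_genes=d["true_effect_genes"],
            group_compositions=d["group_compositions"],
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=size_param, scale=np.maximum(mean, 1e-12) / size_param)
    return rng.poisson(np.where(mean > 0, lam, 0.0))


def _abundance_profile(profile: str, z: np.ndarray) -> np.ndarray:
    if profile == "pv_graded":
        return 1.0 / (1.0 + np.exp(-(z - 0.5) * LOGISTIC_SLOPE))
    if profile == "cv_graded":
        return 1.0 / (1.0 + np.exp((z - 0.5) * LOGISTIC_SLOPE))
    return np.ones_like(z)


def _gene_names(cfg: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    cv = [f"cvmk{i}" for i in range(cfg.n_cv_markers)]
    pv = [f"pvmk{i}" for i in range(cfg.n_pv_markers)]
    n_bg = cfg.n_genes - len(cv) - len(pv)
    bg = [f"gene{i}" for i in range(n_bg)]
    return cv, pv, bg


def simulate_spatial(cfg: SynthConfig):
    """Generate spot counts, metadata, an observed abundance matrix and truth.

    Returns ``(CountMatrix, ObsMeta DataFrame, AbundanceMatrix DataFrame,
    SynthTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    n_per_sample = cfg.n_spots // len(cfg.samples)
    extra = cfg.n_spots - n_per_sample * len(cfg.samples)

    cv_names, pv_names, bg_names = _gene_names(cfg)
    gene_ids = cv_names + pv_names + bg_names
    bg_means = rng.uniform(0.5, 2.0, size=len(bg_names)) * cfg.base_mean

    obs_rows, counts_blocks, ab_blocks, truth_ab_blocks, z_all = [], [], [], [], []
    type_names = [t.name for t in cfg.cell_types]

    for si, (sample, group) in enumerate(cfg.samples.items()):
        n_s = n_per_sample + (1 if si < extra else 0)
        flat = np.arange(rows * cols)
        pos = flat[:n_s]
        x = pos % cols
        y = pos // cols
        # smooth sinusoidal zonation field, >= 2 full periods across columns
        z = 0.5 * (1.0 - np.cos(2.0 * np.pi * 2.0 * x / cols))
        obs_ids = [f"{sample}_spot{i}" for i in range(n_s)]

        mu = np.empty((n_s, cfg.n_genes))
        mu[:, : len(cv_names)] = cfg.base_mean * np.exp(-cfg.zonation_beta * z)[:, None]
        mu[:, len(cv_names): len(cv_names) + len(pv_names)] = (
            cfg.base_mean * np.exp(cfg.zonation_beta * z)[:, None]
        )
        mu[:, len(cv_names) + len(pv_names):] = bg_means[None, :]
        counts_blocks.append(_nb_draw(rng, mu, cfg.nb_dispersion))

        truth_ab = np.column_stack([
            spec.amplitude.get(group, 0.0) * _abundance_profile(spec.profile_for(group), z)
            for spec in cfg.cell_types
        ])
        noise = rng.gamma(shape=1.0 / ABUNDANCE_NOISE_CV**2,
                          scale=ABUNDANCE_NOISE_CV**2, size=truth_ab.shape)
        truth_ab_blocks.append(truth_ab)
        ab_blocks.append(truth_ab * noise)
        z_all.append(pd.Series(z, index=obs_ids, name="z"))
        obs_rows.append(pd.DataFrame({
            "obs_id": obs_ids, "sample_id": sample, "group": group, "x": x, "y": y,
        }))

    meta = pd.concat(obs_rows, ignore_index=True)
    counts = CountMatrix(meta["obs_id"], gene_ids, np.vstack(counts_blocks))
    z_series = pd.concat(z_all)
    abundance = pd.DataFrame(np.vstack(ab_blocks), index=pd.Index(meta["obs_id"], name="obs_id"),
                             columns=type_names)
    truth = SynthTruth(
        z=z_series,
        true_abundance=pd.DataFrame(np.vstack(truth_ab_blocks),
                                    index=abundance.index.copy(), columns=type_names),
        cv_markers=cv_names,
        pv_markers=pv_names,
        group_compositions={},
    )
    return counts, meta, abundance, truth


def simulate_single_cell(cfg: SynthConfig):
    """Generate two-group cell-level counts with known composition and effects.

    Returns ``(CountMatrix, ObsMeta DataFrame, SynthTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    types = sorted({t for g in cfg.sc_groups.values() for t in g.composition})
    gene_ids = [f"gene{i}" for i in range(cfg.n_genes)]
    base_means = rng.uniform(0.5, 2.0, size=cfg.n_genes) * cfg.base_mean

    # disjoint per-type marker genes carved from the gene pool
    marker_map: dict[str, list[str]] = {}
    cursor = 0
    for t in types:
        marker_map[t] = gene_ids[cursor: cursor + cfg.sc_markers_per_type]
        cursor += cfg.sc_markers_per_type
    if cursor > cfg.n_genes:
        raise ValueError("not enough genes for per-type markers")

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for group, spec in cfg.sc_groups.items():
        for t, genes in spec.effect_genes.items():
            unknown = [g for g in genes if g not in gene_pos]
            if unknown:
                raise ValueError(
                    f"effect genes for type {t!r} in group {group!r} not in the "
                    f"gene universe: {unknown[:5]}"
                )
    obs_rows, counts_blocks = [], []
    for group in ("young", "old"):
        spec = cfg.sc_groups[group]
        comp = np.array([spec.composition.get(t, 0.0) for t in types])
        n_per_type = rng.multinomial(cfg.sc_n_cells_per_group, comp)
        for t, n_t in zip(types, n_per_type):
            if n_t == 0:
                continue
            mu = base_means.copy()
            for g in marker_map[t]:
                mu[gene_pos[g]] *= 2.0 ** cfg.sc_marker_log2fc
            for g, lfc in spec.effect_genes.get(t, {}).items():
                mu[gene_pos[g]] *= 2.0 ** lfc
            counts_blocks.append(_nb_draw(rng, np.tile(mu, (n_t, 1)), cfg.nb_dispersion))
            obs_rows.append(pd.DataFrame({
                "obs_id": [f"{group}_{t}_{i}" for i in range(n_t)],
                "sample_id": f"{group}_s1", "group": group, "cell_type": t,
            }))

    meta = pd.concat(obs_rows, ignore_index=True)
    counts = CountMatrix(meta["obs_id"], gene_ids, np.vstack(counts_blocks))
    truth = SynthTruth(
        marker_genes=marker_map,
        true_effect_genes={g: dict(spec.effect_genes)
                           for g, spec in cfg.sc_groups.items()},
        group_compositions={g: dict(spec.composition)
                            for g, spec in cfg.sc_groups.items()},
    )
    return counts, meta, truth
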