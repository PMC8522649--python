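"""Synthetic cohorts, expression matrices, DE datasets and cell-type profiles.

Every generator plants known structure and returns it as a truth object so
downstream stages can be tested for recovery without any external data.

Construction of the cohort: all subjects share a latent regions x features
profile in which a majority "community" of regions loads on a common
feature pattern while the rest are idiosyncratic; community members
therefore have positive weighted degree (regional MS) once features are
z-scored within subject. Group effects act on the correlation structure,
not on means: decreased-MS regions receive extra region-specific noise in
cases (decorrelating them from the community), increased-MS regions get
their noise shrunk toward the latent profile (tightening the correlation).
Default effect regions are the community members with the strongest
baseline weighted degree, alternating down/up, so both effect signs are
recoverable.

All randomness flows from a single seed through named substreams
(``SeedSequence(seed, spawn_key=(stage,))``), so each stage can be
regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mstrans import morphometry
from mstrans.morphometry import (
    FEATURE_NAMES,
    GROUP_CASE,
    GROUP_CONTROL,
    SubjectFeatureTable,
)

CELL_TYPES = ("astrocytes", "neurons", "oligodendrocytes", "microglia")

# substream ids for the seed-splitting scheme
_STAGES = {
    "latent": 0,
    "cohort": 1,
    "memory": 2,
    "expression": 3,
    "de": 4,
    "celltype": 5,
}

# latent-profile geometry (see module docstring); tuned so effect_size=1.5
# yields Cohen's d near 1 on the planted regions
_RANK = 4
_COMM_FRAC = 0.7  # fraction of regions in the correlated community
_COMM_RESID = 0.5  # idiosyncratic low-rank admixture within the community
_SIGMA0 = 0.6  # baseline feature-noise sd
_DOWN_NOISE = 3.5  # case down-region noise variance grows by this * effect
_UP_SHRINK = 5.0  # case up-region noise variance shrinks by this * effect


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for a named generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


def region_ids(n_regions: int, n_left: int) -> np.ndarray:
    """Synthetic atlas ids: left-hemisphere regions first."""
    ids = [
        f"L{i:03d}" if i < n_left else f"R{i - n_left:03d}"
        for i in range(n_regions)
    ]
    return np.asarray(ids)


def gene_symbols(n_genes: int) -> np.ndarray:
    return np.asarray([f"G{i:05d}" for i in range(n_genes)])


@dataclass
class SimulationConfig:
    """Knobs for every synthetic input kind. Counts must be positive."""

    n_per_group: int = 50
    n_regions: int = 308
    n_left_regions: int = 151
    n_features: int = 7
    n_genes: int = 2000
    effect_regions_down: list | None = None
    effect_regions_up: list | None = None
    n_effect_down: int = 10
    n_effect_up: int = 9
    effect_size: float = 1.0
    n_batches: int = 1
    batch_shift: list | None = None
    batch_scale: list | None = None
    coupling_strength: float = 0.8
    coupled_frac_pos: float = 0.05
    coupled_frac_neg: float = 0.05
    memory_coupling: float = 0.5
    n_de_samples: int = 20
    de_frac_up: float = 0.05
    de_frac_down: float = 0.05
    de_lfc: float = 2.0
    de_noise_sd: float = 0.5
    celltype_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_per_group",
            "n_regions",
            "n_left_regions",
            "n_features",
            "n_genes",
            "n_batches",
            "n_de_samples",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_features != len(FEATURE_NAMES):
            raise ValueError(
                f"n_features must be {len(FEATURE_NAMES)} "
                f"(the fixed feature vocabulary)"
            )
        if self.n_left_regions > self.n_regions:
            raise ValueError("n_left_regions cannot exceed n_regions")
        if not -1.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [-1, 1]")
        down = self.effect_regions_down or []
        up = self.effect_regions_up or []
        if set(down) & set(up):
            raise ValueError("effect region lists must be disjoint")

    def explicit_effect_indices(
        self,
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """User-specified planted region indices, validated; None if unset."""
        if self.effect_regions_down is None and self.effect_regions_up is None:
            return None
        ids = region_ids(self.n_regions, self.n_left_regions)
        lookup = {r: i for i, r in enumerate(ids)}

        def _to_idx(lst):
            out = []
            for r in lst:
                if isinstance(r, (int, np.integer)):
                    if not 0 <= r < self.n_regions:
                        raise ValueError(f"effect region index {r} out of range")
                    out.append(int(r))
                else:
                    if r not in lookup:
                        raise ValueError(f"unknown effect region id {r!r}")
                    out.append(lookup[r])
            return np.asarray(out, dtype=int)

        return (
            _to_idx(self.effect_regions_down or []),
            _to_idx(self.effect_regions_up or []),
        )


@dataclass
class CohortTruth:
    """Planted structure behind a synthetic cohort."""

    region_effect: pd.Series  # -1 (down), 0, +1 (up) per region id
    down_regions: np.ndarray
    up_regions: np.ndarray
    batch_shift: np.ndarray
    batch_scale: np.ndarray
    memory_coupling: float
    clean_mean_ms_down: pd.Series = field(default=None)  # per-subject


@dataclass
class ExpressionTruth:
    gene_coupling: pd.Series  # +1 / -1 / 0 per gene


@dataclass
class DETruth:
    de_label: pd.Series  # up / down / ns per gene


@dataclass
class CellTypeTruth:
    celltype_label: pd.Series  # cell-type name or "" per gene


def _latent_profile(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent regions x features profile and the community member indices."""
    rng = stage_rng(config.seed, "latent")
    R, F = config.n_regions, config.n_features
    A = rng.standard_normal((R, _RANK))
    B = rng.standard_normal((_RANK, F)) / np.sqrt(_RANK)
    low = A @ B
    comm = rng.choice(R, max(2, int(_COMM_FRAC * R)), replace=False)
    h = rng.standard_normal(F)
    w = rng.uniform(0.75, 1.25, size=len(comm))
    L = low.copy()
    L[comm] = np.outer(w, h) + _COMM_RESID * low[comm]
    return L, comm


def _latent_weighted_degree(L: np.ndarray) -> np.ndarray:
    """Noise-free regional MS of the latent profile (sign/rank reference)."""
    z = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
    c = np.corrcoef(z)
    np.fill_diagonal(c, np.nan)
    return np.nanmean(c, axis=1)


def _default_effect_regions(
    config: SimulationConfig, L: np.ndarray, comm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Strongest-degree community regions, alternating down/up."""
    m = _latent_weighted_degree(L)
    order = comm[np.argsort(-m[comm])]
    n_total = config.n_effect_down + config.n_effect_up
    if n_total > len(order):
        raise ValueError("more effect regions requested than community size")
    top = order[:n_total]
    return top[0::2][: config.n_effect_down], np.asarray(
        [r for r in top if r not in set(top[0::2][: config.n_effect_down])]
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[SubjectFeatureTable, CohortTruth]:
    """Simulate a two-group cohort of regional feature tables.

    Cases are perturbed in the planted effect regions so that regional MS
    decreases (down regions) or increases (up regions); per-batch location
    shifts and noise-scale factors are applied when ``n_batches > 1``. The
    memory score couples to the subjects' clean (pre-batch) mean MS over the
    down regions at roughly ``memory_coupling`` partial correlation.
    """
    L, comm = _latent_profile(config)
    explicit = config.explicit_effect_indices()
    if explicit is not None:
        down_idx, up_idx = explicit
    else:
        down_idx, up_idx = _default_effect_regions(config, L, comm)
    rng = stage_rng(config.seed, "cohort")
    n = 2 * config.n_per_group
    R, F = config.n_regions, config.n_features
    ids = region_ids(R, config.n_left_regions)

    group = np.array(
        [GROUP_CASE] * config.n_per_group + [GROUP_CONTROL] * config.n_per_group
    )
    age = rng.normal(75, 8, size=n).clip(55, 90)
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    education = rng.normal(16, 2.5, size=n).clip(8, 22)
    batch = np.array([f"site{i % config.n_batches}" for i in range(n)])

    if config.n_batches > 1:
        shift = np.asarray(
            config.batch_shift
            if config.batch_shift is not None
            else np.zeros(config.n_batches),
            dtype=float,
        )
        scale = np.asarray(
            config.batch_scale
            if config.batch_scale is not None
            else np.ones(config.n_batches),
            dtype=float,
        )
        if len(shift) != config.n_batches or len(scale) != config.n_batches:
            raise ValueError("batch_shift/batch_scale must have n_batches entries")
    else:
        shift = np.zeros(1)
        scale = np.ones(1)

    sigma = np.full((n, R), _SIGMA0)
    is_case = group == GROUP_CASE
    es = config.effect_size
    if es:
        if down_idx.size:
            sigma[np.ix_(is_case, down_idx)] = _SIGMA0 * np.sqrt(
                1 + _DOWN_NOISE * es
            )
        if up_idx.size:
            sigma[np.ix_(is_case, up_idx)] = _SIGMA0 / np.sqrt(
                1 + _UP_SHRINK * es
            )

    clean = np.empty((n, R, F))
    noise = rng.standard_normal((n, R, F))
    for s in range(n):
        clean[s] = L + sigma[s][:, None] * noise[s]

    features = clean.copy()
    if config.n_batches > 1:
        b_idx = np.array([i % config.n_batches for i in range(n)])
        extra = rng.standard_normal((n, R, F))
        for s in range(n):
            b = b_idx[s]
            features[s] = (
                clean[s]
                + shift[b]
                + (scale[b] - 1.0) * _SIGMA0 * extra[s]
            )

    # memory couples to clean mean MS over the planted down regions
    mem_rng = stage_rng(config.seed, "memory")
    ref_idx = down_idx if down_idx.size else np.arange(R)
    mean_ms = np.empty(n)
    for s in range(n):
        x = clean[s]
        zx = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        m = morphometry.ms_matrix(zx).matrix
        mean_ms[s] = np.nanmean(m[ref_idx], axis=1).mean()

    def _z(v):
        return (v - v.mean()) / v.std(ddof=1)

    mc = config.memory_coupling
    memory = (
        mc * _z(mean_ms)
        + 0.25 * _z(education)
        - 0.25 * _z(age)
        + np.sqrt(max(0.0, 1 - mc**2)) * mem_rng.standard_normal(n)
    )

    meta = pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "education": education,
            "batch": batch,
            "memory_score": memory,
        }
    )
    table = SubjectFeatureTable(
        features=features,
        meta=meta,
        region_ids=ids,
        feature_names=FEATURE_NAMES,
    )
    effect = pd.Series(0, index=pd.Index(ids, name="region_id"), dtype=int)
    effect.iloc[down_idx] = -1
    effect.iloc[up_idx] = 1
    truth = CohortTruth(
        region_effect=effect,
        down_regions=ids[down_idx],
        up_regions=ids[up_idx],
        batch_shift=shift,
        batch_scale=scale,
        memory_coupling=mc,
        clean_mean_ms_down=pd.Series(
            mean_ms, index=meta["subject_id"], name="clean_mean_ms_down"
        ),
    )
    return table, truth


def generate_expression(
    tmap: pd.DataFrame | pd.Series,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Regions x genes expression with spatial profiles coupled to a T map.

    ``tmap`` must cover exactly the left-hemisphere regions (a Series of T
    values, or a case-control result table with a ``T`` column). Coupled
    genes follow sign * coupling_strength * standardized(T) plus matched
    noise; null genes are pure spatial noise.
    """
    y = tmap["T"] if isinstance(tmap, pd.DataFrame) else tmap
    y = y.astype(float)
    if len(y) != config.n_left_regions:
        raise ValueError(
            f"tmap covers {len(y)} regions, expected {config.n_left_regions} "
            "left-hemisphere regions"
        )
    if y.std(ddof=1) == 0:
        raise ValueError("tmap is constant; cannot standardize")
    rng = stage_rng(config.seed, "expression")
    G = config.n_genes
    n_pos = int(round(config.coupled_frac_pos * G))
    n_neg = int(round(config.coupled_frac_neg * G))
    if n_pos + n_neg > G:
        raise ValueError("fewer genes than planted coupling labels")
    genes = gene_symbols(G)
    labels = np.zeros(G, dtype=int)
    order = rng.permutation(G)
    labels[order[:n_pos]] = 1
    labels[order[n_pos : n_pos + n_neg]] = -1

    t_z = (y - y.mean()) / y.std(ddof=1)
    rho = config.coupling_strength
    R = len(y)
    x = rng.standard_normal((R, G))
    coupled = labels != 0
    x[:, coupled] = (
        labels[coupled] * rho * t_z.to_numpy()[:, None]
        + np.sqrt(1 - rho**2) * x[:, coupled]
    )
    expr = pd.DataFrame(8.0 + x, index=y.index, columns=genes)
    truth = ExpressionTruth(
        gene_coupling=pd.Series(labels, index=pd.Index(genes, name="gene"))
    )
    return expr, truth


def generate_de_dataset(
    config: SimulationConfig,
    up_genes: list | None = None,
    down_genes: list | None = None,
) -> tuple[pd.DataFrame, pd.Series, DETruth]:
    """Two-group samples x genes log2-expression matrix with planted DEGs.

    Planted genes get a true log2 fold change of +/- ``de_lfc`` (beyond the
    +/-1 screening threshold by default). Pass ``up_genes``/``down_genes``
    to plant specific symbols (e.g. an overlap with a PLS-derived set);
    otherwise ``de_frac_up``/``de_frac_down`` random genes are used.
    """
    rng = stage_rng(config.seed, "de")
    G = config.n_genes
    genes = gene_symbols(G)
    gene_pos = {g: i for i, g in enumerate(genes)}
    label = np.array(["ns"] * G, dtype=object)
    if up_genes is None and down_genes is None:
        n_up = int(round(config.de_frac_up * G))
        n_down = int(round(config.de_frac_down * G))
        if n_up + n_down > G:
            raise ValueError("fewer genes than planted DE labels")
        order = rng.permutation(G)
        label[order[:n_up]] = "up"
        label[order[n_up : n_up + n_down]] = "down"
    else:
        for g in up_genes or []:
            if g not in gene_pos:
                raise ValueError(f"unknown gene {g!r}")
            label[gene_pos[g]] = "up"
        for g in down_genes or []:
            if g not in gene_pos:
                raise ValueError(f"unknown gene {g!r}")
            if label[gene_pos[g]] == "up":
                raise ValueError(f"gene {g!r} planted both up and down")
            label[gene_pos[g]] = "down"

    n = config.n_de_samples
    base = rng.normal(7.0, 1.0, size=G)
    shift = np.where(label == "up", config.de_lfc, 0.0) + np.where(
        label == "down", -config.de_lfc, 0.0
    )
    case = base + shift + rng.normal(0, config.de_noise_sd, size=(n, G))
    ctrl = base + rng.normal(0, config.de_noise_sd, size=(n, G))
    expr = pd.DataFrame(
        np.vstack([case, ctrl]),
        index=pd.Index(
            [f"case{i:03d}" for i in range(n)]
            + [f"ctrl{i:03d}" for i in range(n)],
            name="sample_id",
        ),
        columns=genes,
    )
    groups = pd.Series(
        ["case"] * n + ["control"] * n, index=expr.index, name="group"
    )
    truth = DETruth(
        de_label=pd.Series(label, index=pd.Index(genes, name="gene"))
    )
    return expr, groups, truth


def generate_celltype_profiles(
    config: SimulationConfig,
    specific: dict | None = None,
) -> tuple[pd.DataFrame, CellTypeTruth]:
    """Genes x cell-types mean expression with planted type-specific genes.

    Planted genes are strongly concentrated in one cell type; the rest are
    exchangeable across types. ``specific`` maps cell-type name -> gene list
    to plant particular symbols; default draws ``celltype_frac`` of genes
    per type.
    """
    rng = stage_rng(config.seed, "celltype")
    G = config.n_genes
    genes = gene_symbols(G)
    gene_pos = {g: i for i, g in enumerate(genes)}
    label = np.array([""] * G, dtype=object)
    if specific is None:
        per_type = int(round(config.celltype_frac * G))
        if per_type * len(CELL_TYPES) > G:
            raise ValueError("fewer genes than planted cell-type labels")
        order = rng.permutation(G)
        for t_i, t in enumerate(CELL_TYPES):
            label[order[t_i * per_type : (t_i + 1) * per_type]] = t
    else:
        for t, lst in specific.items():
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r}")
            for g in lst:
                if g not in gene_pos:
                    raise ValueError(f"unknown gene {g!r}")
                label[gene_pos[g]] = t

    base = rng.lognormal(mean=1.0, sigma=0.5, size=G)
    noise = rng.lognormal(mean=0.0, sigma=0.15, size=(G, len(CELL_TYPES)))
    x = base[:, None] * noise
    for t_i, t in enumerate(CELL_TYPES):
        sel = label == t
        x[sel] *= 0.2
        x[sel, t_i] *= 40.0
    profile = pd.DataFrame(
        x, index=pd.Index(genes, name="gene"), columns=list(CELL_TYPES)
    )
    truth = CellTypeTruth(
        celltype_label=pd.Series(label, index=pd.Index(genes, name="gene"))
    )
    return profile, truth


def synthetic_atlas(config: SimulationConfig) -> pd.DataFrame:
    """Region atlas table (ids, names, hemisphere, placeholder coordinates)."""
    ids = region_ids(config.n_regions, config.n_left_regions)
    rng = stage_rng(config.seed, "latent")
    coords = rng.uniform(-70, 70, size=(config.n_regions, 3)).round(2)
    return pd.DataFrame(
        {
            "region_id": ids,
            "name": [f"region_{r}" for r in ids],
            "hemisphere": ["L" if r.startswith("L") else "R" for r in ids],
            "mni_x": coords[:, 0],
            "mni_y": coords[:, 1],
            "mni_z": coords[:, 2],
        }
    )
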