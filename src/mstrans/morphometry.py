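"""Per-subject regional features -> harmonized MS matrices and regional MS.

A morphometric-similarity (MS) matrix is the regions x regions Pearson
correlation of each pair of regions' z-scored multimodal feature vectors,
computed within a single subject. Regional MS is the off-diagonal row mean of
that matrix: the weighted degree of each cortical node under signed, weighted
edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mstrans._combat import combat

logger = logging.getLogger(__name__)

#: Fixed 7-feature vocabulary: myelination {fa, md}, gray matter
#: {gm_volume, surface_area, thickness}, curvature {gaussian_curvature,
#: mean_curvature}.
FEATURE_NAMES: tuple[str, ...] = (
    "fa",
    "md",
    "gm_volume",
    "surface_area",
    "thickness",
    "gaussian_curvature",
    "mean_curvature",
)

#: Metadata columns every cohort table must provide.
META_COLUMNS = ("subject_id", "group", "age", "sex", "education", "batch")

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass
class SubjectFeatureTable:
    """Subjects x regions x features array plus per-subject metadata.

    Attributes
    ----------
    features
        Array of shape (n_subjects, n_regions, n_features), no missing values.
    meta
        DataFrame indexed like ``features`` axis 0 with at least
        ``subject_id, group, age, sex, education, batch`` (plus optional
        ``memory_score``).
    region_ids
        Region identifiers, consistent across subjects.
    feature_names
        Names drawn from :data:`FEATURE_NAMES`.
    """

    features: np.ndarray
    meta: pd.DataFrame
    region_ids: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.features.ndim != 3:
            raise ValueError("features must be (subjects, regions, features)")
        ns, nr, nf = self.features.shape
        if len(self.meta) != ns:
            raise ValueError("meta rows must match number of subjects")
        if len(self.region_ids) != nr:
            raise ValueError("region_ids must match features axis 1")
        if len(self.feature_names) != nf:
            raise ValueError("feature_names must match features axis 2")
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        if self.meta["subject_id"].duplicated().any():
            dup = self.meta["subject_id"][self.meta["subject_id"].duplicated()]
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_regions(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "SubjectFeatureTable":
        return replace(
            self, features=self.features.copy(), meta=self.meta.copy()
        )


@dataclass
class MSMatrix:
    """One subject's symmetric regions x regions similarity matrix.

    The diagonal is NaN (self-similarity carries no information); rows of
    degenerate regions (zero feature variance) are fully NaN.
    """

    subject_id: str
    matrix: np.ndarray
    region_ids: np.ndarray
    masked_regions: list = field(default_factory=list)


@dataclass
class RegionalMS:
    """Per-region weighted degree (off-diagonal row means) for one subject."""

    subject_id: str
    values: np.ndarray
    region_ids: np.ndarray


def _design_from_meta(meta: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = []
    for cov in covariates:
        s = meta[cov]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
        else:
            cols.append(s.to_numpy(dtype=float)[:, None])
    if not cols:
        return np.empty((len(meta), 0))
    return np.hstack(cols)


def harmonize_features(
    table: SubjectFeatureTable,
    batch: str = "batch",
    model_covariates: tuple[str, ...] = ("group", "age", "sex", "education"),
) -> SubjectFeatureTable:
    """Remove batch location/scale effects from every (region, feature) series.

    Each (region, feature) pair becomes one row of a features x subjects
    matrix that is adjusted by parametric empirical-Bayes ComBat. Covariates
    named in ``model_covariates`` are preserved, so e.g. a real group effect
    is not absorbed into the batch correction. A single batch is a no-op.
    """
    labels = table.meta[batch].to_numpy()
    if pd.isna(labels).any():
        raise ValueError("batch labels missing for some subjects")
    if len(np.unique(labels)) == 1:
        return table.copy()
    design = _design_from_meta(table.meta, list(model_covariates))
    ns, nr, nf = table.features.shape
    flat = table.features.reshape(ns, nr * nf).T  # (region*feature) x subjects
    adj = combat(flat, labels, design if design.size else None)
    out = table.copy()
    out.features = adj.T.reshape(ns, nr, nf)
    return out


def zscore_features(
    table: SubjectFeatureTable, axis: str = "within_subject"
) -> SubjectFeatureTable:
    """Standardize each feature to mean 0, sample sd 1 (ddof=1).

    The default (and shipped) axis standardizes across regions within each
    subject, making MS a within-individual similarity; the alternative
    ``axis='across_subjects'`` pools each (region, feature) series across
    subjects and exists for sensitivity analysis only. Errors name the first
    offending subject/feature when a series has zero variance.
    """
    x = table.features
    if axis == "within_subject":
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        bad = np.argwhere(sd[:, 0, :] == 0)
        if bad.size:
            s, f = bad[0]
            raise ValueError(
                "zero variance across regions for subject "
                f"{table.meta['subject_id'].iloc[s]!r}, feature "
                f"{table.feature_names[f]!r}"
            )
    elif axis == "across_subjects":
        mean = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            r, f = np.argwhere(sd[0] == 0)[0]
            raise ValueError(
                f"zero variance across subjects for region "
                f"{table.region_ids[r]!r}, feature {table.feature_names[f]!r}"
            )
    else:
        raise ValueError(f"unknown z-scoring axis {axis!r}")
    out = table.copy()
    out.features = (x - mean) / sd
    return out


def ms_matrix(
    subject_features: np.ndarray,
    region_ids: np.ndarray | None = None,
    subject_id: str = "",
) -> MSMatrix:
    """Pearson-correlate every pair of regions' feature vectors.

    ``subject_features`` is one subject's regions x features block (z-scored
    upstream). Entry (i, j) is the Pearson r between region i's and region j's
    7-feature vectors; the diagonal is NaN. Regions whose feature vector has
    zero variance are masked (NaN row/column) and reported.
    """
    x = np.asarray(subject_features, dtype=float)
    if x.ndim != 2:
        raise ValueError("subject_features must be regions x features")
    nr = x.shape[0]
    if region_ids is None:
        region_ids = np.arange(nr)

    sd = x.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = np.corrcoef(x)
    mat = np.asarray(mat, dtype=float)
    if degenerate.size:
        mat[degenerate, :] = np.nan
        mat[:, degenerate] = np.nan
        logger.warning(
            "subject %s: %d degenerate regions masked: %s",
            subject_id,
            degenerate.size,
            np.asarray(region_ids)[degenerate][:10].tolist(),
        )
    np.fill_diagonal(mat, np.nan)
    # clip tiny fp excursions beyond [-1, 1]
    np.clip(mat, -1.0, 1.0, out=mat)
    return MSMatrix(
        subject_id=subject_id,
        matrix=mat,
        region_ids=np.asarray(region_ids),
        masked_regions=np.asarray(region_ids)[degenerate].tolist(),
    )


def regional_ms(ms: MSMatrix) -> RegionalMS:
    """Weighted degree: mean of each row excluding the diagonal.

    Signed edges are retained (no absolute value, no thresholding). Masked
    rows propagate as NaN with a warning.
    """
    mat = ms.matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(mat, axis=1)
    if np.isnan(vals).any():
        logger.warning(
            "subject %s: %d regional MS values missing",
            ms.subject_id,
            int(np.isnan(vals).sum()),
        )
    return RegionalMS(
        subject_id=ms.subject_id, values=vals, region_ids=ms.region_ids
    )


def regional_ms_table(
    table: SubjectFeatureTable, zscored: bool = True
) -> pd.DataFrame:
    """Full morphometry stage for a cohort: subjects x regions regional MS.

    ``table`` must already be harmonized; set ``zscored=False`` to apply the
    within-subject z-scoring here.
    """
    if not zscored:
        table = zscore_features(table)
    rows = []
    for s in range(table.n_subjects):
        sid = str(table.meta["subject_id"].iloc[s])
        m = ms_matrix(table.features[s], table.region_ids, subject_id=sid)
        rows.append(regional_ms(m).values)
    return pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(table.meta["subject_id"].astype(str), name="subject_id"),
        columns=table.region_ids,
    )
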