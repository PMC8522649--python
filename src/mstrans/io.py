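"""Readers and writers for the pipeline's plain-text formats.

TSV with explicit headers is the canonical dialect; CSV is accepted on
ingest (delimiter sniffed from the extension). Region and gene identifiers
are always matched by id/symbol, never by positional order. Full float
precision is preserved on round trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mstrans.morphometry import (
    FEATURE_NAMES,
    META_COLUMNS,
    SubjectFeatureTable,
)
from mstrans.transcription import GeneSet

FLOAT_FMT = "%.17g"


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _check_numeric(df: pd.DataFrame, what: str) -> None:
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{what}: non-numeric columns {bad[:5]}")


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(
    table: SubjectFeatureTable, features_path, meta_path
) -> None:
    """Write long-format features (subject_id, region_id, feature, value)
    and the metadata table."""
    ns, nr, nf = table.features.shape
    sid = np.repeat(table.meta["subject_id"].astype(str).to_numpy(), nr * nf)
    rid = np.tile(np.repeat(table.region_ids.astype(str), nf), ns)
    feat = np.tile(np.asarray(table.feature_names), ns * nr)
    long = pd.DataFrame(
        {
            "subject_id": sid,
            "region_id": rid,
            "feature": feat,
            "value": table.features.ravel(),
        }
    )
    long.to_csv(
        features_path, sep=_sep(features_path), index=False, float_format=FLOAT_FMT
    )
    table.meta.to_csv(
        meta_path, sep=_sep(meta_path), index=False, float_format=FLOAT_FMT
    )


def read_feature_table(features_path, meta_path) -> SubjectFeatureTable:
    """Read a long-format feature table plus metadata into a cohort object."""
    long = pd.read_csv(
        features_path, sep=_sep(features_path), float_precision="round_trip"
    )
    need = {"subject_id", "region_id", "feature", "value"}
    missing = need - set(long.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    unknown = set(long["feature"]) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    dup = long.duplicated(["subject_id", "region_id", "feature"])
    if dup.any():
        first = long.loc[dup, ["subject_id", "region_id", "feature"]].iloc[0]
        raise ValueError(
            f"duplicate entry for {tuple(first)} (and possibly others)"
        )
    meta = pd.read_csv(
        meta_path, sep=_sep(meta_path), float_precision="round_trip"
    )
    miss_meta = [c for c in META_COLUMNS if c not in meta.columns]
    if miss_meta:
        raise ValueError(f"metadata missing columns: {miss_meta}")
    meta["subject_id"] = meta["subject_id"].astype(str)

    wide = long.pivot_table(
        index=["subject_id", "region_id"],
        columns="feature",
        values="value",
        aggfunc="first",
        sort=False,
    )
    if wide.isna().any().any():
        n = int(wide.isna().sum().sum())
        raise ValueError(f"{n} missing (subject, region, feature) entries")
    subjects = meta["subject_id"].tolist()
    regions = pd.unique(long["region_id"].astype(str))
    feats = [f for f in FEATURE_NAMES if f in wide.columns]
    if len(feats) != len(FEATURE_NAMES):
        raise ValueError("feature table does not cover the full vocabulary")
    arr = np.empty((len(subjects), len(regions), len(feats)))
    wide = wide[feats]
    for i, s in enumerate(subjects):
        block = wide.loc[s]
        block.index = block.index.astype(str)
        arr[i] = block.loc[regions].to_numpy(dtype=float)
    return SubjectFeatureTable(
        features=arr,
        meta=meta,
        region_ids=np.asarray(regions),
        feature_names=tuple(feats),
    )


# ---------------------------------------------------------------------------
# matrices and per-region tables


def write_matrix(df: pd.DataFrame, path) -> None:
    """Regions x regions (or any labelled) matrix to TSV, index kept."""
    df.to_csv(path, sep=_sep(path), float_format=FLOAT_FMT)


def read_matrix(path, index_name: str = "region_id") -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.index.name = index_name
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate row ids: {dup[:5]}")
    _check_numeric(df, str(path))
    return df


def write_regional_ms(regional: pd.DataFrame, path) -> None:
    """Subjects x regions regional-MS table."""
    regional.to_csv(path, sep=_sep(path), float_format=FLOAT_FMT)


def read_regional_ms(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    df.columns = df.columns.astype(str)
    _check_numeric(df, str(path))
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Regions x genes matrix; header row = gene symbols (must be unique)."""
    sep = _sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene symbols: {sorted(set(dup))[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "region_id"
    df.columns = df.columns.astype(str)
    _check_numeric(df, str(path))
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


write_expression_matrix = write_matrix


# ---------------------------------------------------------------------------
# gene sets


def write_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gs.genes))


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """One symbol per line, or two-column TSV (set, symbol) for one set."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if lines and "\t" in lines[0]:
        pairs = [ln.split("\t") for ln in lines]
        labels = {p[0] for p in pairs}
        if len(labels) != 1:
            raise ValueError(
                "two-column gene-set file holds multiple sets; use read_gmt"
            )
        return GeneSet(label or labels.pop(), tuple(p[1] for p in pairs))
    return GeneSet(label or Path(path).stem, tuple(lines))


def read_gmt(path) -> dict:
    """GMT-style collection: name <tab> description <tab> genes..."""
    out: dict[str, GeneSet] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:60]!r}")
        name = parts[0]
        if name in out:
            raise ValueError(f"duplicate set name {name!r}")
        out[name] = GeneSet(name, tuple(g for g in parts[2:] if g))
    if not out:
        raise ValueError("empty GMT collection")
    return out


def write_gmt(collection: dict, path) -> None:
    with open(path, "w") as fh:
        for name, gs in collection.items():
            fh.write("\t".join([name, ""] + list(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# atlas & stats tables


def read_region_atlas(path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep=_sep(path))
    need = {"region_id", "hemisphere"}
    missing = need - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas missing columns: {sorted(missing)}")
    atlas["region_id"] = atlas["region_id"].astype(str)
    if atlas["region_id"].duplicated().any():
        dup = atlas["region_id"][atlas["region_id"].duplicated()]
        raise ValueError(f"duplicate region ids: {sorted(set(dup))[:5]}")
    return atlas


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep=_sep(path), index=index, float_format=FLOAT_FMT)


def read_tmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "region_id"
    if "T" not in df.columns:
        raise ValueError("T-map table must carry a 'T' column")
    return df
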