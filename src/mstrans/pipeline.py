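"""End-to-end orchestration: simulate/ingest -> harmonize -> MS -> T map ->
PLS -> gene sets -> enrichment, with a machine-readable run manifest.

Every stage writes its outputs under the run directory as TSV; the manifest
records the config (and its hash), the seed, per-stage output paths and
counts of dropped/masked entities, and is sufficient to re-execute any
stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mstrans import case_control, enrichment, io, morphometry, simulate
from mstrans import transcription as tx
from mstrans.config import AnalysisConfig
from mstrans.simulate import CELL_TYPES, SimulationConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage named; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _rng_seed(cfg: AnalysisConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(100 + stream,))
    )


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute all stages in order and return the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "outputs": {},
        "log": {},
    }

    def _write_manifest():
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage named
            _write_manifest()
            raise PipelineError(stage, exc) from exc

    # ------------------------------------------------------------------ data
    sim_cfg = None
    truths: dict = {}
    if cfg.simulate:
        sim_cfg = SimulationConfig(**{**cfg.sim, "seed": cfg.seed})

        def _simulate():
            table, truth = simulate.generate_cohort(sim_cfg)
            atlas = simulate.synthetic_atlas(sim_cfg)
            io.write_feature_table(
                table, out / "features.tsv", out / "meta.tsv"
            )
            io.write_table(atlas, out / "atlas.tsv", index=False)
            io.write_table(
                truth.region_effect.to_frame("effect"),
                out / "truth_region_effect.tsv",
            )
            return table, atlas, truth

        table, atlas, truths["cohort"] = _run("simulate", _simulate)
        manifest["outputs"]["features"] = str(out / "features.tsv")
    else:

        def _ingest():
            table = io.read_feature_table(cfg.features_path, cfg.meta_path)
            atlas = io.read_region_atlas(cfg.atlas_path)
            return table, atlas

        table, atlas = _run("ingest", _ingest)

    # ------------------------------------------------------------ morphometry
    def _harmonize():
        if not cfg.harmonize or table.meta["batch"].nunique() == 1:
            return table
        return morphometry.harmonize_features(
            table, model_covariates=tuple(cfg.combat_covariates)
        )

    harmonized = _run("harmonize", _harmonize)

    def _ms():
        z = morphometry.zscore_features(harmonized, axis=cfg.zscore_axis)
        regional = morphometry.regional_ms_table(z)
        io.write_regional_ms(regional, out / "regional_ms.tsv")
        if cfg.write_ms_matrices:
            for s in range(z.n_subjects):
                sid = str(z.meta["subject_id"].iloc[s])
                m = morphometry.ms_matrix(
                    z.features[s], z.region_ids, subject_id=sid
                )
                io.write_matrix(
                    pd.DataFrame(
                        m.matrix, index=z.region_ids, columns=z.region_ids
                    ),
                    out / f"ms_{sid}.tsv",
                )
        return regional

    regional = _run("ms", _ms)
    manifest["outputs"]["regional_ms"] = str(out / "regional_ms.tsv")

    # ------------------------------------------------------------ case-control
    def _tmap():
        res = case_control.tmap(
            regional, table.meta, covariates=tuple(cfg.model_covariates)
        )
        keep = [
            c
            for c in ("name", "mni_x", "mni_y", "mni_z")
            if c in atlas.columns
        ]
        t2 = res.join(atlas.set_index("region_id")[keep])
        t2 = t2.sort_values(["direction", "p"])
        io.write_table(t2, out / "tmap.tsv")
        demo = case_control.group_compare(table.meta)
        io.write_table(demo, out / "demographics.tsv", index=False)
        return res

    tmap_res = _run("tmap", _tmap)
    manifest["outputs"]["tmap"] = str(out / "tmap.tsv")
    manifest["log"]["n_sig_regions"] = int((tmap_res["q"] < cfg.fdr_q).sum())

    # -------------------------------------------------------------------- PLS
    left_ids = atlas.loc[
        atlas["hemisphere"].astype(str).str.upper() == "L", "region_id"
    ].astype(str)
    y_left = tmap_res.loc[tmap_res.index.isin(set(left_ids)), "T"]

    if cfg.simulate:

        def _expr():
            expr, truth = simulate.generate_expression(y_left, sim_cfg)
            io.write_expression_matrix(expr, out / "expression.tsv")
            io.write_table(
                truth.gene_coupling.to_frame("coupling"),
                out / "truth_gene_coupling.tsv",
            )
            return expr, truth

        expr, truths["expression"] = _run("simulate_expression", _expr)
    elif cfg.expression_path:
        expr = _run(
            "read_expression",
            lambda: io.read_expression_matrix(cfg.expression_path),
        )
    else:
        expr = None

    pls = None
    gs_pos = gs_neg = None
    if expr is not None:

        def _pls():
            res = tx.bootstrap_z(
                expr,
                y_left,
                B=cfg.B,
                seed=_rng_seed(cfg, 0),
                scale_genes=cfg.scale_genes,
                alpha=cfg.alpha,
            )
            if cfg.z_crit is not None:
                res.z_crit = cfg.z_crit
            pos, neg = tx.threshold_gene_sets(res)
            gene_table = res.gene_table()
            gene_table["set"] = "ns"
            gene_table.loc[list(pos.genes), "set"] = "PLS1+"
            gene_table.loc[list(neg.genes), "set"] = "PLS1-"
            io.write_table(gene_table, out / "pls_genes.tsv")
            io.write_table(
                pd.DataFrame(
                    {"t_score": res.t_score}, index=res.region_ids
                ),
                out / "pls_scores.tsv",
            )
            io.write_gene_set(pos, out / "pls1_pos.txt")
            io.write_gene_set(neg, out / "pls1_neg.txt")
            rows = []
            for gs in (pos, neg):
                if len(gs) == 0:
                    continue
                m = tx.geneset_expression_map(expr, gs)
                r, p = tx.spatial_correlation(m, y_left)
                rows.append({"set": gs.label, "r": r, "p": p, "n": len(gs)})
            io.write_table(
                pd.DataFrame(rows), out / "pls_spatial.tsv", index=False
            )
            return res, pos, neg

        pls, gs_pos, gs_neg = _run("pls", _pls)
        manifest["outputs"]["pls_genes"] = str(out / "pls_genes.tsv")
        manifest["log"]["z_crit"] = pls.z_crit
        manifest["log"]["n_pls_pos"] = len(gs_pos)
        manifest["log"]["n_pls_neg"] = len(gs_neg)
        manifest["log"]["varexp_y"] = pls.varexp_y
        manifest["log"]["dropped_genes"] = len(pls.dropped_genes)

    # ------------------------------------------------------------- enrichment
    background = list(map(str, expr.columns)) if expr is not None else None

    de_expr = de_groups = None
    if cfg.simulate and expr is not None:

        def _de_data():
            coupling = truths["expression"].gene_coupling
            neg_genes = list(coupling.index[coupling == -1])
            rng = _rng_seed(cfg, 1)
            pool = [g for g in expr.columns if g not in set(neg_genes)]
            n_up = int(round(sim_cfg.de_frac_up * sim_cfg.n_genes))
            up_genes = list(rng.choice(pool, size=n_up, replace=False))
            de, grp, truth = simulate.generate_de_dataset(
                sim_cfg, up_genes=up_genes, down_genes=neg_genes
            )
            io.write_table(de, out / "de_expression.tsv")
            io.write_table(grp.to_frame(), out / "de_groups.tsv")
            return de, grp, truth

        de_expr, de_groups, truths["de"] = _run("simulate_de", _de_data)
    elif cfg.de_path and cfg.de_groups_path:

        def _read_de():
            de = io.read_matrix(cfg.de_path, index_name="sample_id")
            grp = pd.read_csv(cfg.de_groups_path, sep="\t", index_col=0)[
                "group"
            ]
            return de, grp

        de_expr, de_groups = _run("read_de", _read_de)

    if de_expr is not None and gs_pos is not None:

        def _enrich():
            de_res = enrichment.moderated_de(
                de_expr,
                de_groups,
                p_thresh=cfg.p_thresh,
                fc_thresh=cfg.fc_thresh,
            )
            io.write_table(de_res.table, out / "de_results.tsv")
            rows = []
            for pls_set in (gs_neg, gs_pos):
                for deg in (de_res.down, de_res.up):
                    res = enrichment.fisher_overlap(
                        pls_set,
                        deg,
                        background,
                        m_comparisons=2,
                        alternative=cfg.fisher_alternative,
                    )
                    rows.append(
                        {
                            "pls_set": pls_set.label,
                            "deg_set": deg.label,
                            **enrichment.overlap_summary(res),
                        }
                    )
            io.write_table(
                pd.DataFrame(rows), out / "deg_overlap.tsv", index=False
            )
            return de_res

        de_res = _run("enrich", _enrich)
        manifest["outputs"]["deg_overlap"] = str(out / "deg_overlap.tsv")
        manifest["log"]["n_deg_up"] = len(de_res.up)
        manifest["log"]["n_deg_down"] = len(de_res.down)

    # --------------------------------------------------------------- celltype
    profile = None
    if cfg.simulate and gs_neg is not None:

        def _celltype_data():
            coupling = truths["expression"].gene_coupling
            neg_genes = list(coupling.index[coupling == -1])
            rng = _rng_seed(cfg, 2)
            pool = [g for g in expr.columns if g not in set(neg_genes)]
            per_type = int(round(sim_cfg.celltype_frac * sim_cfg.n_genes))
            picks = rng.choice(
                pool, size=per_type * (len(CELL_TYPES) - 1), replace=False
            )
            specific = {"neurons": neg_genes}
            others = [t for t in CELL_TYPES if t != "neurons"]
            for i, t in enumerate(others):
                specific[t] = list(picks[i * per_type : (i + 1) * per_type])
            prof, truth = simulate.generate_celltype_profiles(
                sim_cfg, specific=specific
            )
            io.write_table(prof, out / "celltype_profiles.tsv")
            return prof, truth

        profile, truths["celltype"] = _run("simulate_celltype", _celltype_data)
    elif cfg.celltype_path:
        profile = _run(
            "read_celltype",
            lambda: io.read_matrix(cfg.celltype_path, index_name="gene"),
        )

    if profile is not None and gs_pos is not None:

        def _celltype():
            psi = enrichment.psi_compute(
                profile,
                B_perm=cfg.B_perm,
                seed=_rng_seed(cfg, 3),
                psi_thresh=cfg.psi_thresh,
            )
            io.write_table(psi.psi, out / "psi.tsv")
            rows = []
            for pls_set in (gs_neg, gs_pos):
                for t, gs in psi.enriched.items():
                    res = enrichment.fisher_overlap(
                        pls_set,
                        gs,
                        background,
                        m_comparisons=len(psi.enriched),
                        alternative=cfg.fisher_alternative,
                    )
                    rows.append(
                        {
                            "pls_set": pls_set.label,
                            "cell_type": t,
                            **enrichment.overlap_summary(res),
                        }
                    )
            io.write_table(
                pd.DataFrame(rows), out / "celltype_overlap.tsv", index=False
            )
            return psi

        psi = _run("celltype", _celltype)
        manifest["outputs"]["celltype_overlap"] = str(
            out / "celltype_overlap.tsv"
        )

    # -------------------------------------------------------------------- ORA
    if cfg.gmt_path and gs_neg is not None:

        def _ora():
            coll = io.read_gmt(cfg.gmt_path)
            res = enrichment.ora_collection(
                gs_neg, coll, background, alternative=cfg.fisher_alternative
            )
            io.write_table(res, out / "ora_neg.tsv", index=False)
            return res

        _run("ora", _ora)
        manifest["outputs"]["ora"] = str(out / "ora_neg.tsv")

    # --------------------------------------------------------------- behavior
    if "memory_score" in table.meta.columns and not table.meta[
        "memory_score"
    ].isna().all():

        def _behavior():
            sig_down = tmap_res.index[
                (tmap_res["q"] < cfg.fdr_q) & (tmap_res["T"] < 0)
            ]
            sig_up = tmap_res.index[
                (tmap_res["q"] < cfg.fdr_q) & (tmap_res["T"] > 0)
            ]
            covs = np.column_stack(
                [
                    case_control._encode(table.meta[c])
                    for c in cfg.model_covariates
                ]
            )
            rows = []
            for name, regs in (("decreased", sig_down), ("increased", sig_up)):
                if len(regs) == 0:
                    continue
                mean_ms = case_control.mean_ms_subset(regional, list(regs))
                bc = case_control.partial_correlation(
                    mean_ms.to_numpy(),
                    table.meta["memory_score"].to_numpy(dtype=float),
                    covs,
                    covariate_names=tuple(cfg.model_covariates),
                )
                rows.append(
                    {
                        "region_set": name,
                        "n_regions": len(regs),
                        "r": bc.r,
                        "p": bc.p,
                        "n_effective": bc.n_effective,
                    }
                )
            io.write_table(
                pd.DataFrame(rows), out / "memory_correlation.tsv", index=False
            )
            return rows

        manifest["log"]["memory_correlation"] = _run("behavior", _behavior)

    _write_manifest()
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
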