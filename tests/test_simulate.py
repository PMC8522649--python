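import numpy as np
import pandas as pd
import pytest

from mstrans import case_control, morphometry, simulate
from mstrans import transcription as tx
from mstrans.simulate import (
    CELL_TYPES,
    SimulationConfig,
    generate_celltype_profiles,
    generate_cohort,
    generate_de_dataset,
    generate_expression,
)

SMALL = dict(n_per_group=10, n_regions=40, n_left_regions=20, n_genes=100)


class TestConfig:
    def test_counts_positive(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_per_group=0)

    def test_effect_lists_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            SimulationConfig(
                effect_regions_down=[1, 2], effect_regions_up=[2, 3]
            )

    def test_coupling_range(self):
        with pytest.raises(ValueError, match="coupling"):
            SimulationConfig(coupling_strength=1.5)

    def test_effect_region_out_of_range(self):
        cfg = SimulationConfig(
            **SMALL, effect_regions_down=[999], effect_regions_up=[]
        )
        with pytest.raises(ValueError, match="out of range"):
            generate_cohort(cfg)

    def test_left_exceeding_total(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_regions=100, n_left_regions=151)


class TestCohort:
    def test_bit_reproducible(self):
        t1, _ = generate_cohort(SimulationConfig(**SMALL, seed=5))
        t2, _ = generate_cohort(SimulationConfig(**SMALL, seed=5))
        np.testing.assert_array_equal(t1.features, t2.features)
        pd.testing.assert_frame_equal(t1.meta, t2.meta)

    def test_seed_changes_output(self):
        t1, _ = generate_cohort(SimulationConfig(**SMALL, seed=5))
        t2, _ = generate_cohort(SimulationConfig(**SMALL, seed=6))
        assert not np.array_equal(t1.features, t2.features)

    def test_single_batch_ignores_batch_params(self):
        t1, _ = generate_cohort(SimulationConfig(**SMALL, n_batches=1, seed=2))
        t2, _ = generate_cohort(
            SimulationConfig(
                **SMALL,
                n_batches=1,
                batch_shift=[3.0],
                batch_scale=[2.0],
                seed=2,
            )
        )
        np.testing.assert_array_equal(t1.features, t2.features)

    def test_truth_labels_partition_regions(self):
        table, truth = generate_cohort(SimulationConfig(**SMALL, seed=1))
        assert set(truth.region_effect.unique()) <= {-1, 0, 1}
        assert len(truth.region_effect) == table.n_regions
        assert (truth.region_effect == -1).sum() == len(truth.down_regions)
        assert (truth.region_effect == 1).sum() == len(truth.up_regions)
        assert not (set(truth.down_regions) & set(truth.up_regions))

    def test_metadata_complete(self):
        table, _ = generate_cohort(SimulationConfig(**SMALL, seed=1))
        assert not table.meta[
            ["group", "age", "sex", "education", "batch", "memory_score"]
        ].isna().any().any()
        assert (table.meta["group"] == "case").sum() == 10

    def test_batch_shift_moves_means(self):
        cfg = SimulationConfig(
            **SMALL, n_batches=2, batch_shift=[0.0, 2.0], seed=3
        )
        table, truth = generate_cohort(cfg)
        b = table.meta["batch"].to_numpy()
        diff = (
            table.features[b == "site1"].mean()
            - table.features[b == "site0"].mean()
        )
        assert diff == pytest.approx(2.0, abs=0.2)
        np.testing.assert_array_equal(truth.batch_shift, [0.0, 2.0])

    def test_null_effect_calibration_single_cohort(self):
        cfg = SimulationConfig(
            n_per_group=15, n_regions=60, n_left_regions=30,
            n_genes=50, effect_size=0.0, seed=4,
        )
        table, _ = generate_cohort(cfg)
        reg = morphometry.regional_ms_table(
            morphometry.zscore_features(table)
        )
        res = case_control.tmap(reg, table.meta)
        # loose single-replicate bound; full calibration in acceptance tests
        assert (res["p"] < 0.05).mean() < 0.2

    def test_memory_couples_to_planted_mean_ms(self):
        cfg = SimulationConfig(
            n_per_group=40, n_regions=80, n_left_regions=40, n_genes=50,
            effect_size=1.0, memory_coupling=0.6, seed=9,
        )
        table, truth = generate_cohort(cfg)
        r = np.corrcoef(
            truth.clean_mean_ms_down.to_numpy(),
            table.meta["memory_score"].to_numpy(),
        )[0, 1]
        assert r > 0.3


class TestExpression:
    def _tmap(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        ids = simulate.region_ids(cfg.n_regions, cfg.n_left_regions)
        return pd.Series(
            rng.normal(size=cfg.n_left_regions),
            index=ids[: cfg.n_left_regions],
        )

    def test_shape_and_no_missing(self):
        cfg = SimulationConfig(**SMALL, seed=2)
        expr, truth = generate_expression(self._tmap(cfg), cfg)
        assert expr.shape == (20, 100)
        assert not expr.isna().any().any()
        assert set(truth.gene_coupling.unique()) <= {-1, 0, 1}

    def test_region_mismatch_errors(self):
        cfg = SimulationConfig(**SMALL, seed=2)
        y = self._tmap(cfg)
        with pytest.raises(ValueError, match="regions"):
            generate_expression(y.iloc[:10], cfg)

    def test_coupled_profiles_correlate_with_t(self):
        cfg = SimulationConfig(
            n_per_group=10, n_regions=120, n_left_regions=60, n_genes=60,
            coupling_strength=0.9, seed=3,
        )
        y = self._tmap(cfg)
        expr, truth = generate_expression(y, cfg)
        pos = truth.gene_coupling[truth.gene_coupling == 1].index
        rs = [np.corrcoef(expr[g], y)[0, 1] for g in pos]
        assert np.mean(rs) > 0.7

    def test_single_coupled_gene_zero_noise_max_weight(self):
        cfg = SimulationConfig(
            n_per_group=10, n_regions=40, n_left_regions=20, n_genes=50,
            coupling_strength=1.0, coupled_frac_pos=0.02,
            coupled_frac_neg=0.0, seed=6,
        )
        y = self._tmap(cfg)
        expr, truth = generate_expression(y, cfg)
        coupled = truth.gene_coupling[truth.gene_coupling == 1].index
        assert len(coupled) == 1
        res = tx.pls1_fit(expr, y)
        w = pd.Series(np.abs(res.w), index=res.genes)
        assert w.idxmax() == coupled[0]

    def test_reproducible(self):
        cfg = SimulationConfig(**SMALL, seed=8)
        y = self._tmap(cfg)
        e1, _ = generate_expression(y, cfg)
        e2, _ = generate_expression(y, cfg)
        pd.testing.assert_frame_equal(e1, e2)


class TestDEDataset:
    def test_labels_partition(self):
        cfg = SimulationConfig(**SMALL, seed=1)
        expr, groups, truth = generate_de_dataset(cfg)
        assert set(truth.de_label.unique()) <= {"up", "down", "ns"}
        assert expr.shape == (2 * cfg.n_de_samples, cfg.n_genes)
        assert groups.value_counts().to_dict() == {
            "case": cfg.n_de_samples,
            "control": cfg.n_de_samples,
        }

    def test_planted_lfc_sign(self):
        cfg = SimulationConfig(**SMALL, seed=2)
        expr, groups, truth = generate_de_dataset(cfg)
        up = truth.de_label[truth.de_label == "up"].index
        case = expr[groups == "case"]
        ctrl = expr[groups == "control"]
        lfc = case[up].mean() - ctrl[up].mean()
        assert (lfc > 1.0).all()

    def test_explicit_gene_lists(self):
        cfg = SimulationConfig(**SMALL, seed=3)
        expr, groups, truth = generate_de_dataset(
            cfg, up_genes=["G00001"], down_genes=["G00002"]
        )
        assert truth.de_label["G00001"] == "up"
        assert truth.de_label["G00002"] == "down"
        assert (truth.de_label == "ns").sum() == cfg.n_genes - 2

    def test_conflicting_lists_error(self):
        cfg = SimulationConfig(**SMALL, seed=3)
        with pytest.raises(ValueError, match="both"):
            generate_de_dataset(
                cfg, up_genes=["G00001"], down_genes=["G00001"]
            )

    def test_too_many_planted_error(self):
        cfg = SimulationConfig(**SMALL, de_frac_up=0.6, de_frac_down=0.6)
        with pytest.raises(ValueError, match="fewer genes"):
            generate_de_dataset(cfg)


class TestCellTypes:
    def test_planted_concentration(self):
        cfg = SimulationConfig(**SMALL, seed=4)
        prof, truth = generate_celltype_profiles(cfg)
        assert list(prof.columns) == list(CELL_TYPES)
        assert (prof.to_numpy() >= 0).all()
        neurons = truth.celltype_label[
            truth.celltype_label == "neurons"
        ].index
        sub = prof.loc[neurons]
        assert (
            sub["neurons"] > sub.drop(columns="neurons").max(axis=1)
        ).all()

    def test_explicit_specific_map(self):
        cfg = SimulationConfig(**SMALL, seed=5)
        prof, truth = generate_celltype_profiles(
            cfg, specific={"microglia": ["G00003"]}
        )
        assert truth.celltype_label["G00003"] == "microglia"
        row = prof.loc["G00003"]
        assert row["microglia"] == row.max()

    def test_unknown_type_errors(self):
        cfg = SimulationConfig(**SMALL)
        with pytest.raises(ValueError, match="unknown cell type"):
            generate_celltype_profiles(cfg, specific={"bogus": ["G00001"]})


def test_stage_streams_are_independent():
    cfg = SimulationConfig(**SMALL, seed=7)
    e1 = simulate.stage_rng(7, "expression").normal(size=5)
    generate_cohort(cfg)  # consuming the cohort stream must not shift others
    e2 = simulate.stage_rng(7, "expression").normal(size=5)
    np.testing.assert_array_equal(e1, e2)
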