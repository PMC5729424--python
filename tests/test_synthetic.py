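import numpy as np
import pandas as pd
import pytest

import envscreen as es
from envscreen.simulate import _zip_blocks
from envscreen.transforms import apply_schema


def _transformed_corr(land, schema, cols):
    t = apply_schema(land.indicator_table, schema)
    return t[cols].corr()


class TestIndicators:
    def test_identity_corr_gives_independence(self, schema):
        names = schema.names[:8]
        ident = pd.DataFrame(np.eye(8), index=names, columns=names)
        cfg = es.SyntheticConfig(n_rows=50, n_cols=40, target_corr=ident,
                                 missing_rate=0.0, seed=0)
        land = es.generate_indicators(cfg)
        corr = _transformed_corr(land, schema, names).to_numpy()
        off = corr[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08  # ~3.5/sqrt(2000)

    def test_strong_pair_correlation_reproduced(self, schema):
        # poverty-education r = 0.82 in the default target matrix
        cfg = es.SyntheticConfig(n_rows=64, n_cols=63, missing_rate=0.0, seed=1)
        land = es.generate_indicators(cfg)
        corr = _transformed_corr(land, schema, ["poverty", "education"])
        assert corr.loc["poverty", "education"] == pytest.approx(0.82, abs=0.05)

    def test_copula_mean_absolute_deviation_small(self, schema):
        cfg = es.SyntheticConfig(n_rows=64, n_cols=63, missing_rate=0.0, seed=2)
        land = es.generate_indicators(cfg)
        target = land.truth["repaired_corr"]
        emp = _transformed_corr(land, schema, list(target.columns)).to_numpy()
        diff = np.abs(emp - target.to_numpy())
        mask = ~np.eye(len(target), dtype=bool)
        assert diff[mask].mean() < 0.05

    def test_missing_rate_zero_means_imputation_noop(self, schema):
        cfg = es.SyntheticConfig(n_rows=12, n_cols=12, missing_rate=0.0, seed=3)
        land = es.generate_indicators(cfg)
        cols = schema.names
        assert land.indicator_table[cols].notna().all().all()
        t = apply_schema(land.indicator_table, schema)[cols]
        completed, imp = es.impute_iterative(t)
        pd.testing.assert_frame_equal(completed, t)
        m1 = es.CorrelationPCA().fit(completed)
        m2 = es.CorrelationPCA().fit(t)
        pd.testing.assert_frame_equal(m1.loadings_, m2.loadings_)

    def test_missingness_rate_honored(self, schema):
        cfg = es.SyntheticConfig(n_rows=40, n_cols=40, missing_rate=0.1, seed=4)
        land = es.generate_indicators(cfg)
        frac = land.indicator_table[schema.names].isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_invalid_corr_rejected(self, schema):
        names = schema.names[:3]
        bad = pd.DataFrame(np.array([[1.0, 0.5, 0.1],
                                     [0.4, 1.0, 0.2],
                                     [0.1, 0.2, 1.0]]),
                           index=names, columns=names)
        cfg = es.SyntheticConfig(n_rows=5, n_cols=5, target_corr=bad, seed=0)
        with pytest.raises(ValueError, match="symmetric"):
            es.generate_indicators(cfg)

    def test_pd_repair_flags_large_changes(self):
        arr = np.array([[1.0, 0.95, -0.95],
                        [0.95, 1.0, 0.95],
                        [-0.95, 0.95, 1.0]])  # badly indefinite
        rep, delta = es.nearest_positive_definite(arr)
        assert np.linalg.eigvalsh(rep).min() >= 1e-9
        assert np.allclose(np.diag(rep), 1.0)
        assert delta > 0.1  # would be recorded as a repair warning
        cfg = es.SyntheticConfig(
            n_rows=4, n_cols=4, seed=0,
            target_corr=pd.DataFrame(arr, index=["ozone", "pm25", "poverty"],
                                     columns=["ozone", "pm25", "poverty"]))
        land = es.generate_indicators(cfg)
        assert land.truth["repair_warning"]

    def test_default_matrix_repair_is_gentle(self):
        rep, delta = es.nearest_positive_definite(
            es.default_target_corr().to_numpy())
        assert delta < 0.1

    def test_determinism_bit_identical(self):
        cfg = es.SyntheticConfig(n_rows=8, n_cols=8, seed=9)
        l1 = es.generate_indicators(cfg)
        l2 = es.generate_indicators(cfg)
        pd.testing.assert_frame_equal(l1.indicator_table, l2.indicator_table)
        r1, z1 = es.generate_disease(l1, cfg)
        r2, z2 = es.generate_disease(l2, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(z1, z2)


class TestGeography:
    def test_every_tract_maps_to_one_contiguous_zip(self, small_landscape):
        _, land, _, _ = small_landscape
        za = land.zip_assignment
        assert za.notna().all()
        assert set(za.index) == set(land.indicator_table.index)
        # contiguity: within each zip, tracts form one rook-connected block
        rook = land.tract_weights(scheme="rook")
        for zid, members in za.groupby(za).groups.items():
            members = set(members)
            seen = {next(iter(members))}
            frontier = list(seen)
            while frontier:
                cur = frontier.pop()
                for nb in rook.neighbors[cur]:
                    if nb in members and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            assert seen == members, f"zip {zid} not contiguous"

    def test_zip_blocks_absorb_remainder(self):
        labels = _zip_blocks(2, 7, 3)
        assert len(labels) == 14
        # each row: zips of size 3, 3, and 1 absorbed -> 3,4
        row0 = labels[:7]
        assert row0.count("z0_0") == 3 and row0.count("z0_1") == 4

    def test_zip_weights_projected_from_tract_adjacency(self, small_landscape):
        _, land, _, _ = small_landscape
        zw = land.zip_weights()
        assert zw.n == land.zip_assignment.nunique()
        assert not zw.islands
        mat = zw.binary_dense()
        assert np.allclose(mat, mat.T)

    def test_geometry_export_matches_units(self, small_landscape):
        _, land, _, _ = small_landscape
        geo = land.tract_geometry()
        assert len(geo["features"]) == len(land.indicator_table)
        props = geo["features"][0]["properties"]
        assert {"tract_id", "zip_id"} <= set(props)


class TestDisease:
    def test_flat_surface_when_no_signal(self):
        cfg = es.SyntheticConfig(n_rows=40, n_cols=40, tracts_per_zip=4,
                                 beta_true={}, lambda_true=0.0,
                                 sigma_eps=0.02, pop_range=(2000, 4000), seed=5)
        land = es.generate_indicators(cfg)
        _, _ = es.generate_disease(land, cfg)
        rate = land.truth["rate"]
        assert rate.std() / rate.mean() < 0.1

    def test_dedup_count_equals_record_count(self):
        cfg = es.SyntheticConfig(n_rows=10, n_cols=10, tracts_per_zip=4,
                                 multi_category_rate=0.3, seed=6)
        land = es.generate_indicators(cfg)
        records, _ = es.generate_disease(land, cfg)
        counts = es.count_events(records)
        assert counts.sum() == len(records)
        flag_total = records[list(es.CATEGORIES)].to_numpy().sum()
        assert flag_total > len(records)  # multi-category flags exist

    def test_multi_category_fraction_near_target(self):
        cfg = es.SyntheticConfig(n_rows=14, n_cols=14, tracts_per_zip=4,
                                 multi_category_rate=0.3,
                                 pop_range=(1000, 2000), seed=7)
        land = es.generate_indicators(cfg)
        records, _ = es.generate_disease(land, cfg)
        assert len(records) > 5000
        frac = (records[list(es.CATEGORIES)].sum(axis=1) >= 2).mean()
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_over65_negatively_tracks_combined_factor(self):
        cfg = es.SyntheticConfig(n_rows=40, n_cols=40, tracts_per_zip=4, seed=8)
        land = es.generate_indicators(cfg)
        _, zip_table = es.generate_disease(land, cfg)
        r = np.corrcoef(land.truth["zip_pc1"],
                        zip_table["over65"].to_numpy())[0, 1]
        assert r == pytest.approx(-0.45, abs=0.1)

    def test_spatial_signal_detected_when_lambda_positive(self):
        hits = 0
        for seed in range(10):
            cfg = es.SyntheticConfig(n_rows=48, n_cols=48, tracts_per_zip=4,
                                     lambda_true=0.6, pop_range=(200, 400),
                                     seed=seed)
            land = es.generate_indicators(cfg)
            es.generate_disease(land, cfg)
            y = land.truth["transformed_burden"].to_numpy()
            res = es.morans_i(y, land.zip_weights(), n_perm=199, seed=seed)
            hits += res.p_value < 0.01
        assert hits >= 9

    def test_lambda_zero_gives_uniform_moran_p(self):
        ps = []
        for seed in range(120):
            cfg = es.SyntheticConfig(n_rows=10, n_cols=10, tracts_per_zip=4,
                                     lambda_true=0.0, pop_range=(100, 200),
                                     seed=seed)
            land = es.generate_indicators(cfg)
            es.generate_disease(land, cfg)
            y = land.truth["transformed_burden"].to_numpy()
            ps.append(es.morans_i(y, land.zip_weights(),
                                  n_perm=199, seed=seed).p_value)
        import scipy.stats

        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_full_pipeline_parameter_recovery(self):
        """Generator + burden + SAR fit recovers the generating parameters."""
        lam_ok = beta_ok = 0
        n_rep = 20
        for seed in range(n_rep):
            # 40x40 tracts in 4-tract strips -> a 20x20-scale field of 400 zips
            cfg = es.SyntheticConfig(n_rows=40, n_cols=40, tracts_per_zip=4,
                                     lambda_true=0.6,
                                     beta_true={"PC1all": 0.5, "Over65": 0.6},
                                     pop_range=(150, 350),
                                     missing_rate=0.0, seed=seed)
            land = es.generate_indicators(cfg)
            records, zip_table = es.generate_disease(land, cfg)
            counts = es.count_events(records)
            db = es.build_burden(counts, zip_table["population"],
                                 over65=zip_table["over65"])
            w = land.zip_weights()
            y = es.standardize(db["transformed"].reindex(w.ids).to_numpy())
            x = pd.DataFrame({
                "PC1all": land.truth["zip_pc1"].reindex(w.ids).to_numpy(),
                "Over65": land.truth["zip_over65_pred"].reindex(w.ids).to_numpy(),
            })
            fit = es.sar_error_fit(y, x, w)
            sd_y = land.truth["transformed_burden"].std() / cfg.burden_scale
            lam_ok += abs(fit.lambda_ - 0.6) <= 0.15
            ok = all(abs(fit.coef_[i] - [0.5, 0.6][i] / sd_y) <= 2 * fit.stderr_[i]
                     for i in range(2))
            beta_ok += ok
        assert lam_ok >= 0.9 * n_rep
        assert beta_ok >= 0.9 * n_rep
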