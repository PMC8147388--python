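"""Preprocessing chain: log2 transform, background filter, quantile
normalization (with hand oracle), and ComBat batch adjustment (with
scanpy as the independent reference implementation)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnctox.core import LnctoxError
from lnctox.preprocess import (
    BackgroundRule,
    adjust_batch,
    background_filter,
    log2_transform,
    quantile_normalize,
)
from lnctox.simulate import simulate_experiment

from conftest import make_expr, make_two_group_design, small_config


class TestLog2:
    def test_known_values(self):
        m = make_expr([[8.0, 1.0]], scale="raw")
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert out.scale == "log2"

    def test_fold_change_arithmetic(self):
        """A 1.5-fold intensity ratio is a log2 difference of 0.58 (2 dp)."""
        m = make_expr([[100.0, 150.0]], scale="raw")
        out = log2_transform(m)
        diff = out.values.iloc[0, 1] - out.values.iloc[0, 0]
        assert round(diff, 2) == 0.58

    def test_nonpositive_errors_with_location(self):
        m = make_expr([[1.0, -2.0]], scale="raw")
        with pytest.raises(LnctoxError, match="p0.*s1"):
            log2_transform(m)


def _bg_matrix(values_by_probe, n_neg=20, neg_level=5.0):
    """Matrix with controllable true-probe rows plus flat negative controls."""
    n_samples = len(next(iter(values_by_probe.values())))
    rows, biotypes, ids = [], [], []
    for pid, vals in values_by_probe.items():
        rows.append(vals)
        biotypes.append("mRNA")
        ids.append(pid)
    rng = np.random.default_rng(0)
    for i in range(n_neg):
        rows.append(neg_level + 0.1 * rng.standard_normal(n_samples))
        biotypes.append("negative_control")
        ids.append(f"neg{i}")
    return make_expr(np.array(rows), biotypes=biotypes, probe_ids=ids)


class TestBackgroundFilter:
    def test_above_everywhere_retained_and_zero_removed(self):
        m = _bg_matrix({"hi": [9.0] * 4, "lo": [1.0] * 4})
        out = background_filter(m)
        assert list(out.values.index) == ["hi"]

    def test_exactly_half_is_retained(self):
        """'At least half' is inclusive on an even sample count."""
        m = _bg_matrix({"half": [9.0, 9.0, 1.0, 1.0]})
        out = background_filter(m)
        assert "half" in out.values.index

    def test_just_under_half_removed(self):
        m = _bg_matrix({"under": [9.0, 1.0, 1.0, 1.0]})
        assert len(background_filter(m).values.index) == 0

    def test_negative_controls_removed_from_output(self):
        m = _bg_matrix({"hi": [9.0] * 4})
        assert not (background_filter(m).biotype == "negative_control").any()

    def test_no_negative_controls_errors(self):
        m = make_expr([[9.0, 9.0]])
        with pytest.raises(LnctoxError, match="negative-control"):
            background_filter(m)

    def test_monotone_in_quantile(self):
        """Raising the background quantile never retains more probes."""
        rng = np.random.default_rng(1)
        m = _bg_matrix(
            {f"p{i}": 5.0 + rng.normal(0.3, 0.6, 6) for i in range(40)}, n_neg=30
        )
        kept = [
            len(background_filter(m, BackgroundRule(method="quantile", q=q)).values)
            for q in (0.5, 0.7, 0.9, 0.99)
        ]
        assert kept == sorted(kept, reverse=True)


class TestQuantileNormalize:
    def test_hand_oracle_3x2(self):
        m = make_expr([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = quantile_normalize(m).values.to_numpy()
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
        assert np.allclose(out, expected)

    def test_identical_columns_fixed_point(self):
        X = np.array([[1.0, 1.0], [4.0, 4.0], [2.0, 2.0]])
        out = quantile_normalize(make_expr(X)).values.to_numpy()
        assert np.allclose(out, X)

    def test_ties_get_mean_of_spanned_quantiles(self):
        # column 0 has a tie at value 1 spanning the two lowest quantiles
        m = make_expr([[1.0, 2.0], [1.0, 4.0], [5.0, 6.0]])
        out = quantile_normalize(m).values.to_numpy()
        ref = np.array([1.5, 2.5, 5.5])  # row means of sorted columns
        assert np.allclose(out[:, 0], [2.0, 2.0, 5.5])  # mean(1.5, 2.5) = 2.0
        assert np.allclose(np.sort(out[:, 1]), ref)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 30), st.integers(2, 6))
    def test_columns_share_sorted_values_and_ranks_preserved(self, seed, n, s):
        rng = np.random.default_rng(seed)
        X = rng.normal(8, 2, (n, s))
        out = quantile_normalize(make_expr(X)).values.to_numpy()
        for j in range(1, s):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))
        for j in range(s):
            a = np.argsort(X[:, j], kind="stable")
            assert np.all(np.diff(out[a, j]) >= -1e-12)


class TestAdjustBatch:
    def _sim_with_batch(self, seed=0, batch_shift=1.0):
        rng = np.random.default_rng(seed)
        n_probes, n = 150, 24
        group = np.array((["A"] * 6 + ["B"] * 6) * 2)
        batch = np.array(["X"] * 12 + ["Y"] * 12)
        X = 8.0 + rng.normal(0, 1, (n_probes, 1)) + rng.normal(0, 0.3, (n_probes, n))
        X[:30, group == "B"] += 1.0
        X[:, batch == "Y"] += batch_shift
        m = make_expr(X)
        design = pd.DataFrame(
            {
                "sample_id": m.values.columns,
                "material": group,
                "surface": "Core",
                "dispersant": "PBS",
                "batch_label": batch,
                "batch_array": "A1",
                "replicate": 1,
                "group": group,
            }
        )
        return m, design, batch, group

    def test_single_batch_level_is_identity(self):
        m, design, *_ = self._sim_with_batch()
        out = adjust_batch(m, design, "batch_array", preserve="group")
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-10)

    def test_planted_shift_removed(self):
        m, design, batch, _ = self._sim_with_batch(batch_shift=1.0)
        out = adjust_batch(m, design, "batch_label", preserve="group")
        X = out.values.to_numpy()
        diff = X[:, batch == "Y"].mean(axis=1) - X[:, batch == "X"].mean(axis=1)
        assert np.abs(diff).mean() <= 0.1

    def test_group_effect_preserved(self):
        m, design, _, group = self._sim_with_batch(batch_shift=1.5)
        out = adjust_batch(m, design, "batch_label", preserve="group")
        X = out.values.to_numpy()
        effect = X[:30, group == "B"].mean() - X[:30, group == "A"].mean()
        assert 0.9 <= effect <= 1.1  # planted 1.0, recovered within 10%

    def test_approximately_idempotent(self):
        m, design, *_ = self._sim_with_batch(batch_shift=1.0)
        once = adjust_batch(m, design, "batch_label", preserve="group")
        twice = adjust_batch(once, design, "batch_label", preserve="group")
        delta = np.abs(twice.values.to_numpy() - once.values.to_numpy())
        assert delta.mean() <= 0.05

    def test_matches_scanpy_combat(self):
        import anndata as ad
        import scanpy as sc

        m, design, batch, group = self._sim_with_batch(batch_shift=0.8)
        mine = adjust_batch(m, design, "batch_label", preserve="group")
        adata = ad.AnnData(
            m.values.to_numpy().T.copy(),
            obs=pd.DataFrame(
                {"batch": batch, "g": (group == "B").astype(float)},
                index=list(m.values.columns),
            ),
        )
        sc.pp.combat(adata, key="batch", covariates=["g"])
        assert np.abs(mine.values.to_numpy() - adata.X.T).max() < 5e-3

    def test_confounded_batch_errors(self):
        m, design, *_ = self._sim_with_batch()
        design = design.copy()
        design["batch_label"] = np.where(design["group"] == "A", "X", "Y")
        with pytest.raises(LnctoxError, match="confounded"):
            adjust_batch(m, design, "batch_label", preserve="group")

    def test_singleton_batch_errors(self):
        m, design, *_ = self._sim_with_batch()
        design = design.copy()
        design.loc[0, "batch_label"] = "Z"
        with pytest.raises(LnctoxError, match="single sample"):
            adjust_batch(m, design, "batch_label", preserve="group")


def test_chain_recovers_planted_de_effect(preprocessed):
    """After filter/normalize/batch adjustment the planted group effect
    survives within 10% on average."""
    m, design, truth, cfg = preprocessed
    group = "CuO-Core"
    exp = design.loc[design["group"] == group, "sample_id"]
    ctrl = design.loc[design["group"] == "control-PBS", "sample_id"]
    planted = {
        p: fc for p, fc in truth.de_probes[group].items() if p in m.values.index
    }
    assert len(planted) > 10
    X = m.values
    est = X[list(exp)].mean(axis=1) - X[list(ctrl)].mean(axis=1)
    ratio = np.mean([est[p] / fc for p, fc in planted.items()])
    assert 0.9 <= ratio <= 1.1
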