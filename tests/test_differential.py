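import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirdep import GeneratorParams, adjust_bh, call_signature, contrast, generate_expression

from conftest import group_sheet, toy_matrix

TWO_GROUP_SHEET = group_sheet(
    {
        "a1": ("WT", "M1"), "a2": ("WT", "M1"), "a3": ("WT", "M1"),
        "b1": ("WT", "M0"), "b2": ("WT", "M0"), "b3": ("WT", "M0"),
    }
)


def bh_oracle(p):
    """Direct enumeration of the step-up formula (independent of statsmodels)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestContrast:
    def test_identical_means_give_unit_fc_and_p_one(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        res = contrast(m, ("WT", "M1"), ("WT", "M0"))
        assert res.fc.iloc[0] == pytest.approx(1.0)
        assert res.p_raw.iloc[0] == pytest.approx(1.0)

    def test_unit_log2_difference_doubles(self):
        values = np.array([[3.0, 3.1, 2.9, 2.0, 2.1, 1.9]])
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        res = contrast(m, ("WT", "M1"), ("WT", "M0"))
        assert res.fc.iloc[0] == pytest.approx(2.0)

    def test_p_matches_textbook_t_cdf_oracle(self):
        """100-probe fixture vs a per-probe pooled-t computation (+-1e-12)."""
        rng = np.random.default_rng(42)
        values = rng.normal(7.0, 1.0, size=(100, 6))
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        res = contrast(m, ("WT", "M1"), ("WT", "M0"))
        a, b = values[:, :3], values[:, 3:]
        for i in range(100):
            na, nb = 3, 3
            sp2 = ((na - 1) * a[i].var(ddof=1) + (nb - 1) * b[i].var(ddof=1)) / (na + nb - 2)
            t = (a[i].mean() - b[i].mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
            assert res.p_raw.iloc[i] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_probe_flagged_not_nan(self):
        values = np.array([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]])
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        res = contrast(m, ("WT", "M1"), ("WT", "M0"))
        assert res.p_raw.iloc[0] == 0.0  # means differ, no variance
        assert res.p_raw.iloc[1] == 1.0  # identical everywhere

    def test_small_group_rejected(self):
        sheet = group_sheet({"a1": ("WT", "M1"), "b1": ("WT", "M0"), "b2": ("WT", "M0")})
        m = toy_matrix(np.zeros((2, 3)), samples=list(sheet.index), sheet=sheet)
        with pytest.raises(ValueError, match=">=2"):
            contrast(m, ("WT", "M1"), ("WT", "M0"))

    def test_reciprocal_fold_changes_multiply_to_one(self, small_study):
        matrix, _, _ = small_study
        ab = contrast(matrix, ("WT", "M1"), ("WT", "M0"))
        ba = contrast(matrix, ("WT", "M0"), ("WT", "M1"))
        assert np.allclose(ab.fc * ba.fc, 1.0)


class TestAdjustBH:
    def test_step_up_worked_example(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_degenerate_inputs(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert adjust_bh([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_enumeration_oracle(self, p):
        adjusted = adjust_bh(p)
        assert adjusted == pytest.approx(bh_oracle(p), abs=1e-12)
        assert np.all(adjusted >= np.asarray(p) - 1e-15)
        # monotone: adjusted ordering never inverts the raw ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


class TestCallSignature:
    def test_all_unit_fc_gives_empty_signature(self):
        values = np.tile([5.0, 5.1, 4.9], (10, 2))
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        sig = call_signature(contrast(m, ("WT", "M1"), ("WT", "M0")))
        assert len(sig) == 0

    def test_boundary_fc_is_inclusive(self):
        table = pd.DataFrame(
            {"fc": [2.0, 0.5, 1.0], "p_raw": [0.01, 0.01, 0.01], "p_adj": [0.01, 0.01, 0.01]},
            index=["up_gene", "down_gene", "flat"],
        )
        from mirdep.differential import ContrastResult

        res = ContrastResult(label="toy", table=table, n_a=3, n_b=3)
        sig = call_signature(res)
        assert "up_gene" in sig.up and "down_gene" in sig.down and len(sig) == 2
        strict = call_signature(res, inclusive=False)
        assert len(strict) == 0

    def test_invalid_thresholds_rejected(self, small_contrasts):
        with pytest.raises(ValueError):
            call_signature(small_contrasts["wt"], up_threshold=0.9)

    def test_planted_fourfold_probes_recovered(self):
        """50 planted 4-fold-up probes among noise: >=45 called up, none down."""
        rng = np.random.default_rng(5)
        n = 500
        values = rng.normal(7.0, 0.25, size=(n, 6))
        values[:50, :3] += 2.0  # 4-fold up in group A
        m = toy_matrix(values, samples=list(TWO_GROUP_SHEET.index), sheet=TWO_GROUP_SHEET)
        sig = call_signature(contrast(m, ("WT", "M1"), ("WT", "M0")))
        planted = {f"p{i}" for i in range(50)}
        assert len(planted & set(sig.up.members)) >= 45
        assert not planted & set(sig.down.members)

    def test_alpha_one_classifies_every_probe_disjointly(self, small_contrasts):
        eps = 1e-9
        sig = call_signature(
            small_contrasts["wt"], up_threshold=1 + eps, down_threshold=1 - eps, alpha=1.0 + eps
        )
        res = small_contrasts["wt"]
        off_boundary = (res.fc - 1.0).abs() > eps
        assert not set(sig.up.members) & set(sig.down.members)
        assert len(sig) >= int(off_boundary.sum())

    def test_null_type_one_error_calibrated(self):
        """Pure-noise generation: fraction with p_raw < 0.05 is 0.05 +- 0.01."""
        for seed in (1, 2, 3):
            params = GeneratorParams(
                n_probes=10_000, fraction_induced=0.0, fraction_repressed=0.0,
                n_targets=0, seed=seed,
            )
            matrix, _, _ = generate_expression(params)
            res = contrast(matrix, ("WT", "M1"), ("WT", "M0"))
            frac = float((res.p_raw < 0.05).mean())
            assert 0.04 <= frac <= 0.06
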