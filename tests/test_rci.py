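import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st
from scipy import stats

from cogrci.battery import PARAMETER_NAMES
from cogrci.rci import (
    ControlReference,
    UnclassifiableError,
    ZPanel,
    classify,
    classify_frame,
    fit_control_reference,
    null_false_positive_rate,
    zscore_baseline,
    zscore_change,
    zscore_frame,
)

PARAMS = list(PARAMETER_NAMES)


def _frames(change_first_param, n=3, fill=None):
    """Control frames where the first parameter is given and others vary."""
    rng = np.random.default_rng(99)
    data = {p: rng.normal(0, 1, n) for p in PARAMS}
    data[PARAMS[0]] = np.asarray(change_first_param, dtype=float)
    if fill is not None:
        for p in PARAMS[1:]:
            data[p] = np.full(n, fill) + rng.normal(0, 1, n)
    return pd.DataFrame(data)


class TestFitControlReference:
    def test_hand_computed_moments(self):
        # sample SD of {0, 1, 2} is 1 (n-1 denominator)
        change = _frames([0.0, 1.0, 2.0])
        baseline = _frames([5.0, 6.0, 7.0])
        ref = fit_control_reference(change, baseline)
        assert ref.mean_change[PARAMS[0]] == pytest.approx(1.0)
        assert ref.sd_change[PARAMS[0]] == pytest.approx(1.0)
        assert ref.mean_baseline[PARAMS[0]] == pytest.approx(6.0)
        assert ref.n_control == 3

    def test_zero_variance_rejected(self):
        change = _frames([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero control variance"):
            fit_control_reference(change, _frames([0.0, 1.0, 2.0]))

    def test_sum_scaling_near_sqrt7_for_independent_normals(self, iid_normal_reference):
        assert iid_normal_reference.sd_sum_z_change == pytest.approx(math.sqrt(7), rel=0.05)
        assert iid_normal_reference.sd_sum_z_baseline == pytest.approx(math.sqrt(7), rel=0.05)

    def test_json_round_trip(self, tmp_path, iid_normal_reference):
        path = tmp_path / "ref.json"
        iid_normal_reference.to_json(path)
        back = ControlReference.from_json(path)
        assert back.mean_change == iid_normal_reference.mean_change
        assert back.sd_sum_z_change == iid_normal_reference.sd_sum_z_change
        # cached subset scalings survive the round trip
        key = "|".join(sorted(PARAMS))
        assert back.subset_scalings_change[key] == pytest.approx(
            iid_normal_reference.sd_sum_z_change
        )


class TestZScoring:
    def test_centering_gives_zero(self, unit_reference):
        vec = {p: 0.0 for p in PARAMS}
        panel = zscore_change(vec, unit_reference)
        assert all(v == pytest.approx(0.0) for v in panel.z.values())
        assert panel.composite_z == pytest.approx(0.0)
        assert panel.n_available == 7

    def test_direct_substitution_change(self, unit_reference):
        # control mean_change 1, sd 1, patient delta -1.5 -> z = 2.5
        ref = unit_reference
        ref.mean_change = {p: 1.0 for p in PARAMS}
        vec = {p: -1.5 if p == PARAMS[0] else 1.0 for p in PARAMS}
        panel = zscore_change(vec, ref)
        assert panel.z[PARAMS[0]] == pytest.approx(2.5)
        assert all(panel.z[p] == pytest.approx(0.0) for p in PARAMS[1:])

    def test_direct_substitution_baseline(self, unit_reference):
        ref = unit_reference
        ref.mean_baseline = {p: 10.0 for p in PARAMS}
        ref.sd_baseline = {p: 2.0 for p in PARAMS}
        vec = {p: 10.0 for p in PARAMS} | {PARAMS[2]: 5.0}
        panel = zscore_baseline(vec, ref)
        assert panel.z[PARAMS[2]] == pytest.approx(2.5)

    def test_improvement_never_impairs(self, unit_reference):
        vec = {p: 10.0 for p in PARAMS}  # far above control mean change of 0
        panel = zscore_change(vec, unit_reference)
        assert all(v < 0 for v in panel.z.values())
        assert panel.composite_z < 0
        assert not classify(panel).impaired

    def test_too_many_missing_unclassifiable(self, unit_reference):
        vec = {p: 0.0 for p in PARAMS[:4]} | {p: None for p in PARAMS[4:]}
        panel = zscore_baseline(vec, unit_reference)
        assert panel.composite_z is None
        assert panel.n_available == 4
        with pytest.raises(UnclassifiableError):
            classify(panel)

    def test_subset_renormalization_keeps_null_sd_one(self, iid_normal_reference):
        # z-score iid N(0,1) subjects with 2 items missing: composite SD ~ 1
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.standard_normal((4000, 7)), columns=PARAMS)
        frame[PARAMS[1]] = np.nan
        frame[PARAMS[5]] = np.nan
        z = zscore_frame(frame, iid_normal_reference, "change")
        assert z["composite_z"].std(ddof=1) == pytest.approx(1.0, rel=0.05)


class TestClassify:
    def _panel(self, z_values, composite):
        z = {p: z_values.get(p) for p in PARAMS}
        return ZPanel("s", z, composite, sum(v is not None for v in z.values()))

    def test_composite_only(self):
        panel = self._panel({p: 0.0 for p in PARAMS}, 2.5)
        label = classify(panel)
        assert label.impaired and label.criterion == "composite_only"

    def test_multi_test_only(self):
        z = {p: 0.0 for p in PARAMS}
        z[PARAMS[0]] = 2.0
        z[PARAMS[1]] = 2.0
        label = classify(self._panel(z, 1.5))
        assert label.impaired and label.criterion == "multi_test_only"

    def test_boundary_strict(self):
        # one individual hit and composite exactly at threshold: not impaired
        z = {p: 0.0 for p in PARAMS}
        z[PARAMS[0]] = 3.5
        label = classify(self._panel(z, 1.96))
        assert not label.impaired and label.criterion == "none"

    def test_both_clauses(self):
        z = {p: 3.0 for p in PARAMS}
        label = classify(self._panel(z, 5.0))
        assert label.criterion == "both"

    def test_outcome_kind_passthrough(self):
        label = classify(self._panel({p: 0.0 for p in PARAMS}, 0.0), outcome_kind="preCI")
        assert label.outcome_kind == "preCI"


def brute_force_classify(z_values, composite, threshold=1.96):
    """Independent oracle: literal restatement of the two-clause rule."""
    hits = [v for v in z_values if v is not None and v > threshold]
    clause_composite = composite is not None and composite > threshold
    clause_multi = len(hits) >= 2
    return clause_composite or clause_multi


class TestOracleEquivalence:
    def test_exhaustive_grid(self, unit_reference):
        grid = [-1.0, 1.96, 2.5]
        missing_patterns = [
            pat for pat in itertools.product([True, False], repeat=7) if sum(pat) >= 5
        ]
        for values in itertools.product(grid, repeat=3):
            # first three parameters take grid values, rest fixed at 0
            base = list(values) + [0.0] * 4
            for pat in missing_patterns[:: 7]:  # stride to keep runtime modest
                vec = {p: (base[i] if pat[i] else None) for i, p in enumerate(PARAMS)}
                panel = zscore_change({k: (None if v is None else -v) for k, v in vec.items()}, unit_reference)
                # unit reference: z = -x, so feed -v to get z == v
                expected = brute_force_classify(
                    [panel.z[p] for p in PARAMS], panel.composite_z
                )
                assert classify(panel).impaired == expected

    @given(
        st.lists(st.floats(-4, 4), min_size=7, max_size=7),
        st.floats(-4, 4),
    )
    def test_random_panels_match_oracle(self, zs, composite):
        panel = ZPanel("s", dict(zip(PARAMS, zs)), composite, 7)
        assert classify(panel).impaired == brute_force_classify(zs, composite)


class TestMonotonicity:
    @settings(max_examples=50, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        deltas=st.lists(st.floats(-3, 3), min_size=7, max_size=7),
        idx=st.integers(min_value=0, max_value=6),
        worsen=st.floats(min_value=0.01, max_value=5),
    )
    def test_worsening_never_unimpairs(self, unit_reference, deltas, idx, worsen):
        vec = dict(zip(PARAMS, deltas))
        panel = zscore_change(vec, unit_reference)
        worse_vec = dict(vec)
        worse_vec[PARAMS[idx]] -= worsen
        worse = zscore_change(worse_vec, unit_reference)
        assert worse.z[PARAMS[idx]] >= panel.z[PARAMS[idx]]
        assert all(worse.z[p] == pytest.approx(panel.z[p]) for p in PARAMS if p != PARAMS[idx])
        assert worse.composite_z >= panel.composite_z
        if classify(panel).impaired:
            assert classify(worse).impaired


class TestControlSelfConsistency:
    def test_controls_zscore_to_standard_moments(self, iid_normal_reference):
        ref = iid_normal_reference
        z = ref._z_change
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)
        composite = z.sum(axis=1) / ref.sd_sum_z_change
        assert composite.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_self_zscore_via_public_api(self):
        rng = np.random.default_rng(11)
        change = pd.DataFrame(rng.standard_normal((500, 7)) * 2 + 0.3, columns=PARAMS)
        baseline = pd.DataFrame(rng.standard_normal((500, 7)), columns=PARAMS)
        ref = fit_control_reference(change, baseline)
        z = zscore_frame(change, ref, "change")
        assert np.allclose(z[PARAMS].mean(), 0.0, atol=1e-10)
        assert np.allclose(z[PARAMS].std(ddof=1), 1.0, atol=1e-10)
        assert z["composite_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestNullFalsePositiveRate:
    def test_huge_threshold_rate_zero(self):
        assert null_false_positive_rate(7, threshold=50.0, n_sims=2000, seed=0) == 0.0

    def test_multi_clause_matches_binomial_closed_form(self):
        # oracle: P(>=2 of 7 exceed) with p = P(Z > 1.96)
        p = stats.norm.sf(1.96)
        expected = 1 - (1 - p) ** 7 - 7 * p * (1 - p) ** 6
        n = 100_000
        rate = null_false_positive_rate(7, 1.96, n, seed=3, composite_clause=False)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * se
        assert expected == pytest.approx(0.0121, abs=2e-4)

    def test_full_rule_rate_in_band(self):
        rate = null_false_positive_rate(7, 1.96, 100_000, seed=4)
        assert 0.02 < rate < 0.05

    def test_n_sims_floor(self):
        with pytest.raises(ValueError):
            null_false_positive_rate(7, n_sims=10)


class TestClassifyFrame:
    def test_matches_scalar_classify(self, iid_normal_reference):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.standard_normal((200, 7)) * 2, columns=PARAMS)
        frame.iloc[0, :3] = np.nan  # unclassifiable row (4 available)
        z = zscore_frame(frame, iid_normal_reference, "change")
        labels = classify_frame(z)
        assert labels["criterion"].iloc[0] == "unclassifiable"
        assert pd.isna(labels["impaired"].iloc[0])
        for i in range(1, 200):
            panel = zscore_change(frame.iloc[i].to_dict(), iid_normal_reference)
            assert labels["impaired"].iloc[i] == classify(panel).impaired
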