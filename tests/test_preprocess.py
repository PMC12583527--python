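import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mvewas.preprocess import (
    celltype_pca,
    filter_probes_by_detection,
    logit_transform,
    transform_biomarkers,
)


def detp_frame(rows: dict, n_samples: int) -> pd.DataFrame:
    return pd.DataFrame(
        {pid: np.asarray(v, dtype=float) for pid, v in rows.items()},
        index=[f"s{i}" for i in range(n_samples)],
    ).T


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "values,kept",
        [
            # passes all three rules
            ([0.001] * 10, True),
            # mean 0.06 > 0.05 -> mean rule
            ([0.06] * 10, False),
            # 0.2 in exactly half the samples -> half-or-more rule
            ([0.2] * 5 + [0.001] * 5, False),
            # detp >= 0.01 in 3/10 samples (> 20%) -> strict-fraction rule
            ([0.02, 0.02, 0.02] + [0.001] * 7, False),
            # detp >= 0.01 in exactly 2/10 samples (not > 20%) -> kept
            ([0.0099] * 8 + [0.02, 0.02], True),
        ],
    )
    def test_single_probe_rules(self, values, kept):
        detp = detp_frame({"p": values, "anchor": [0.001] * len(values)}, len(values))
        survivors, _ = filter_probes_by_detection(detp)
        assert ("p" in survivors) is kept

    def test_combined_filter_matches_hand_derivation(self):
        n = 10
        rows = {
            "good": [0.001] * n,
            "mean_bad": [0.06] * n,
            "half_bad": [0.2] * 5 + [0.001] * 5,
            "frac_bad": [0.015] * 3 + [0.001] * 7,
            "edge_ok": [0.009] * n,
        }
        survivors, report = filter_probes_by_detection(detp_frame(rows, n))
        assert survivors == ["good", "edge_ok"]
        assert report.n_input == 5 and report.n_kept == 2
        # mean_bad and half_bad both trip rule (i) (means 0.06 and 0.1005);
        # both also exceed 0.05 in >= half the samples, so rule (ii) fires
        # twice; all three removed probes have detp >= 0.01 in > 20% of
        # samples, so rule (iii) fires three times
        assert report.removed_mean_rule == 2
        assert report.removed_half_rule == 2
        assert report.removed_fraction_rule == 3

    def test_survivors_preserve_input_order(self):
        n = 4
        rows = {"b": [0.001] * n, "a": [0.001] * n, "z": [0.06] * n, "c": [0.001] * n}
        survivors, _ = filter_probes_by_detection(detp_frame(rows, n))
        assert survivors == ["b", "a", "c"]

    def test_rule_order_independence(self):
        # rules are row predicates; applying them successively in any order
        # gives the same survivor set as the combined call
        rng = np.random.default_rng(5)
        detp = pd.DataFrame(
            rng.uniform(0, 0.1, size=(50, 12)),
            index=[f"p{i}" for i in range(50)],
        )
        survivors, _ = filter_probes_by_detection(detp)
        vals = detp.to_numpy()
        r1 = vals.mean(axis=1) > 0.05
        r2 = (vals > 0.05).sum(axis=1) >= 6
        r3 = (vals >= 0.01).sum(axis=1) > 0.2 * 12
        for order in [(r1, r2, r3), (r3, r1, r2), (r2, r3, r1)]:
            keep = np.ones(50, dtype=bool)
            for r in order:
                keep &= ~r
            assert list(detp.index[keep]) == survivors

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            filter_probes_by_detection(pd.DataFrame())


class TestLogitTransform:
    def test_known_values(self):
        out = logit_transform(np.array([0.5, 0.75]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(np.log(3.0), abs=1e-12)

    def test_boundary_clipping(self):
        out = logit_transform(np.array([0.0, 1.0]), eps=1e-6)
        expected = np.log((1 - 1e-6) / 1e-6)
        assert out[1] == pytest.approx(expected, abs=1e-9)
        assert out[0] == pytest.approx(-expected, abs=1e-9)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            logit_transform(np.array([-0.1, 0.5]))
        with pytest.raises(ValueError):
            logit_transform(np.array([0.5, 1.1]))

    def test_roundtrip_with_inverse(self, rng):
        b = rng.uniform(1e-4, 1 - 1e-4, size=200)
        assert np.abs(expit(logit_transform(b)) - b).max() < 1e-12

    def test_dataframe_passthrough(self):
        df = pd.DataFrame([[0.5, 0.75]], index=["p"], columns=["s1", "s2"])
        out = logit_transform(df)
        assert list(out.index) == ["p"] and list(out.columns) == ["s1", "s2"]


class TestBiomarkerTransform:
    def test_hand_computed_example(self):
        a, _, _ = transform_biomarkers(
            np.array([100.0, 200.0, 400.0, 800.0]),
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([1.0, 2.0, 3.0, 4.0]),
        )
        expected = np.array([-1.16190, -0.38730, 0.38730, 1.16190])
        np.testing.assert_allclose(a, expected, atol=1e-5)

    def test_identical_tau_gives_zero_difference(self, rng):
        t = rng.lognormal(3, 0.4, size=30)
        _, m, d = transform_biomarkers(rng.lognormal(7, 0.5, 30), t, t)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_proportional_tau(self, rng):
        t = rng.lognormal(3, 0.4, size=30)
        _, m, d = transform_biomarkers(rng.lognormal(7, 0.5, 30), t, 3.7 * t)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        sd_log_t = (np.log(t) - np.log(t).mean()) / np.log(t).std(ddof=1)
        np.testing.assert_allclose(m, sd_log_t, atol=1e-12)

    def test_m_d_exactly_uncorrelated(self, rng):
        _, m, d = transform_biomarkers(
            rng.lognormal(7, 0.6, 200),
            rng.lognormal(3, 0.4, 200),
            rng.lognormal(5.5, 0.4, 200),
        )
        assert abs(np.corrcoef(m, d)[0, 1]) < 1e-10

    def test_moment_contracts(self, rng):
        a, m, _ = transform_biomarkers(
            rng.lognormal(7, 0.6, 100),
            rng.lognormal(3, 0.4, 100),
            rng.lognormal(5.5, 0.4, 100),
        )
        assert abs(a.mean()) < 1e-12 and abs(m.mean()) < 1e-12
        assert a.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_raises(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            transform_biomarkers(np.array([0.0, 2.0, 3.0]), v, v)

    def test_zero_variance_raises(self):
        v = np.array([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            transform_biomarkers(v, v, v)


class TestCelltypePCA:
    def test_two_type_toy(self):
        props = np.array([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        scores, frac = celltype_pca(props, k=1)
        np.testing.assert_allclose(
            scores[:, 0], [0.4 * np.sqrt(2), -0.4 * np.sqrt(2), 0.0], atol=1e-10
        )
        assert frac == pytest.approx(1.0)

    def test_default_three_components(self, small_cohort):
        cols = [c for c in small_cohort.covariates.columns if c.startswith("cell_")]
        scores, frac = celltype_pca(small_cohort.covariates[cols].to_numpy())
        assert scores.shape == (len(small_cohort.covariates), 3)
        assert 0 < frac <= 1

    def test_sign_convention_deterministic(self, rng):
        props = rng.dirichlet(np.ones(5), size=40)
        s1, _ = celltype_pca(props)
        s2, _ = celltype_pca(props[::-1][::-1])  # same data
        np.testing.assert_allclose(s1, s2)

    def test_degenerate_input_raises(self):
        props = np.tile(np.full(4, 0.25), (10, 1))
        with pytest.raises(ValueError):
            celltype_pca(props)
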