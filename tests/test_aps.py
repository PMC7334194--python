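"""APS metric: calibration identity, recovery of injected selection."""
import numpy as np
import pandas as pd
import pytest

from svpopgen import aps as aps_mod
from svpopgen.aps import (
    APSModel, aps, aps_conservation_correlation, aps_full_vs_partial,
    fit_singleton_model,
)


def make_reference(n=2_000, seed=0, singleton_logit=(-1.0, 0.6)):
    """Reference sites whose singleton odds rise with log10 size."""
    rng = np.random.default_rng(seed)
    svtype = rng.choice(["DEL", "DUP", "INS"], size=n)
    svlen = rng.lognormal(np.log(2_000), 1.2, size=n).clip(50, 1e6)
    a, b = singleton_logit
    eta = a + b * (np.log10(svlen) - 3.0) + 0.3 * (svtype == "DEL")
    p = 1 / (1 + np.exp(-eta))
    return pd.DataFrame({
        "sv_id": [f"r{i}" for i in range(n)],
        "svtype": svtype, "svlen": svlen,
        "is_singleton": rng.random(n) < p,
    })


@pytest.fixture(scope="module")
def reference():
    return make_reference()


@pytest.fixture(scope="module")
def model(reference):
    return fit_singleton_model(reference)


class TestFitSingletonModel:
    def test_in_sample_calibration_identity(self, reference, model):
        """ML intercept makes mean prediction equal observed fraction: APS=0."""
        res = aps(reference, model, seed=1)
        assert res.aps == pytest.approx(0.0, abs=1e-10)
        assert res.ci[0] <= 0 <= res.ci[1]

    def test_constant_covariates_reduce_to_intercept(self):
        rng = np.random.default_rng(3)
        sites = pd.DataFrame({
            "svtype": "DEL", "svlen": 1_000.0,
            "is_singleton": rng.random(1_000) < 0.4})
        m = fit_singleton_model(sites)
        frac = sites["is_singleton"].mean()
        pred = m.predict(sites)
        assert np.allclose(pred, frac, atol=1e-8)

    def test_size_coefficient_recovered(self, reference, model):
        assert model.params["log10_svlen"] == pytest.approx(0.6, abs=0.15)

    def test_too_few_reference_sites_rejected(self, reference):
        with pytest.raises(ValueError, match="reference sites"):
            fit_singleton_model(reference.head(100))

    def test_schema_mismatch_detected(self):
        rng = np.random.default_rng(9)
        ref = make_reference(800, seed=9)
        ref["repeat_flag"] = (rng.random(len(ref)) < 0.3).astype(float)
        m = fit_singleton_model(ref, extra_flags=("repeat_flag",))
        with pytest.raises(ValueError, match="covariate"):
            m.predict(make_reference(10, seed=4))  # lacks repeat_flag

    def test_model_json_round_trip(self, model, tmp_path, reference):
        p = tmp_path / "m.json"
        model.to_json(p)
        back = APSModel.from_json(p)
        np.testing.assert_allclose(back.predict(reference), model.predict(reference))


class TestAps:
    def test_injected_singleton_excess_recovered(self, reference, model):
        """Queries with +0.2 singleton excess over matched covariates score ~0.2."""
        rng = np.random.default_rng(7)
        query = make_reference(1_500, seed=11)
        pred = model.predict(query)
        query["is_singleton"] = rng.random(len(query)) < np.clip(pred + 0.2, 0, 1)
        res = aps(query, model, seed=2)
        assert res.ci[0] <= res.aps <= res.ci[1]
        assert res.aps == pytest.approx(0.2, abs=0.05)
        assert res.p_one_tailed < 1e-6

    def test_single_site_degenerate_ci(self, model):
        q = pd.DataFrame({"svtype": ["DEL"], "svlen": [1_000.0],
                          "is_singleton": [True]})
        res = aps(q, model, seed=1)
        assert res.degenerate_ci
        assert res.aps == pytest.approx(1.0 - model.predict(q)[0])

    def test_empty_query_rejected(self, model):
        with pytest.raises(ValueError, match="empty"):
            aps(pd.DataFrame(columns=["svtype", "svlen", "is_singleton"]), model)

    def test_invariant_to_query_order_and_ids(self, reference, model):
        q = make_reference(400, seed=13)
        r1 = aps(q, model, seed=5)
        shuffled = q.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled["sv_id"] = [f"renamed{i}" for i in range(len(shuffled))]
        r2 = aps(shuffled, model, seed=5)
        assert r1.aps == pytest.approx(r2.aps, abs=1e-12)

    def test_monotone_in_injected_selection_strength(self, model):
        rng = np.random.default_rng(19)
        scores = []
        for excess in (0.05, 0.15, 0.3):
            q = make_reference(2_000, seed=23)
            pred = model.predict(q)
            q["is_singleton"] = rng.random(len(q)) < np.clip(pred + excess, 0, 1)
            scores.append(aps(q, model, seed=3).aps)
        assert scores[0] < scores[1] < scores[2]


class TestFullVsPartial:
    def test_identical_strata_give_t_zero_p_one(self):
        df = pd.DataFrame({"element_class": [f"c{i}" for i in range(14)],
                           "aps_full": 0.1, "aps_partial": 0.1})
        res = aps_full_vs_partial(df)
        assert res["t"] == 0.0 and res["p_two_tailed"] == 1.0
        assert res["n_classes"] == 14

    def test_stronger_selection_on_full_overlaps_detected(self):
        rng = np.random.default_rng(29)
        df = pd.DataFrame({
            "element_class": [f"c{i}" for i in range(14)],
            "aps_full": 0.12 + rng.normal(0, 0.01, 14),
            "aps_partial": 0.04 + rng.normal(0, 0.01, 14)})
        res = aps_full_vs_partial(df)
        assert res["mean_difference"] > 0
        assert res["p_two_tailed"] < 0.01

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            aps_full_vs_partial(pd.DataFrame(
                {"element_class": ["a"], "aps_full": [0.1], "aps_partial": [0.0]}))


class TestConservationCorrelation:
    def test_constant_track_flagged_not_computed(self, model):
        q = make_reference(500, seed=31)
        q["conservation_sum"] = 5.0
        res = aps_conservation_correlation(q, model)
        assert res["defined"] is False

    def test_rolling_mean_of_constant_series_is_constant(self):
        from svpopgen._util import rolling_mean
        out = rolling_mean(np.full(50, 0.3), 21)
        np.testing.assert_allclose(out, 0.3)

    def test_selection_proportional_to_conservation_detected(self, model):
        rng = np.random.default_rng(37)
        q = make_reference(4_000, seed=41)
        q["conservation_sum"] = rng.lognormal(3, 1, len(q))
        pred = model.predict(q)
        boost = 0.3 * (q["conservation_sum"].rank(pct=True).to_numpy())
        q["is_singleton"] = rng.random(len(q)) < np.clip(pred + boost, 0, 1)
        res = aps_conservation_correlation(q, model, seed=2)
        assert res["defined"]
        assert res["spearman_rho"] > 0.5
        assert res["p_two_sided"] < 0.05
        assert len(res["bins"]) == 100
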