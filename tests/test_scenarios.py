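import numpy as np
import pandas as pd
import pytest

from npskin.applicability import generate_insilico
from npskin.datamodel import DEPTH_CLASSES, DatasetError, FeatureEncoder
from npskin.scenarios import (
    MAGNITUDES,
    ScenarioResult,
    ScenarioSpec,
    apply_scenario,
    route_attribution,
    run_route_experiment,
)
from npskin.synth import GeneratorConfig, builtin_skin_reference, generate_frame


@pytest.fixture(scope="module")
def human_back():
    return builtin_skin_reference().lookup("human", "back")


class TestApplyScenario:
    def test_zero_magnitude_is_identity(self, human_back):
        assert apply_scenario(human_back, ScenarioSpec("baseline", 0)) == human_back

    def test_lipophilic_shift_ten_percent(self, human_back):
        out = apply_scenario(human_back, ScenarioSpec("lipophilic_shift", 10))
        assert out.lipid_lipophilicity == pytest.approx(
            human_back.lipid_lipophilicity * 1.10
        )
        assert out.lipid_polarity == pytest.approx(
            human_back.lipid_polarity * 0.90
        )
        assert out.hf_density == human_back.hf_density

    def test_reduced_follicles_touches_density_only(self, human_back):
        out = apply_scenario(human_back, ScenarioSpec("reduced_follicles", 20))
        assert out.hf_density == pytest.approx(human_back.hf_density * 0.80)
        for fld in ("sc_thickness", "epidermis_thickness", "dermis_thickness",
                    "hf_diameter", "lipid_lipophilicity", "lipid_polarity"):
            assert getattr(out, fld) == getattr(human_back, fld)

    @pytest.mark.parametrize("sid", ["reduced_follicles", "lipophilic_shift",
                                     "polar_shift"])
    @pytest.mark.parametrize("mag", [5, 10, 15, 20])
    def test_inverse_multipliers_recover_baseline(self, human_back, sid, mag):
        spec = ScenarioSpec(sid, mag)
        perturbed = apply_scenario(human_back, spec)
        for fld, mult in spec.multipliers().items():
            assert getattr(perturbed, fld) / mult == pytest.approx(
                getattr(human_back, fld), abs=1e-12
            )

    def test_invalid_specs_rejected(self):
        with pytest.raises(DatasetError):
            ScenarioSpec("baseline", 10)
        with pytest.raises(DatasetError):
            ScenarioSpec("reduced_follicles", 7)
        with pytest.raises(DatasetError):
            ScenarioSpec("meteor_strike", 5)


class _DensityModel:
    """Surrogate whose predicted depth deepens with hair-follicle density
    (strongly) and particle size (mildly), so a fixed-skin population
    still spreads over several layers."""

    def __init__(self, density_col, size_col, cuts=(-4.0, -3.0, -2.0, -1.0)):
        self.density_col = density_col
        self.size_col = size_col
        self.cuts = np.asarray(cuts)

    def predict(self, X):
        score = 4.0 * X[:, self.density_col] + X[:, self.size_col]
        idx = np.searchsorted(self.cuts, score)
        return np.array([DEPTH_CLASSES[i] for i in idx])


@pytest.fixture(scope="module")
def route_setup():
    source = generate_frame(GeneratorConfig(n_records=300, seed=20,
                                            missingness={}))
    enc = FeatureEncoder().fit(source)
    pop = generate_insilico(source, n=3000, seed=21,
                            medium_levels=("aqueous", "emulsion", "oil"))
    fm = enc.transform(pop.frame)
    model = _DensityModel(fm.column("hf_density"),
                          fm.column("log10_core_diameter"))
    return enc, pop, model


class TestRouteExperiment:
    def test_occupancy_closure_and_zero_baseline_deltas(self, route_setup):
        enc, pop, model = route_setup
        result = run_route_experiment(model, pop, enc)
        sums = result.table.groupby(["medium", "scenario", "magnitude"])[
            "occupancy_pct"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)
        base = result.table[result.table.scenario == "baseline"]
        np.testing.assert_allclose(base["delta_pp"], 0.0, atol=1e-12)

    def test_follicle_reduction_shallows_monotonically(self, route_setup):
        """With depth increasing in follicle density, removing follicles
        shifts occupancy toward shallower layers, more so at larger
        magnitudes."""
        enc, pop, model = route_setup
        result = run_route_experiment(model, pop, enc)
        t = result.table
        for medium in result.media:
            sel = t[(t.medium == medium) & (t.scenario == "reduced_follicles")]
            shallow = sel[sel.layer.isin(["Surface", "SC"])].groupby(
                "magnitude")["delta_pp"].sum()
            assert (shallow.values >= -1e-9).all()
            diffs = np.diff(shallow.reindex([5, 10, 15, 20]).values)
            assert (diffs >= -1e-9).all()

    def test_row_order_invariance(self, route_setup):
        enc, pop, model = route_setup
        result = run_route_experiment(model, pop, enc)
        import copy
        shuffled = copy.copy(pop)
        shuffled.frame = pop.frame.sample(frac=1.0, random_state=0)
        result2 = run_route_experiment(model, shuffled, enc)
        pd.testing.assert_frame_equal(
            result.table.reset_index(drop=True),
            result2.table.reset_index(drop=True),
        )

    def test_empty_medium_group_rejected(self, route_setup):
        enc, pop, model = route_setup
        only_aq = type(pop)(
            frame=pop.frame[pop.frame.medium == "aqueous"],
            bounds=pop.bounds, skin_context=pop.skin_context,
            condition=pop.condition, seed=pop.seed,
        )
        with pytest.raises(DatasetError, match="oil"):
            run_route_experiment(model, only_aq, enc, media=("aqueous", "oil"))


def _constructed_result(deltas_by_scenario):
    rows = []
    for medium in ("aqueous", "emulsion", "oil"):
        for scenario in ("baseline", "reduced_follicles", "lipophilic_shift",
                         "polar_shift"):
            for mag in MAGNITUDES if scenario != "baseline" else (0,):
                if mag == 0 and scenario != "baseline":
                    continue
                for layer in DEPTH_CLASSES:
                    delta = 0.0
                    if scenario != "baseline" and layer == "SC":
                        delta = deltas_by_scenario.get((medium, scenario), 0.0)
                        delta *= mag / 20.0
                    rows.append({
                        "medium": medium, "scenario": scenario,
                        "magnitude": mag, "layer": layer,
                        "occupancy_pct": 20.0 + delta, "delta_pp": delta,
                    })
    return ScenarioResult(table=pd.DataFrame(rows),
                          media=("aqueous", "emulsion", "oil"))


class TestRouteAttribution:
    def test_zero_deltas_mean_no_preference(self):
        result = _constructed_result({})
        att = route_attribution(result)
        assert (att["preferred_routes"] == "no inferred preference").all()

    def test_follicle_sensitivity_fires_transappendageal(self):
        result = _constructed_result({("oil", "reduced_follicles"): 8.0})
        att = route_attribution(result).set_index("medium")
        assert "transappendageal" in att.loc["oil", "preferred_routes"]
        assert att.loc["aqueous", "preferred_routes"] == "no inferred preference"

    def test_reported_media_route_pattern(self):
        """Emulsion/oil sensitive to follicle and lipophilic scenarios,
        aqueous to the polar scenario: labels mirror that pattern."""
        result = _constructed_result({
            ("emulsion", "reduced_follicles"): 6.0,
            ("emulsion", "lipophilic_shift"): 5.0,
            ("oil", "reduced_follicles"): 7.0,
            ("oil", "lipophilic_shift"): 6.0,
            ("aqueous", "polar_shift"): 4.0,
        })
        att = route_attribution(result).set_index("medium")
        for medium in ("emulsion", "oil"):
            labels = att.loc[medium, "preferred_routes"]
            assert "transappendageal" in labels and "intercellular" in labels
            assert "intracellular" not in labels
        assert att.loc["aqueous", "preferred_routes"] == "intracellular"

    def test_deltas_always_reported_with_labels(self):
        att = route_attribution(_constructed_result({}))
        for col in ("transappendageal_max_delta_pp",
                    "intercellular_max_delta_pp",
                    "intracellular_max_delta_pp"):
            assert col in att.columns
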