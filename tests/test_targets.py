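"""Energy-proportional target scaling and comparison semantics.

The frozen expected values are the published child targets for the two age
groups (mean energy intakes 1311 and 1449 kcal/day): every adult value is
multiplied by energy/2500 and rounded to the printed precision.
"""

import pytest

from dietgap.targets import (
    ADULT_TARGETS,
    AdultTarget,
    classify_vs_range,
    diet_gap_percent,
    dump_adult_targets,
    load_adult_targets,
    meets_target,
    scale_targets,
    ScaledTarget,
)

# group -> (target, range_lo, range_hi) at each age group's mean energy
TABLE_3TO4 = {  # 1311 kcal/day
    "whole_grains": (122, None, None),
    "tubers": (26, 0, 52),
    "vegetables": (157, 105, 315),
    "fruits": (105, 52, 157),
    "dairy": (131, 0, 262),
    "red_meat": (7, 0, 15),
    "beef_lamb": (4, 0, 7),
    "pork": (4, 0, 7),
    "poultry": (15, 0, 30),
    "eggs": (7, 0, 13),
    "fish": (15, 0, 52),
    "legumes": (39, 0, 79),
    "nuts": (26, 13, 52),
    "saturated_fats": (6.2, 0, 6.2),
    "unsaturated_oils": (21, 10, 42),
    "added_sugars": (16, 0, 16),
}
TABLE_5TO6 = {  # 1449 kcal/day
    "whole_grains": (134, None, None),
    "tubers": (29, 0, 58),
    "vegetables": (174, 116, 348),
    "fruits": (116, 58, 174),
    "dairy": (145, 0, 290),
    "red_meat": (8, 0, 16),
    "beef_lamb": (4, 0, 8),
    "pork": (4, 0, 8),
    "poultry": (17, 0, 34),
    "eggs": (8, 0, 14),
    "fish": (16, 0, 58),
    "legumes": (43, 0, 87),
    "nuts": (29, 14, 58),
    "saturated_fats": (6.8, 0, 6.8),
    "unsaturated_oils": (23, 12, 46),
    "added_sugars": (18, 0, 18),
}


class TestScaling:
    @pytest.mark.parametrize(
        "energy,expected", [(1311.0, TABLE_3TO4), (1449.0, TABLE_5TO6)], ids=["3to4", "5to6"]
    )
    def test_reproduces_published_child_targets(self, energy, expected):
        scaled = scale_targets(energy)
        assert len(scaled.targets) == 16
        for t in scaled:
            assert (t.target_g, t.range_lo_g, t.range_hi_g) == expected[t.group], t.group

    def test_identity_at_reference_energy(self):
        for t, a in zip(scale_targets(2500.0), ADULT_TARGETS):
            assert t.target_g == pytest.approx(a.target_g)
            if a.range_lo_g is not None:
                assert t.range_lo_g == pytest.approx(a.range_lo_g)
                assert t.range_hi_g == pytest.approx(a.range_hi_g)

    def test_monotone_in_energy(self):
        energies = [800.0, 1000.0, 1311.0, 1449.0, 2000.0, 2500.0]
        tables = [scale_targets(e) for e in energies]
        for group in TABLE_3TO4:
            vals = [tab[group].target_g for tab in tables]
            assert vals == sorted(vals)

    def test_non_positive_energy_rejected(self):
        with pytest.raises(ValueError):
            scale_targets(0.0)

    def test_range_ordering_preserved(self):
        for energy in (900.0, 1311.0, 1449.0, 3000.0):
            for t in scale_targets(energy):
                if t.has_range:
                    assert t.range_lo_g <= t.target_g <= t.range_hi_g

    def test_direction_assignment(self):
        scaled = scale_targets(1311.0)
        for g in ("whole_grains", "vegetables", "fruits", "fish", "legumes", "nuts", "unsaturated_oils"):
            assert scaled[g].direction == "minimum"
        for g in ("tubers", "dairy", "red_meat", "beef_lamb", "pork", "poultry", "eggs", "saturated_fats", "added_sugars"):
            assert scaled[g].direction == "maximum"


class TestComparisons:
    def test_boundary_counts_as_met(self):
        t_min = ScaledTarget("whole_grains", 122.0, None, None, "minimum")
        assert meets_target(122.0, t_min)
        assert not meets_target(121.9, t_min)
        t_max = ScaledTarget("dairy", 131.0, 0.0, 262.0, "maximum")
        assert meets_target(131.0, t_max)
        assert not meets_target(640.0, t_max)

    def test_degenerate_zero_minimum(self):
        t = ScaledTarget("fish", 0.0, None, None, "minimum")
        assert meets_target(0.0, t)

    def test_range_classification(self):
        assert classify_vs_range(30.0, 0.0, 52.0) == "within"
        assert classify_vs_range(53.0, 0.0, 52.0) == "above"
        assert classify_vs_range(0.0, 0.0, 52.0) == "within"  # boundary inclusive
        assert classify_vs_range(104.9, 105.0, 315.0) == "below"

    def test_diet_gap(self):
        assert diet_gap_percent(122.0, 122.0) == pytest.approx(100.0)
        assert diet_gap_percent(41.0, 122.0) == pytest.approx(33.6, abs=0.05)
        assert diet_gap_percent(0.0, 122.0) == 0.0
        with pytest.raises(ValueError):
            diet_gap_percent(10.0, 0.0)


def test_targets_file_round_trip(tmp_path):
    path = tmp_path / "targets.json"
    dump_adult_targets(ADULT_TARGETS, path)
    loaded = load_adult_targets(path)
    assert loaded == ADULT_TARGETS


def test_adult_target_validation():
    with pytest.raises(ValueError):
        AdultTarget("x", 10.0, 20.0, 30.0, "minimum")  # target below range
    with pytest.raises(ValueError):
        AdultTarget("x", 10.0, 0.0, None, "minimum")  # half a range
    with pytest.raises(ValueError):
        AdultTarget("x", 10.0, None, None, "sideways")
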