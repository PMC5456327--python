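import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabrymeta.errors import ValidationError
from fabrymeta.harmonize import (ThresholdConfig, apply_thresholds,
                                 collapse_within_study, fc_magnitude,
                                 map_identifiers)


def _meas(rows):
    return pd.DataFrame(rows, columns=["study_id", "raw_id", "ratio",
                                       "p_value"])


def _feat(rows):
    return pd.DataFrame(rows, columns=["cluster_id", "study_id", "ratio",
                                       "p_value", "direction", "tag"])


class TestMapIdentifiers:
    def test_aliases_of_one_cluster_share_cluster_id(self, alias_df):
        meas = _meas([("S1", "GLA", 2.0, 0.01),
                      ("S1", "P06280", 2.1, 0.01),
                      ("S2", "GLA_HUMAN", 1.9, 0.02)])
        mapped, unmapped = map_identifiers(meas, alias_df)
        assert set(mapped["cluster_id"]) == {"C_GLA"}
        assert unmapped.empty

    def test_distinct_cluster_count_on_mixed_fixture(self, alias_df):
        # 3 records via aliases of C_GLA plus one record per singleton
        rows = [("S1", "GLA", 2.0, 0.01), ("S1", "P06280", 2.0, 0.01),
                ("S2", "GLA_HUMAN", 2.0, 0.01)]
        rows += [("S1", f"g{i}", 1.5, 0.01) for i in range(7)]
        mapped, unmapped = map_identifiers(_meas(rows), alias_df)
        assert mapped["cluster_id"].nunique() == 8
        assert len(mapped) == 10 and unmapped.empty

    def test_unmapped_identifier_routed_to_side_list(self, alias_df):
        meas = _meas([("S1", "GLA", 2.0, 0.01),
                      ("S1", "NOT_IN_MAP", 2.0, 0.01)])
        mapped, unmapped = map_identifiers(meas, alias_df)
        assert len(mapped) == 1
        assert unmapped["raw_id"].tolist() == ["NOT_IN_MAP"]

    @given(st.lists(st.tuples(st.sampled_from(["GLA", "g1", "nope", "zz"]),
                              st.floats(0.1, 10)), max_size=30))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_mapped_plus_unmapped_equals_input(self, entries):
        alias = pd.DataFrame([("GLA", "C_GLA", "ENZ"), ("g1", "C_A", "MET")],
                             columns=["raw_id", "cluster_id", "tag"])
        meas = _meas([("S1", raw, r, 0.01) for raw, r in entries])
        mapped, unmapped = map_identifiers(meas, alias)
        assert len(mapped) + len(unmapped) == len(meas)


class TestCollapseWithinStudy:
    def test_mean_of_repeated_ratios(self):
        mapped = _meas([("S1", "a", 1.6, 0.01), ("S1", "b", 2.0, 0.03)])
        mapped["cluster_id"] = "C1"
        mapped["tag"] = "MET"
        out = collapse_within_study(mapped)
        assert len(out) == 1
        assert out.loc[0, "ratio"] == pytest.approx(1.8)
        assert out.loc[0, "p_value"] == pytest.approx(0.01)  # group minimum
        assert out.loc[0, "direction"] == "up"

    def test_singleton_passes_through_unchanged(self):
        mapped = _meas([("S1", "a", 0.4, 0.02)])
        mapped["cluster_id"] = "C1"
        mapped["tag"] = "TP"
        out = collapse_within_study(mapped)
        assert out.loc[0, "ratio"] == 0.4
        assert out.loc[0, "direction"] == "down"

    def test_conflicting_directions_drop_the_group(self, caplog):
        mapped = _meas([("S1", "a", 1.6, 0.01), ("S1", "b", 0.5, 0.01),
                        ("S2", "c", 1.6, 0.01)])
        mapped["cluster_id"] = "C1"
        mapped["tag"] = "MET"
        out, dropped = collapse_within_study(mapped, return_dropped=True)
        assert out["study_id"].tolist() == ["S2"]
        assert dropped["study_id"].tolist() == ["S1"]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rows = [(f"S{rng.integers(3)}", f"r{i}",
                 float(np.exp(rng.normal(0.4, 0.3))), float(rng.uniform()))
                for i in range(40)]
        mapped = _meas(rows)
        mapped["cluster_id"] = [f"C{rng.integers(10)}" for _ in rows]
        mapped["tag"] = "UK"
        once = collapse_within_study(mapped)
        twice = collapse_within_study(
            once.rename(columns={})[["study_id", "ratio", "p_value",
                                     "cluster_id", "tag"]])
        pd.testing.assert_frame_equal(
            once.sort_values(["cluster_id", "study_id"]).reset_index(drop=True),
            twice.sort_values(["cluster_id", "study_id"]).reset_index(drop=True))

    def test_fisher_and_geometric_options(self):
        mapped = _meas([("S1", "a", 2.0, 0.04), ("S1", "b", 8.0, 0.04)])
        mapped["cluster_id"] = "C1"
        mapped["tag"] = "MET"
        out = collapse_within_study(mapped, p_policy="fisher",
                                    ratio_policy="geometric")
        assert out.loc[0, "ratio"] == pytest.approx(4.0)  # sqrt(2*8)
        assert 0 < out.loc[0, "p_value"] < 1


class TestApplyThresholds:
    def test_transcriptomics_below_platform_threshold_excluded(
            self, studies_df):
        feats = _feat([("C1", "S1", 1.8, 0.01, "up", "MET")])
        assert apply_thresholds(feats, studies_df).empty

    def test_proteomics_passing_platform_but_failing_global(self,
                                                            studies_df):
        feats = _feat([("C1", "S2", 1.35, 0.01, "up", "MET")])
        assert apply_thresholds(feats, studies_df).empty

    def test_halved_proteomics_feature_included_as_down(self, studies_df):
        feats = _feat([("C1", "S2", 0.5, 0.01, "down", "MET")])
        out = apply_thresholds(feats, studies_df)
        assert len(out) == 1 and out.loc[0, "direction"] == "down"

    def test_p_value_gate(self, studies_df):
        feats = _feat([("C1", "S2", 3.0, 0.05, "up", "MET"),
                       ("C2", "S2", 3.0, 0.049, "up", "MET")])
        out = apply_thresholds(feats, studies_df)
        assert out["cluster_id"].tolist() == ["C2"]

    def test_unknown_platform_is_reference_error(self, studies_df):
        feats = _feat([("C1", "S9", 3.0, 0.01, "up", "MET")])
        with pytest.raises(ValidationError, match="S9"):
            apply_thresholds(feats, studies_df)

    @given(st.lists(st.tuples(st.floats(0.05, 20), st.floats(0, 1)),
                    min_size=1, max_size=30),
           st.floats(1.05, 3), st.floats(1.05, 3), st.floats(0.01, 0.2))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_every_threshold(self, entries, fc_t, fc_g, p_max):
        feats = _feat([("C%d" % i, "S2", r, p, "up", "MET")
                       for i, (r, p) in enumerate(entries)])
        studies = pd.DataFrame({"study_id": ["S2"],
                                "platform": ["proteomics"],
                                "fluid": ["blood"], "group": ["naive"]})
        lo = ThresholdConfig(fc_prot_metab=fc_t, fc_global=fc_g, p_max=p_max)
        hi = ThresholdConfig(fc_prot_metab=fc_t * 1.2, fc_global=fc_g * 1.2,
                             p_max=p_max / 2)
        kept_lo = set(apply_thresholds(feats, studies, lo)["cluster_id"])
        kept_hi = set(apply_thresholds(feats, studies, hi)["cluster_id"])
        assert kept_hi <= kept_lo

    @given(st.floats(0.05, 20), st.floats(0.001, 0.049))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_direction_symmetry(self, ratio, p):
        studies = pd.DataFrame({"study_id": ["S2"],
                                "platform": ["proteomics"],
                                "fluid": ["blood"], "group": ["naive"]})
        direct = _feat([("C1", "S2", ratio, p, "up", "MET")])
        flipped = _feat([("C1", "S2", 1.0 / ratio, p, "down", "MET")])
        assert (len(apply_thresholds(direct, studies))
                == len(apply_thresholds(flipped, studies)))


def test_fc_magnitude_symmetric():
    assert fc_magnitude(0.5) == pytest.approx(2.0)
    assert fc_magnitude(2.0) == pytest.approx(2.0)
    assert np.allclose(fc_magnitude([0.25, 4.0]), [4.0, 4.0])
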