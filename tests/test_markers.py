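import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfecomm import (
    functional_composition,
    functional_permanova,
    marker_sets,
    pairwise_permanova,
    recover_markers,
    spec_occu,
)
from rfecomm.markers import MarkerSet
from rfecomm.ordination import bray_curtis


def _meta(groups: dict[str, int]) -> pd.DataFrame:
    rows = []
    for g, n in groups.items():
        for i in range(n):
            rows.append(
                {"sample_id": f"{g}{i}", "species": f"sp_{g}{i}", "group": g, "replicate": 1}
            )
    return pd.DataFrame(rows).set_index("sample_id")


def brute_force_spec_occu(table: pd.DataFrame, metadata: pd.DataFrame):
    """Independent oracle: nested loops, no vectorization."""
    out = {}
    groups = list(dict.fromkeys(metadata.loc[table.index, "group"]))
    for otu in table.columns:
        means = {}
        for g in groups:
            samples = [s for s in table.index if metadata.loc[s, "group"] == g]
            total = 0.0
            for s in samples:
                total += table.loc[s, otu]
            means[g] = total / len(samples)
        denom = sum(means.values())
        for g in groups:
            samples = [s for s in table.index if metadata.loc[s, "group"] == g]
            present = 0
            for s in samples:
                if table.loc[s, otu] > 0:
                    present += 1
            spec = means[g] / denom if denom > 0 else 0.0
            out[(otu, g)] = (spec, present / len(samples))
    return out


class TestSpecOccu:
    def test_exclusive_presence_is_marker(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame(
            {"OTU1": [4, 6, 0, 0], "OTU2": [1, 1, 1, 1]}, index=md.index
        )
        rec = spec_occu(table, md).set_index(["otu_id", "group"])
        row = rec.loc[("OTU1", "A")]
        assert row["specificity"] == pytest.approx(1.0)
        assert row["occupancy"] == pytest.approx(1.0)
        assert bool(row["is_marker"])
        assert not bool(rec.loc[("OTU1", "B"), "is_marker"])

    def test_group_mean_ratio(self):
        """Group means 3 (A) and 1 (B) split specificity 0.75 / 0.25."""
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [2, 4, 1, 1], "OTU2": [1, 1, 1, 1]}, index=md.index)
        rec = spec_occu(table, md).set_index(["otu_id", "group"])
        assert rec.loc[("OTU1", "A"), "specificity"] == pytest.approx(0.75)
        assert rec.loc[("OTU1", "B"), "specificity"] == pytest.approx(0.25)

    def test_occupancy_two_thirds_blocks_marker(self):
        """Present in 2 of 3 group samples: occupancy 2/3 < 0.7, no marker flag
        even at specificity 1."""
        md = _meta({"A": 3, "B": 2})
        table = pd.DataFrame({"OTU1": [5, 5, 0, 0, 0], "OTU2": [1, 1, 1, 1, 1]}, index=md.index)
        rec = spec_occu(table, md).set_index(["otu_id", "group"])
        row = rec.loc[("OTU1", "A")]
        assert row["specificity"] == pytest.approx(1.0)
        assert row["occupancy"] == pytest.approx(2.0 / 3.0)
        assert not bool(row["is_marker"])

    def test_threshold_boundary_inclusive(self):
        """specificity = occupancy = 0.7 exactly -> marker (>= threshold)."""
        md = _meta({"A": 10, "B": 10})
        # A mean = 7, B mean = 3 -> specificity_A = 0.7; present in 7/10 -> 0.7
        a_counts = [10, 10, 10, 10, 10, 10, 10, 0, 0, 0]
        b_counts = [3] * 10
        table = pd.DataFrame(
            {"OTU1": a_counts + b_counts, "OTU2": [1] * 20}, index=md.index
        )
        rec = spec_occu(table, md).set_index(["otu_id", "group"])
        row = rec.loc[("OTU1", "A")]
        assert row["specificity"] == pytest.approx(0.7)
        assert row["occupancy"] == pytest.approx(0.7)
        assert bool(row["is_marker"])

    def test_absent_otu_flagged_undefined(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [1, 2, 3, 4], "OTU2": [0, 0, 0, 0]}, index=md.index)
        rec = spec_occu(table, md)
        ghost = rec[rec["otu_id"] == "OTU2"]
        assert ghost["undefined"].all()
        assert (ghost["specificity"] == 0.0).all()
        assert not ghost["is_marker"].any()

    @given(st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n_groups = int(r.integers(2, 4))
        sizes = {chr(65 + i): int(r.integers(1, 4)) for i in range(n_groups)}
        md = _meta(sizes)
        table = pd.DataFrame(
            r.integers(0, 20, size=(len(md), int(r.integers(2, 8)))),
            index=md.index,
        ).rename(columns=str)
        rec = spec_occu(table, md).set_index(["otu_id", "group"])
        oracle = brute_force_spec_occu(table, md)
        for (otu, g), (spec, occ) in oracle.items():
            assert rec.loc[(str(otu), g), "specificity"] == pytest.approx(spec, abs=1e-12)
            assert rec.loc[(str(otu), g), "occupancy"] == pytest.approx(occ, abs=1e-12)
        sums = rec.groupby("otu_id")["specificity"].sum()
        observed = table.sum(axis=0) > 0
        np.testing.assert_allclose(sums[observed.index[observed].astype(str)], 1.0, atol=1e-12)

    def test_marker_flag_monotone_in_home_counts(self):
        """Raising an OTU's counts only within group H cannot lower its
        specificity or occupancy for H."""
        md = _meta({"A": 3, "B": 3})
        base = pd.DataFrame(
            {"OTU1": [2, 0, 1, 1, 1, 1], "OTU2": [5] * 6}, index=md.index
        )
        bumped = base.copy()
        bumped.loc[["A0", "A1"], "OTU1"] += 4
        r0 = spec_occu(base, md).set_index(["otu_id", "group"]).loc[("OTU1", "A")]
        r1 = spec_occu(bumped, md).set_index(["otu_id", "group"]).loc[("OTU1", "A")]
        assert r1["specificity"] >= r0["specificity"]
        assert r1["occupancy"] >= r0["occupancy"]


class TestMarkerRecovery:
    def test_planted_markers_recovered(self, small_dataset):
        from rfecomm import rarefy

        rare = rarefy(small_dataset.otu_table, seed=0)
        rec = spec_occu(rare, small_dataset.metadata)
        report = recover_markers(rec, small_dataset.truth.markers)
        assert report["n_planted"] == 9
        assert report["sensitivity"] >= 0.8

    def test_report_arithmetic(self):
        records = pd.DataFrame(
            {
                "otu_id": ["o1", "o2", "o3"],
                "group": ["A", "A", "B"],
                "specificity": [1.0, 1.0, 1.0],
                "occupancy": [1.0, 1.0, 1.0],
                "is_marker": [True, True, True],
                "undefined": [False] * 3,
            }
        )
        report = recover_markers(records, {"A": ["o1"], "B": ["oX"]})
        assert report["sensitivity"] == pytest.approx(0.5)  # o1 of {o1, oX}
        assert report["fdr"] == pytest.approx(2 / 3)  # o2, o3 flagged falsely


class TestFunctionalComposition:
    def test_single_marker_single_mode(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [5, 5, 1, 1], "OTU2": [1, 1, 5, 5]}, index=md.index)
        guilds = pd.Series({"OTU1": "Symbiotroph", "OTU2": "Pathotroph"})
        ms = MarkerSet(markers={"A": ["OTU1"]}, sequence_fraction={"A": 0.5})
        fc = functional_composition(table, md, guilds, ms)
        assert fc.loc["A", "Symbiotroph"] == pytest.approx(1.0)

    def test_pooled_mode_fractions(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame(
            {"OTU1": [20, 10, 0, 0], "OTU2": [5, 5, 0, 0], "OTU3": [1, 1, 9, 9]},
            index=md.index,
        )
        guilds = pd.Series(
            {"OTU1": "Symbiotroph", "OTU2": "Pathotroph", "OTU3": "Saprotroph"}
        )
        ms = MarkerSet(
            markers={"A": ["OTU1", "OTU2"], "B": []}, sequence_fraction={}
        )
        fc = functional_composition(table, md, guilds, ms)
        assert fc.loc["A", "Symbiotroph"] == pytest.approx(0.75)
        assert fc.loc["A", "Pathotroph"] == pytest.approx(0.25)

    def test_triple_mode_is_one_category(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [5, 5, 2, 2], "OTU2": [1, 1, 1, 1]}, index=md.index)
        guilds = pd.Series({"OTU1": "Pathotroph-Saprotroph-Symbiotroph"})
        ms = MarkerSet(markers={"A": ["OTU1"]}, sequence_fraction={})
        fc = functional_composition(table, md, guilds, ms)
        assert fc.loc["A", "Pathotroph-Saprotroph-Symbiotroph"] == pytest.approx(1.0)
        assert "Pathotroph" not in fc.columns

    def test_unannotated_marker_unassigned(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [5, 5, 2, 2], "OTU2": [1, 1, 1, 1]}, index=md.index)
        guilds = pd.Series({"OTU2": "Symbiotroph"})
        ms = MarkerSet(markers={"A": ["OTU1"]}, sequence_fraction={})
        fc = functional_composition(table, md, guilds, ms)
        assert fc.loc["A", "Unassigned"] == pytest.approx(1.0)

    def test_marker_sets_sequence_fraction(self):
        md = _meta({"A": 2, "B": 2})
        table = pd.DataFrame({"OTU1": [8, 8, 0, 0], "OTU2": [2, 2, 10, 10]}, index=md.index)
        rec = spec_occu(table, md)
        sets = marker_sets(rec, table, md)
        assert sets.markers["A"] == ["OTU1"]
        assert sets.sequence_fraction["A"] == pytest.approx(16 / 20)


class TestFunctionalPermanova:
    def test_delegates_to_generic_pairwise(self, small_dataset):
        from rfecomm import rarefy

        ds = small_dataset
        rare = rarefy(ds.otu_table, seed=1)
        rec = spec_occu(rare, ds.metadata)
        sets = marker_sets(rec, rare, ds.metadata)
        results = functional_permanova(rare, ds.metadata, ds.guilds, sets, n_permutations=99, seed=4)
        fc = functional_composition(rare, ds.metadata, ds.guilds, sets, level="sample")
        fc = fc.loc[fc.sum(axis=1) > 0]
        direct = pairwise_permanova(
            bray_curtis(fc),
            ds.metadata.loc[fc.index, "group"],
            n_permutations=99,
            seed=4,
        )
        assert [r.statistic for r in results] == pytest.approx(
            [r.statistic for r in direct], abs=1e-12
        )
        assert [r.p_value for r in results] == [r.p_value for r in direct]

    def test_identical_profiles_nonsignificant(self):
        md = _meta({"A": 3, "B": 3})
        table = pd.DataFrame(
            {"OTU1": [10] * 6, "OTU2": [5] * 6}, index=md.index
        )
        guilds = pd.Series({"OTU1": "Symbiotroph", "OTU2": "Pathotroph"})
        ms = MarkerSet(markers={"A": ["OTU1"], "B": ["OTU2"]}, sequence_fraction={})
        results = functional_permanova(table, md, guilds, ms, n_permutations=99, seed=0)
        assert all(r.p_value > 0.05 for r in results)
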