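"""Bootstrap core procedure: analytic detection limits, monotonicity, Venn algebra."""

import numpy as np
import pandas as pd
import pytest

from coregrad import (
    CoreParams,
    FeatureTable,
    annotate_core,
    bootstrap_core,
    core_intersections,
    group_cores,
)


def presence_table(n_samples, present_in, count, filler=1000) -> FeatureTable:
    """One focal feature ('focal') present at `count` in the first
    `present_in` samples, plus a ubiquitous filler feature."""
    focal = [count] * present_in + [0] * (n_samples - present_in)
    df = pd.DataFrame(
        {f"s{j}": [focal[j], filler] for j in range(n_samples)},
        index=["focal", "filler"],
    )
    return FeatureTable(df)


class TestBootstrapCore:
    def test_saturated_feature_support_one(self):
        table = presence_table(10, present_in=10, count=500, filler=500)
        res = bootstrap_core(table, CoreParams(n_boot=100, seed=0))
        assert res.support["focal"] == 1.0
        assert "focal" in res.core_set

    def test_absent_feature_never_core(self):
        table = presence_table(10, present_in=0, count=0)
        res = bootstrap_core(table, CoreParams(n_boot=100, seed=0))
        assert res.support["focal"] == 0.0
        assert "focal" not in res.core_set

    def test_analytic_detection_probabilities(self):
        # 80% occupancy at relative abundance 0.10, depth 500:
        # detection ~ 1-(0.9)^500 ~ 1, prevalence ~ 0.80 >= 0.75 -> core
        n = 20
        abundant = presence_table(n, present_in=16, count=1000, filler=9000)
        res = bootstrap_core(abundant, CoreParams(n_boot=400, depth=500, seed=1))
        assert res.support["focal"] > 0.95
        assert "focal" in res.core_set
        # same occupancy at relative abundance 1/10,000: detection ~ 0.049,
        # per-replicate prevalence ~ 0.039 << 0.75 -> support ~ 0
        rare = presence_table(n, present_in=16, count=1, filler=9999)
        res2 = bootstrap_core(rare, CoreParams(n_boot=400, depth=500, seed=1))
        assert res2.support["focal"] == 0.0
        assert "focal" not in res2.core_set
        assert res2.mean_prevalence["focal"] == pytest.approx(
            0.8 * (1 - (1 - 1e-4) ** 500), abs=0.02
        )

    def test_support_monotone_in_prevalence_threshold(self):
        table = presence_table(10, present_in=8, count=50, filler=50)
        sup = [
            bootstrap_core(table, CoreParams(n_boot=200, prevalence_threshold=t, seed=3))
            .support["focal"]
            for t in (0.5, 0.7, 0.9)
        ]
        assert sup[0] >= sup[1] >= sup[2]

    def test_infinite_depth_limit_is_raw_prevalence(self):
        # at depth 1e6, detection of any present feature is certain, so
        # support becomes the indicator of raw prevalence >= threshold
        table = presence_table(10, present_in=8, count=3, filler=997)
        res = bootstrap_core(
            table, CoreParams(n_boot=50, depth=1_000_000, prevalence_threshold=0.75, seed=0)
        )
        assert res.support["focal"] == 1.0
        res2 = bootstrap_core(
            table, CoreParams(n_boot=50, depth=1_000_000, prevalence_threshold=0.85, seed=0)
        )
        assert res2.support["focal"] == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 50, (20, 8)) + 1,
                          index=[f"f{i}" for i in range(20)])
        table = FeatureTable(df)
        a = bootstrap_core(table, CoreParams(n_boot=100, seed=7))
        b = bootstrap_core(table, CoreParams(n_boot=100, seed=7))
        pd.testing.assert_series_equal(a.support, b.support)

    def test_sample_bootstrap_mode(self):
        table = presence_table(10, present_in=10, count=50)
        res = bootstrap_core(table, CoreParams(n_boot=100, seed=0, mode="samples"))
        assert res.support["focal"] == 1.0

    def test_zero_total_sample_errors(self):
        df = pd.DataFrame({"s1": [3], "s2": [0]}, index=["f1"])
        with pytest.raises(ValueError, match="s2"):
            bootstrap_core(FeatureTable(df), CoreParams(n_boot=10, seed=0))


class TestGroupCores:
    def make_meta(self, table, stages):
        return pd.DataFrame(
            {
                "stage": stages,
                "site": "x",
                "latitude_deg_n": 19.0,
                "altitude_masl": 10.0,
                "transect": "latitudinal",
            },
            index=pd.Index(table.sample_ids, name="sample_id"),
        )

    def test_single_group_reduces_to_whole_table(self):
        table = presence_table(6, present_in=6, count=100)
        meta = self.make_meta(table, ["larva"] * 6)
        params = CoreParams(n_boot=100, seed=3)
        grouped = group_cores(table, meta, "stage", params)
        assert list(grouped) == ["larva"]
        assert grouped["larva"].core_set == ["focal", "filler"]

    def test_singleton_group_named_in_error(self):
        table = presence_table(3, present_in=3, count=100)
        meta = self.make_meta(table, ["larva", "larva", "pulp"])
        with pytest.raises(ValueError, match="pulp"):
            group_cores(table, meta, "stage", CoreParams(n_boot=10, seed=0))

    def test_per_group_threshold_override(self):
        table = presence_table(8, present_in=8, count=100)
        meta = self.make_meta(table, ["larva"] * 4 + ["pulp"] * 4)
        lax = CoreParams(n_boot=50, prevalence_threshold=0.65, seed=1)
        out = group_cores(
            table, meta, "stage", CoreParams(n_boot=50, seed=1), {"pulp": lax}
        )
        assert out["pulp"].params.prevalence_threshold == 0.65

    def test_raising_threshold_never_enlarges_core(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(0, 8, (30, 12)) + (rng.random((30, 12)) < 0.4),
                          index=[f"f{i}" for i in range(30)]).astype(int) + 1
        table = FeatureTable(df)
        meta = self.make_meta(table, ["larva"] * 12)
        lo = group_cores(table, meta, "stage",
                         CoreParams(n_boot=100, prevalence_threshold=0.65, seed=2))
        hi = group_cores(table, meta, "stage",
                         CoreParams(n_boot=100, prevalence_threshold=0.75, seed=2))
        assert set(hi["larva"].core_set) <= set(lo["larva"].core_set)


class TestIntersectionsAndAnnotation:
    def test_basic_set_algebra(self):
        regions = core_intersections({"larvae": {"a", "b", "c"}, "adults": {"b", "d"}})
        assert regions[("larvae",)] == ["a", "c"]
        assert regions[("adults",)] == ["d"]
        assert regions[("adults", "larvae")] == ["b"]

    def test_disjoint_cores(self):
        regions = core_intersections({"x": {"a"}, "y": {"b"}})
        assert ("x", "y") not in regions

    @pytest.mark.parametrize("seed", range(5))
    def test_regions_partition_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"f{i}" for i in range(30)]
        cores = {
            g: set(rng.choice(universe, size=rng.integers(0, 15), replace=False))
            for g in ("a", "b", "c")
        }
        regions = core_intersections(cores)
        union = set().union(*cores.values())
        flat = [f for region in regions.values() for f in region]
        assert sorted(flat) == sorted(union)  # partition: no overlap, covers all

    def test_annotate_core_join_and_flags(self):
        table = presence_table(6, present_in=6, count=100)
        core = bootstrap_core(table, CoreParams(n_boot=50, seed=0))
        traits = pd.DataFrame({"nifH": [1]}, index=["focal"])
        out = annotate_core(core, traits)
        assert out.loc["focal", "nifH"] == 1
        assert not out.loc["filler", "annotated"]

    def test_annotate_empty_core(self):
        table = presence_table(6, present_in=1, count=1)
        core = bootstrap_core(
            table, CoreParams(n_boot=20, prevalence_threshold=1.0, seed=0)
        )
        res_features = [f for f in core.core_set if f != "filler"]
        out = annotate_core(core, pd.DataFrame(index=pd.Index([])))
        assert "focal" not in out.index
        assert res_features == []
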