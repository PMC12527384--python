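"""Region assignment, cluster frequencies and region comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest

from trackpheno import tme_regions as R
from trackpheno import stats as ST
from trackpheno.types import ClusterResult, RegionAssignment, TrackphenoWarning, TrackTable


def _table(positions):
    """Track table with the given {(mouse, pos): n_tracks} layout."""
    rows = []
    for (mouse, pos), n in positions.items():
        for tid in range(1, n + 1):
            for i in range(3):
                rows.append(
                    {
                        "mouse_id": mouse, "position_id": pos, "track_id": tid,
                        "t": float(i), "x": float(i), "y": 0.0, "z": 0.0,
                    }
                )
    return TrackTable.from_dataframe(pd.DataFrame(rows))


def _cluster_result(table, labels):
    idx = table.track_ids()
    return ClusterResult(
        idx, np.zeros((len(idx), 2)), np.asarray(labels), k=int(np.max(labels)) + 1
    )


class TestAssign:
    def test_positions_inherit_labels(self):
        table = _table({("m1", "p1"): 2, ("m1", "p2"): 3})
        regions = RegionAssignment(
            pd.DataFrame(
                {
                    "mouse_id": ["m1", "m1"],
                    "position_id": ["p1", "p2"],
                    "region_label": ["Void", "TAMM/Oligo"],
                }
            ),
            label_set=["Void", "TAMM/Oligo"],
        )
        out = R.assign_regions(table, regions)
        assert (out.loc[("m1", "p1")] == "Void").all()
        assert (out.loc[("m1", "p2")] == "TAMM/Oligo").all()

    def test_per_cell_labels_win(self):
        table = _table({("m1", "p1"): 2})
        regions = RegionAssignment(
            pd.DataFrame(
                {
                    "mouse_id": ["m1", "m1"],
                    "position_id": ["p1", "p1"],
                    "track_id": [1, 2],
                    "region_label": ["Void", "TAMM/Oligo"],
                }
            ),
            label_set=["Void", "TAMM/Oligo"],
            source="per_cell_table",
        )
        out = R.assign_regions(table, regions)
        assert out.loc[("m1", "p1", 1)] == "Void"
        assert out.loc[("m1", "p1", 2)] == "TAMM/Oligo"

    def test_undeclared_label_rejected(self):
        with pytest.raises(ValueError, match="declared set"):
            RegionAssignment(
                pd.DataFrame(
                    {"mouse_id": ["m1"], "position_id": ["p1"], "region_label": ["Mystery"]}
                ),
                label_set=["Void"],
            ).validate()

    def test_uncovered_position_listed(self):
        table = _table({("m1", "p1"): 1, ("m1", "p2"): 1})
        regions = RegionAssignment(
            pd.DataFrame(
                {"mouse_id": ["m1"], "position_id": ["p1"], "region_label": ["Void"]}
            ),
            label_set=["Void"],
        )
        with pytest.raises(ValueError, match="p2"):
            R.assign_regions(table, regions)


class TestFrequencies:
    @staticmethod
    def _freqs(labels_by_pos, regions_by_pos):
        table = _table({k: len(v) for k, v in labels_by_pos.items()})
        labels = np.concatenate([np.asarray(v) for v in labels_by_pos.values()])
        res = _cluster_result(table, labels)
        rows = [
            {"mouse_id": m, "position_id": p, "region_label": r}
            for (m, p), r in regions_by_pos.items()
        ]
        regions = RegionAssignment(
            pd.DataFrame(rows), label_set=sorted(set(regions_by_pos.values()))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TrackphenoWarning)
            return R.cluster_frequencies(res, regions, table)

    def test_percentages(self):
        freqs = self._freqs(
            {("m1", "p1"): [0] * 7 + [1] * 3, ("m1", "p2"): [0, 1]},
            {("m1", "p1"): "Void", ("m1", "p2"): "Void"},
        )
        p1 = freqs[(freqs["position_id"] == "p1")].set_index("cluster")["pct"]
        assert p1[0] == pytest.approx(70.0)
        assert p1[1] == pytest.approx(30.0)

    def test_percentages_sum_to_100_per_position(self):
        freqs = self._freqs(
            {("m1", "p1"): [0, 0, 1, 2], ("m1", "p2"): [2, 2, 2, 1]},
            {("m1", "p1"): "Void", ("m1", "p2"): "TAMM/Oligo"},
        )
        sums = freqs.groupby(["mouse_id", "position_id"])["pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_zscores_mean_zero_sd_one_within_mouse_cluster(self):
        rng = np.random.default_rng(54)
        layout = {("m1", f"p{i}"): list(rng.integers(0, 3, size=8)) for i in range(1, 5)}
        freqs = self._freqs(
            layout, {k: "Void" for k in layout}
        )
        for (_, _), g in freqs.groupby(["mouse_id", "cluster"]):
            z = g["pct_z"].dropna()
            if len(z) >= 2:
                assert z.mean() == pytest.approx(0.0, abs=1e-9)
                assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_single_position_mouse_missing_z(self):
        freqs = self._freqs(
            {("m1", "p1"): [0, 1], ("m2", "p1"): [0, 1], ("m2", "p2"): [1, 1]},
            {("m1", "p1"): "Void", ("m2", "p1"): "Void", ("m2", "p2"): "Void"},
        )
        m1 = freqs[freqs["mouse_id"] == "m1"]
        assert m1["pct_z"].isna().all()

    def test_track_order_invariance(self):
        a = self._freqs(
            {("m1", "p1"): [0, 1, 1, 2], ("m1", "p2"): [2, 1, 0, 0]},
            {("m1", "p1"): "Void", ("m1", "p2"): "Void"},
        )
        b = self._freqs(
            {("m1", "p1"): [1, 1, 2, 0], ("m1", "p2"): [0, 0, 1, 2]},
            {("m1", "p1"): "Void", ("m1", "p2"): "Void"},
        )
        pd.testing.assert_frame_equal(
            a.sort_values(["position_id", "cluster"]).reset_index(drop=True),
            b.sort_values(["position_id", "cluster"]).reset_index(drop=True),
        )


class TestCompareRegions:
    @staticmethod
    def _planted_freqs(rng, effect=0.0, n_mice=4, pos_per_region=2):
        """Synthetic per-position percentages: cluster 0 enriched by `effect`
        in region B, with mouse-level baseline offsets."""
        rows = []
        for m in range(n_mice):
            base = rng.normal(30, 3)
            for region in ("A", "B"):
                for p in range(pos_per_region):
                    bump = effect if region == "B" else 0.0
                    pct0 = np.clip(base + bump + rng.normal(0, 2), 1, 95)
                    rest = 100 - pct0
                    rows.append(
                        {
                            "mouse_id": f"m{m}",
                            "position_id": f"{region}{p}",
                            "region_label": region,
                            "cluster": 0,
                            "pct": pct0,
                        }
                    )
                    rows.append(
                        {
                            "mouse_id": f"m{m}",
                            "position_id": f"{region}{p}",
                            "region_label": region,
                            "cluster": 1,
                            "pct": rest,
                        }
                    )
        freqs = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TrackphenoWarning)
            freqs["pct_z"] = ST.zscore_within(
                freqs["pct"].to_numpy(),
                (freqs["mouse_id"] + "|" + freqs["cluster"].astype(str)).to_numpy(),
            )
        return freqs

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(10):
            tests = R.compare_regions(
                self._planted_freqs(rng, effect=12.0), post_hoc=False
            )
            hits += tests[0]["anova"].pvalue < 0.05
        assert hits >= 9

    def test_null_calibration(self):
        # z-scoring couples the positions of one mouse; with >= 4 positions
        # per region the residual coupling is negligible and the omnibus
        # test is calibrated
        rng = np.random.default_rng(56)
        rejections = 0
        n = 200
        for _ in range(n):
            tests = R.compare_regions(
                self._planted_freqs(rng, effect=0.0, pos_per_region=4), post_hoc=False
            )
            rejections += tests[0]["anova"].pvalue < 0.05
        assert 0.05 - 0.04 <= rejections / n <= 0.05 + 0.04

    def test_two_regions_tukey_matches_anova(self):
        rng = np.random.default_rng(57)
        tests = R.compare_regions(self._planted_freqs(rng, effect=6.0))
        for res in tests.values():
            assert len(res["tukey"]) == 1
            assert res["tukey"]["p_adj"].item() == pytest.approx(
                res["anova"].pvalue, abs=1e-6
            )

    def test_degenerate_groups_skipped(self):
        freqs = pd.DataFrame(
            {
                "mouse_id": ["m1"] * 2,
                "position_id": ["p1", "p2"],
                "region_label": ["A", "B"],
                "cluster": [0, 0],
                "pct": [50.0, 50.0],
                "pct_z": [np.nan, np.nan],
            }
        )
        with pytest.warns(TrackphenoWarning, match="skipped"):
            out = R.compare_regions(freqs)
        assert out == {}
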