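"""Imaging feature extraction, cell typing, niches and spatial statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import distance_transform_edt
from sklearn.metrics import adjusted_rand_score

from c3map import codex, synthetic
from c3map.config import SynthConfig


# ---------------------------------------------------------------------------
# masks and ring percentages


class TestExpandMasks:
    def test_distant_nuclei_fully_dilated(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[5:8, 5:8] = 1
        mask[30:33, 30:33] = 2
        out = codex.expand_masks(mask, 3)
        assert (out == 1).sum() > (mask == 1).sum()
        assert (out == 2).sum() == (out == 1).sum()  # same shape, same growth

    def test_adjacent_nuclei_split_at_equidistance(self):
        """Contested pixels go to the nearer nucleus (distance-transform oracle)."""
        mask = np.zeros((21, 41), dtype=np.int32)
        mask[10, 10] = 1
        mask[10, 30] = 2
        out = codex.expand_masks(mask, 30)
        d1 = distance_transform_edt(mask != 1)
        d2 = distance_transform_edt(mask != 2)
        assigned = out > 0
        # every strictly-closer assigned pixel belongs to its nearer nucleus;
        # exactly equidistant pixels may break ties either way
        assert (out[assigned & (d1 < d2)] == 1).all()
        assert (out[assigned & (d2 < d1)] == 2).all()
        # labels stay disjoint by construction of a single label image
        assert set(np.unique(out)) <= {0, 1, 2}

    def test_radius_zero_is_identity(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:4, 2:4] = 5
        assert (codex.expand_masks(mask, 0) == mask).all()


class TestRingPercentage:
    def _single_cell(self, ring_value):
        mask = np.zeros((31, 31), dtype=np.int32)
        yy, xx = np.mgrid[0:31, 0:31]
        d2 = (yy - 15) ** 2 + (xx - 15) ** 2
        mask[d2 <= 25] = 1  # radius-5 nucleus
        intensity = np.zeros((31, 31), dtype=float)
        ring = (d2 > 25) & (d2 <= 64)  # radius 5..8 band
        intensity[ring] = ring_value
        return mask, intensity

    def test_fully_positive_ring_scores_100(self):
        mask, intensity = self._single_cell(100.0)
        pct = codex.ring_percentage(mask, intensity, ring_width=3)
        assert pct.loc[1, "marker"] == pytest.approx(100.0)

    def test_half_positive_ring_scores_near_50(self):
        mask, intensity = self._single_cell(100.0)
        intensity[:, 16:] = 0.0  # wipe the right half of the ring
        pct = codex.ring_percentage(mask, intensity, ring_width=3)
        assert pct.loc[1, "marker"] == pytest.approx(50.0, abs=3.0)

    def test_intensity_exactly_20_not_positive(self):
        mask, intensity = self._single_cell(20.0)
        pct = codex.ring_percentage(mask, intensity, ring_width=3)
        assert pct.loc[1, "marker"] == 0.0

    def test_generated_image_truth_recovered(self):
        mask, intensity, truth = synthetic.generate_codex_images(seed=4)
        pct = codex.ring_percentage(mask, intensity, ring_width=3)
        called = pct["marker"] > 50
        assert (called == truth.loc[pct.index]).all()


# ---------------------------------------------------------------------------
# typing


def _typed_cells(seed=0, n_per_class=400, classes=("A", "B", "C")):
    """Well-separated Gaussian classes in two marker channels."""
    rng = np.random.default_rng(seed)
    frames = []
    centers = {"A": (10, 0), "B": (0, 10), "C": (10, 10)}
    for cls in classes:
        cx, cy = centers[cls]
        frames.append(
            pd.DataFrame(
                {
                    "m1": rng.normal(cx, 1.0, n_per_class),
                    "m2": rng.normal(cy, 1.0, n_per_class),
                    "truth": cls,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestGating:
    def test_planted_classes_gated_with_full_precision(self):
        cells = _typed_cells()
        gates = {
            "A": [("m1", ">=", 7.0), ("m2", "<=", 4.0)],
            "B": [("m1", "<=", 4.0), ("m2", ">=", 7.0)],
        }
        labels = codex.gate_training_set(cells, gates)
        assert len(labels) > 0
        assert (labels == cells.loc[labels.index, "truth"]).all()

    def test_contradictory_gate_warns_and_matches_nothing(self):
        cells = _typed_cells()
        with pytest.warns(UserWarning, match="matched no cells"):
            labels = codex.gate_training_set(
                cells, {"X": [("m1", ">=", 5.0), ("m1", "<=", -5.0)]}
            )
        assert len(labels) == 0

    def test_ambiguous_cells_excluded(self):
        cells = pd.DataFrame({"m1": [10.0, 0.0]})
        gates = {"P": [("m1", ">=", 5.0)], "Q": [("m1", ">=", 8.0)]}
        labels = codex.gate_training_set(cells, gates)
        assert 0 not in labels.index  # satisfies both P and Q -> ambiguous


class TestBalanceClasses:
    def test_cap_applied_only_above(self):
        labels = pd.Series(["big"] * 3000 + ["small"] * 1200)
        out = codex.balance_classes(labels, cap=2500, seed=0)
        counts = out.value_counts()
        assert counts["big"] == 2500 and counts["small"] == 1200

    def test_seeded_reproducibility(self):
        labels = pd.Series(["big"] * 3000 + ["small"] * 100)
        o1 = codex.balance_classes(labels, cap=2500, seed=5)
        o2 = codex.balance_classes(labels, cap=2500, seed=5)
        assert list(o1.index) == list(o2.index)


class TestKnnClassify:
    def test_well_separated_classes_accurate(self):
        cells = _typed_cells(seed=1)
        train = cells.iloc[::2]
        query = cells.iloc[1::2]
        pred = codex.knn_classify(
            train, train["truth"], query, ["m1", "m2"], k=50
        )
        assert (pred == query["truth"].to_numpy()).mean() >= 0.95

    def test_k1_on_training_point_returns_own_label(self):
        cells = _typed_cells(seed=2, n_per_class=30)
        pred = codex.knn_classify(cells, cells["truth"], cells, ["m1", "m2"], k=1)
        assert (pred == cells["truth"].to_numpy()).all()

    def test_matches_brute_force_neighbor_scan(self):
        cells = _typed_cells(seed=3, n_per_class=80)  # 240 training cells
        rng = np.random.default_rng(4)
        query = pd.DataFrame(
            {"m1": rng.uniform(-2, 12, 100), "m2": rng.uniform(-2, 12, 100)}
        )
        k = 7
        pred = codex.knn_classify(cells, cells["truth"], query, ["m1", "m2"], k=k)
        # brute force in the identically scaled space
        from sklearn.preprocessing import RobustScaler

        scaler = RobustScaler().fit(cells[["m1", "m2"]])
        T = scaler.transform(cells[["m1", "m2"]])
        Q = scaler.transform(query)
        labels = cells["truth"].to_numpy()
        for i in range(len(query)):
            d = ((T - Q[i]) ** 2).sum(axis=1)
            nearest = labels[np.argsort(d, kind="stable")[:k]]
            vals, counts = np.unique(nearest, return_counts=True)
            expected = min(vals[counts == counts.max()])
            assert pred[i] == expected


class TestRescueClassify:
    def test_surrounded_cell_gets_unanimous_label(self):
        cells = _typed_cells(seed=5)
        unresolved = pd.DataFrame({"m1": [10.0], "m2": [0.2]})  # deep in class A
        out = codex.rescue_classify(
            unresolved, cells, cells["truth"], ["m1", "m2"], seed=1
        )
        assert out["label"].iloc[0] == "A" and out["accepted"].iloc[0]

    def test_rescued_immune_cells_rejected(self):
        cells = _typed_cells(seed=6)
        unresolved = pd.DataFrame({"m1": [0.1], "m2": [10.0]})  # class B territory
        out = codex.rescue_classify(
            unresolved, cells, cells["truth"], ["m1", "m2"],
            immune_labels={"B"}, seed=1,
        )
        assert out["label"].iloc[0] == "B" and not out["accepted"].iloc[0]

    def test_votes_match_per_round_recomputation(self):
        cells = _typed_cells(seed=7, n_per_class=200)
        rng = np.random.default_rng(8)
        unresolved = pd.DataFrame(
            {"m1": rng.uniform(0, 10, 20), "m2": rng.uniform(0, 10, 20)}
        )
        out = codex.rescue_classify(
            unresolved, cells, cells["truth"], ["m1", "m2"],
            rounds=10, per_class=50, k=5, seed=3,
        )
        # replay the rounds with the same derived seeds
        from collections import Counter

        seed_rng = np.random.default_rng([8, 3])
        votes = []
        for _ in range(10):
            rd_seed = int(seed_rng.integers(0, 2**31 - 1))
            sub = codex.balance_classes(cells["truth"], cap=50, seed=rd_seed)
            votes.append(
                codex.knn_classify(cells.loc[sub.index], sub, unresolved,
                                   ["m1", "m2"], k=5)
            )
        votes = np.stack(votes, axis=1)
        for i in range(len(unresolved)):
            counts = Counter(votes[i])
            top = max(counts.values())
            assert out["label"].iloc[i] == min(
                l for l, c in counts.items() if c == top
            )


# ---------------------------------------------------------------------------
# neighborhood profiles and niches


class TestNeighborhoodProfiles:
    def test_isolated_cell_is_pure_self(self):
        cells = pd.DataFrame(
            {
                "spot_id": ["s1"] * 3,
                "x": [0.0, 5000.0, 5000.0],
                "y": [0.0, 5000.0, 5010.0],
                "broad_type": ["A", "B", "B"],
            }
        )
        prof, n_used = codex.neighborhood_profiles(cells, categories=["A", "B"])
        assert prof.iloc[0].tolist() == [1.0, 0.0]
        assert n_used[0] == 0

    def test_ten_neighbors_of_one_type(self):
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        cells = pd.DataFrame(
            {
                "spot_id": "s1",
                "x": np.concatenate([[0.0], 10 * np.cos(angles)]),
                "y": np.concatenate([[0.0], 10 * np.sin(angles)]),
                "broad_type": ["B"] + ["A"] * 10,
            }
        )
        prof, _ = codex.neighborhood_profiles(cells, categories=["A", "B"])
        assert prof.iloc[0]["A"] == pytest.approx(10 / 11)
        assert prof.iloc[0]["B"] == pytest.approx(1 / 11)

    def test_matches_brute_force_distance_sort(self):
        rng = np.random.default_rng(9)
        cells = pd.DataFrame(
            {
                "spot_id": "s1",
                "x": rng.uniform(0, 400, 300),
                "y": rng.uniform(0, 400, 300),
                "broad_type": rng.choice(["A", "B", "C"], 300),
            }
        )
        cats = ["A", "B", "C"]
        prof, _ = codex.neighborhood_profiles(cells, categories=cats)
        pos = cells[["x", "y"]].to_numpy()
        types = cells["broad_type"].to_numpy()
        for i in range(0, 300, 17):
            d = np.sqrt(((pos - pos[i]) ** 2).sum(axis=1))
            order = [j for j in np.argsort(d, kind="stable") if d[j] <= 200][:11]
            counts = pd.Series(types[order]).value_counts()
            for c in cats:
                assert prof.iloc[i][c] == pytest.approx(
                    counts.get(c, 0) / len(order)
                )

    def test_profiles_sum_to_one(self, codex_profiles):
        prof, _ = codex_profiles
        assert np.allclose(prof.sum(axis=1), 1.0)


class TestNicheDetection:
    def test_auc_curve_high_up_to_planted_k_then_flat_or_declining(self, codex_profiles):
        prof, _ = codex_profiles
        curve = codex.select_k_niches(prof, [2, 3, 4, 6, 8], seed=0)
        auc = dict(zip(curve["k"], curve["mean_auc"]))
        assert all(auc[k] >= 0.9 for k in (2, 3, 4))
        assert max(auc[6], auc[8]) <= auc[4] + 0.02

    def test_k1_skipped_with_warning(self, codex_profiles):
        prof, _ = codex_profiles
        with pytest.warns(UserWarning, match="degenerate"):
            curve = codex.select_k_niches(prof, [1, 2], seed=0)
        assert curve["k"].tolist() == [2]

    def test_curve_reproducible(self, codex_profiles):
        prof, _ = codex_profiles
        c1 = codex.select_k_niches(prof, [3, 4], seed=7)
        c2 = codex.select_k_niches(prof, [3, 4], seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_planted_niches_recovered(self, codex_cells, codex_profiles):
        prof, _ = codex_profiles
        assignment, niches = codex.detect_niches(prof, 4, seed=0)
        assert adjusted_rand_score(codex_cells["niche_true"], assignment) >= 0.8
        for n in niches:
            assert n.centroid.sum() == pytest.approx(1.0, abs=1e-6)
            assert n.label != "unlabelled"

    def test_assignment_deterministic(self, codex_profiles):
        prof, _ = codex_profiles
        a1, _ = codex.detect_niches(prof, 4, seed=3)
        a2, _ = codex.detect_niches(prof, 4, seed=3)
        assert (a1 == a2).all()


class TestMergeNiches:
    def test_named_pair_merge_reduces_count_by_one(self, codex_profiles):
        prof, _ = codex_profiles
        assignment, niches = codex.detect_niches(prof, 5, seed=0)
        merged_assign, merged = codex.merge_niches(assignment, niches, pair=(1, 3))
        assert len(merged) == 4
        assert 3 not in set(merged_assign)
        m = {n.niche_id: n for n in merged}
        assert len(m[1].members) == len(niches[1].members) + len(niches[3].members)

    def test_merging_identical_niches_keeps_centroid(self):
        from c3map.containers import CellularNiche

        c = np.array([0.5, 0.5])
        niches = [
            CellularNiche(0, c.copy(), "x", np.array([0, 1])),
            CellularNiche(1, c.copy(), "x", np.array([2, 3])),
        ]
        assignment = np.array([0, 0, 1, 1])
        _, merged = codex.merge_niches(assignment, niches, pair=(0, 1))
        assert np.allclose(merged[0].centroid, c)

    def test_similarity_threshold_merge(self, codex_profiles):
        prof, _ = codex_profiles
        assignment, niches = codex.detect_niches(prof, 6, seed=0)
        merged_assign, merged = codex.merge_niches(
            assignment, niches, similarity_threshold=0.999999
        )
        assert len(merged) <= len(niches)

    def test_exactly_one_mode_required(self, codex_profiles):
        prof, _ = codex_profiles
        assignment, niches = codex.detect_niches(prof, 3, seed=0)
        with pytest.raises(ValueError):
            codex.merge_niches(assignment, niches)


class TestNicheEntropy:
    def test_pure_niche_zero(self):
        assert codex.niche_entropy(["A"] * 10) == pytest.approx(0.0)

    def test_uniform_niche_log_n(self):
        for n in (2, 3, 4, 6):
            members = [f"t{i}" for i in range(n)] * 5
            assert codex.niche_entropy(members) == pytest.approx(np.log(n))

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(10)
        members = list(rng.choice(["A", "B", "C", "D"], 50))
        s = codex.niche_entropy(members)
        brute = 0.0
        for t in set(members):
            p = members.count(t) / len(members)
            brute -= p * np.log(p)
        assert s == pytest.approx(brute)

    def test_entropy_bounds_and_mixing_inequality(self):
        rng = np.random.default_rng(11)
        a = list(rng.choice(["A", "B", "C"], 40, p=[0.7, 0.2, 0.1]))
        b = list(rng.choice(["A", "B", "C"], 160, p=[0.1, 0.1, 0.8]))
        sa, sb = codex.niche_entropy(a), codex.niche_entropy(b)
        s_union = codex.niche_entropy(a + b)
        assert 0 <= s_union <= np.log(3)
        w = len(a) / (len(a) + len(b))
        assert s_union >= w * sa + (1 - w) * sb - 1e-12  # concavity


class TestEnrichmentAndProximity:
    def test_planted_subtype_enrichment_detected(self, codex_cells):
        cells = codex_cells.copy()
        cells["niche"] = cells["niche_true"]
        enr = codex.subtype_enrichment(cells)
        row = enr[(enr["niche"] == 1) & (enr["subtype"] == "CD8T")].iloc[0]
        assert row["odds_ratio"] > 1 and row["pval"] < 1e-10

    def test_uniform_assignment_not_inflated(self):
        rng = np.random.default_rng(12)
        n_sig = 0
        n_tot = 0
        for _ in range(20):
            cells = pd.DataFrame(
                {
                    "niche": rng.integers(0, 4, 400),
                    "broad_type": rng.choice(["A", "B", "C"], 400),
                }
            )
            enr = codex.subtype_enrichment(cells)
            n_sig += (enr["pval"] <= 0.05).sum()
            n_tot += len(enr)
        assert n_sig / n_tot <= 0.075

    def test_planted_marker_shift_recovered(self, codex_cells):
        cells = codex_cells.copy()
        cells["niche"] = cells["niche_true"]
        res = codex.marker_enrichment(cells, "CD8T", "CD49a", 3)
        assert res is not None and res["pval"] < 0.05 and res["effect"] > 0

    def test_too_few_cells_skipped(self, codex_cells):
        cells = codex_cells.head(50).copy()
        cells["niche"] = 0
        with pytest.warns(UserWarning, match="too few"):
            res = codex.marker_enrichment(cells, "CD8T", "CD49a", 99)
        assert res is None

    def _layout(self, interleaved: bool):
        # 30 queries and 30 targets per spot; either interleaved on a grid
        # or segregated into two distant bands
        rows = []
        for spot in ("s1", "s2"):
            for i in range(30):
                if interleaved:
                    rows.append((spot, (i % 6) * 20, (i // 6) * 20, "Q"))
                    rows.append((spot, (i % 6) * 20 + 10, (i // 6) * 20, "T"))
                else:
                    rows.append((spot, (i % 6) * 20, (i // 6) * 20, "Q"))
                    rows.append((spot, (i % 6) * 20 + 500, (i // 6) * 20, "T"))
        return pd.DataFrame(rows, columns=["spot_id", "x", "y", "broad_type"])

    def test_interleaved_layout_closer_than_segregated(self):
        near = codex.median_nearest_distances(self._layout(True), "Q", "T")
        far = codex.median_nearest_distances(self._layout(False), "Q", "T")
        assert near.max() < far.min()

    def test_spot_below_minimum_examples_excluded(self):
        cells = self._layout(True)
        # s2 keeps only 24 targets: below the >= 25 requirement
        drop = cells[(cells.spot_id == "s2") & (cells.broad_type == "T")].index[:6]
        cells = cells.drop(drop)
        med = codex.median_nearest_distances(cells, "Q", "T")
        assert set(med.index) == {"s1"}

    def test_self_target_excludes_own_cell(self):
        cells = self._layout(True)
        med = codex.median_nearest_distances(
            cells, "Q", "Q", min_examples=25
        )
        assert (med > 0).all()

    def test_proximity_comparison_significant(self):
        near = self._layout(True)
        far = self._layout(False)
        far["broad_type"] = far["broad_type"].replace({"Q": "Q2"})
        far["spot_id"] = far["spot_id"].replace({"s1": "s3", "s2": "s4"})
        cells = pd.concat([near, far], ignore_index=True)
        # give every spot both targets close by for Q and far for Q2
        res = codex.proximity_analysis(cells, "Q", "Q2", "T")
        assert res["medians_a"].median() < res["medians_b"].median()

    def test_matches_brute_force_nearest_scan(self, codex_cells):
        sub = codex_cells[codex_cells["spot_id"] == "core0"]
        med = codex.median_nearest_distances(codex_cells, "CD8T", "Stromal")
        q = sub[sub["broad_type"] == "CD8T"][["x", "y"]].to_numpy()
        t = sub[sub["broad_type"] == "Stromal"][["x", "y"]].to_numpy()
        dists = [np.sqrt(((t - qi) ** 2).sum(axis=1)).min() for qi in q]
        assert med["core0"] == pytest.approx(np.median(dists))
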