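from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hippoparc import transcriptomics as tx
from hippoparc.synth import generate_donor_expression


@pytest.fixture(scope="module")
def donor_data():
    return generate_donor_expression(seed=7)


def small_probe_table(entrez):
    n = len(entrez)
    probes = [f"p{i}" for i in range(n)]
    ann = pd.DataFrame(
        {"gene_symbol": [f"G{i}" for i in range(n)], "entrez_id": entrez},
        index=pd.Index(probes, name="probe_id"),
    )
    intensity = pd.DataFrame(
        np.ones((4, n)), columns=probes, index=[f"s{i}" for i in range(4)]
    )
    flags = intensity > 0
    return tx.ProbeTable(annotations=ann, intensity=intensity, above_background=flags)


class TestProbeFiltering:
    def test_drop_unannotated(self):
        pt = small_probe_table([101, np.nan, 102, -1, 103])
        out = tx.drop_unannotated_probes(pt)
        assert list(out.annotations.index) == ["p0", "p2", "p4"]
        assert list(out.intensity.columns) == ["p0", "p2", "p4"]

    def test_all_annotated_identity(self):
        pt = small_probe_table([1, 2, 3])
        assert list(tx.drop_unannotated_probes(pt).annotations.index) == ["p0", "p1", "p2"]

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError, match="Entrez"):
            tx.drop_unannotated_probes(small_probe_table([np.nan, np.nan]))

    def test_intensity_filter_boundary(self):
        pt = small_probe_table([1, 2, 3])
        # p0 always above, p1 exactly half below (discarded), p2 always below
        pt.above_background.loc[:, "p1"] = [True, True, False, False]
        pt.above_background.loc[:, "p2"] = False
        out = tx.intensity_filter(pt)
        assert list(out.annotations.index) == ["p0"]


class TestDifferentialStability:
    def test_identical_patterns_give_one(self):
        pattern = pd.Series([1.0, 3.0, 2.0, 5.0], index=list("abcd"))
        assert tx.differential_stability({"d1": pattern, "d2": pattern, "d3": pattern}) == 1.0

    def test_two_donors_single_spearman(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=10), index=range(10))
        b = pd.Series(rng.normal(size=10), index=range(10))
        expected = sps.spearmanr(a, b).statistic
        assert tx.differential_stability({"d1": a, "d2": b}) == pytest.approx(expected)

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(1)
        donors = {f"d{i}": pd.Series(rng.normal(size=12), index=range(12)) for i in range(4)}
        brute = np.mean(
            [
                sps.spearmanr(donors[a], donors[b]).statistic
                for a, b in combinations(sorted(donors), 2)
            ]
        )
        assert tx.differential_stability(donors) == pytest.approx(brute, abs=1e-12)

    def test_vectorized_scores_match_scalar(self):
        rng = np.random.default_rng(2)
        regional = {
            f"d{i}": pd.DataFrame(
                rng.normal(size=(10, 5)), index=range(10), columns=[f"p{j}" for j in range(5)]
            )
            for i in range(3)
        }
        scores = tx.differential_stability_scores(regional)
        for p in scores.index:
            scalar = tx.differential_stability({d: m[p] for d, m in regional.items()})
            assert scores[p] == pytest.approx(scalar, abs=1e-12)

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            tx.differential_stability({"d1": pd.Series([1.0, 2.0, 3.0])})


class TestProbeSelection:
    def test_max_ds_wins_and_tie_breaks_to_smaller_id(self):
        pt = small_probe_table([1, 2, 3, 4])
        pt.annotations["gene_symbol"] = ["GA", "GA", "GB", "GB"]
        scores = pd.Series({"p0": 0.2, "p1": 0.9, "p2": 0.5, "p3": 0.5})
        chosen = tx.select_probe_per_gene(scores, pt)
        assert chosen["GA"] == "p1"
        assert chosen["GB"] == "p2"  # exact tie -> lexicographically smallest

    def test_single_probe_gene(self):
        pt = small_probe_table([1])
        chosen = tx.select_probe_per_gene(pd.Series({"p0": 0.1}), pt)
        assert chosen == {"G0": "p0"}


class TestAssignSamples:
    def test_centroid_sample_and_hemisphere_constraint(self, donor_data):
        pt, donors, region_meta, truth = donor_data
        donor = next(iter(donors.values()))
        out = tx.assign_samples(donor, region_meta)
        # samples were generated near their own region centroid
        expected = list(region_meta.index)
        assert list(out["region"]) == expected

    def test_wrong_hemisphere_never_assigned(self, donor_data):
        pt, donors, region_meta, truth = donor_data
        donor = next(iter(donors.values()))
        meta = region_meta.copy()
        meta.loc[meta.index[:10], "hemisphere"] = "R"  # samples are all L
        out = tx.assign_samples(donor, meta)
        assigned = out.loc[out["region"] != -1, "region"]
        assert not set(assigned) & set(meta.index[:10])

    def test_distance_outlier_excluded(self, donor_data):
        pt, donors, region_meta, truth = donor_data
        donor = next(iter(donors.values()))
        samples = donor.samples.copy()
        samples.loc[samples.index[0], "x"] += 500.0  # 10x the typical distance
        moved = tx.DonorExpression(
            donor_id=donor.donor_id, samples=samples, expression=donor.expression
        )
        out = tx.assign_samples(moved, region_meta)
        assert not out.loc[samples.index[0], "kept"]

    def test_no_candidate_region_unassigned(self, donor_data):
        pt, donors, region_meta, truth = donor_data
        donor = next(iter(donors.values()))
        meta = region_meta[region_meta["division"] == "cortex"]
        out = tx.assign_samples(donor, meta)
        sub_samples = donor.samples["division"] == "subcortex/brainstem"
        assert (out.loc[sub_samples.to_numpy(), "region"] == -1).all()


class TestFillMissingRegions:
    def test_inverse_distance_weighted_mean(self):
        # two donors at distances 1 and 3 with values 10 and 20 -> 12.5
        meta = pd.DataFrame(
            {"x": [0.0], "y": [0.0], "z": [0.0], "hemisphere": ["L"], "division": ["cortex"]},
            index=pd.Index([1], name="region"),
        )
        donors, normalized, assignments = {}, {}, {}
        for donor_id, dist, value in [("d1", 1.0, 10.0), ("d2", 3.0, 20.0)]:
            samples = pd.DataFrame(
                {"x": [dist], "y": [0.0], "z": [0.0], "hemisphere": ["L"], "division": ["cortex"]},
                index=pd.Index([f"{donor_id}_s"], name="sample_id"),
            )
            expr = pd.DataFrame({"g": [value]}, index=samples.index)
            donors[donor_id] = tx.DonorExpression(donor_id, samples, expr)
            normalized[donor_id] = expr
            assignments[donor_id] = pd.DataFrame(
                {"region": [-1], "distance": [np.nan], "kept": [False]}, index=samples.index
            )
        filled, imputed = tx.fill_missing_regions(assignments, donors, meta, normalized)
        assert imputed == [1]
        assert filled[1]["g"] == pytest.approx(12.5)

    def test_assigned_regions_untouched(self, donor_data):
        pt, donors, region_meta, truth = donor_data
        assignments = {d: tx.assign_samples(don, region_meta) for d, don in donors.items()}
        normalized = {d: don.expression for d, don in donors.items()}
        filled, imputed = tx.fill_missing_regions(assignments, donors, region_meta, normalized)
        assert imputed == []  # every region has samples in this design


class TestNormalization:
    def test_median_maps_to_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        out = tx.robust_sigmoid(x)
        assert out[2] == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        x = np.sort(np.random.default_rng(0).normal(size=50))
        out = tx.robust_sigmoid(x)
        assert np.all(np.diff(out) >= 0)
        assert out.max() < 1.0 and out.min() > 0.0

    def test_outlier_stays_bounded(self):
        out = tx.robust_sigmoid(np.array([0.0, 1.0, 2.0, 3.0, 1e9]))
        assert out[-1] < 1.0

    def test_zero_iqr_degenerates_to_half(self):
        assert np.allclose(tx.robust_sigmoid(np.full(6, 2.0)), 0.5)

    def test_rescale_endpoints(self):
        x = np.array([0.3, 0.9, 0.5])
        out = tx.rescale_unit(x)
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[np.argmin(x)] == 0.0 and out[np.argmax(x)] == 1.0

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_rescale_affine_invariance(self, a, b):
        x = np.array([0.1, 0.7, 0.3, 0.95, 0.5])
        np.testing.assert_allclose(
            tx.rescale_unit(a * x + b), tx.rescale_unit(x), atol=1e-9
        )

    def test_normalize_matrix_bounded_and_affine_invariant(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(12, 8)))
        out = tx.normalize_matrix(mat)
        assert out.to_numpy().min() >= 0.0 and out.to_numpy().max() <= 1.0
        out2 = tx.normalize_matrix(3.0 * mat + 11.0)
        np.testing.assert_allclose(out.to_numpy(), out2.to_numpy(), atol=1e-9)

    def test_normalize_matrix_preserves_rank_order_per_gene(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(10, 4)))
        out = tx.normalize_matrix(mat)
        # the final (across-samples) pass is monotone per gene column
        for c in mat.columns:
            assert sps.spearmanr(mat[c], out[c]).statistic > 0


class TestAggregationAndGenesets:
    def test_two_donor_average(self):
        meta = pd.DataFrame(
            {"x": [0.0], "y": [0.0], "z": [0.0], "hemisphere": ["L"], "division": ["cortex"]},
            index=pd.Index([1], name="region"),
        )
        normalized, assignments = {}, {}
        for donor_id, value in [("d1", 0.2), ("d2", 0.4)]:
            idx = pd.Index([f"{donor_id}_s"], name="sample_id")
            normalized[donor_id] = pd.DataFrame({"g": [value]}, index=idx)
            assignments[donor_id] = pd.DataFrame(
                {"region": [1], "distance": [0.1], "kept": [True]}, index=idx
            )
        rem = tx.aggregate_regions(normalized, assignments, meta)
        assert rem.values.loc[1, "g"] == pytest.approx(0.3)

    def test_donor_missing_region_skipped(self):
        meta = pd.DataFrame(
            {"x": [0.0, 5.0], "y": 0.0, "z": 0.0, "hemisphere": "L", "division": "cortex"},
            index=pd.Index([1, 2], name="region"),
        )
        normalized, assignments = {}, {}
        idx1 = pd.Index(["d1_a", "d1_b"], name="sample_id")
        normalized["d1"] = pd.DataFrame({"g": [0.1, 0.9]}, index=idx1)
        assignments["d1"] = pd.DataFrame(
            {"region": [1, 2], "distance": 0.1, "kept": True}, index=idx1
        )
        idx2 = pd.Index(["d2_a"], name="sample_id")
        normalized["d2"] = pd.DataFrame({"g": [0.5]}, index=idx2)
        assignments["d2"] = pd.DataFrame(
            {"region": [1], "distance": 0.1, "kept": True}, index=idx2
        )
        rem = tx.aggregate_regions(normalized, assignments, meta)
        assert rem.values.loc[1, "g"] == pytest.approx(0.3)
        assert rem.values.loc[2, "g"] == pytest.approx(0.9)  # only d1 has region 2

    def test_geneset_intersection(self):
        gs = tx.intersect_genesets(["A", "b", "C"], ["B", "c", "D"], "GO:X")
        assert gs.genes == ["B", "C"]
        empty = tx.intersect_genesets(["A"], ["B"])
        assert empty.empty

    def test_geneset_map_single_and_mean(self):
        values = pd.DataFrame(
            {"G1": [0.2, 0.8, 0.5], "G2": [0.6, 0.4, 0.5]},
            index=pd.Index([1, 2, 3], name="region"),
        )
        rem = tx.RegionExpressionMatrix(values=values)
        single = tx.geneset_expression_map(rem, tx.GeneSet("s", ["G1"]))
        np.testing.assert_allclose(single.values, values["G1"])
        both = tx.geneset_expression_map(rem, tx.GeneSet("s", ["G1", "G2"]))
        np.testing.assert_allclose(both.values, [0.4, 0.6, 0.5])
        with pytest.raises(ValueError, match="no genes"):
            tx.geneset_expression_map(rem, tx.GeneSet("s", ["NOPE"]))


class TestFullChain:
    def test_zero_noise_gradient_recovery(self):
        pt, donors, region_meta, truth = generate_donor_expression(noise_sd=0.0, seed=9)
        rem, scores = tx.build_region_expression(pt, donors, region_meta)
        # gradient probes achieve perfect cross-donor rank stability
        grad_probes = [
            p
            for p, g in truth["probe_gene"].items()
            if g in truth["gradient_genes"]
            and p not in truth["dim_probes"]
            and p not in truth["unannotated_probes"]
        ]
        for p in grad_probes:
            assert scores[p] == pytest.approx(1.0)
        # the gene-set map over gradient genes reproduces the planted rank order
        gs = tx.intersect_genesets(truth["gradient_genes"], list(rem.values.columns), "grad")
        gmap = tx.geneset_expression_map(rem, gs)
        rho = sps.spearmanr(gmap.values.to_numpy(), truth["gradient"]).statistic
        assert rho == pytest.approx(1.0)

    def test_nongradient_ds_near_zero(self):
        pt, donors, region_meta, truth = generate_donor_expression(seed=10)
        rem, scores = tx.build_region_expression(pt, donors, region_meta)
        non_grad = [
            p
            for p, g in truth["probe_gene"].items()
            if g not in truth["gradient_genes"] and p in scores.index
        ]
        # mean over many independent-noise probes stays within the null band
        n_pairs = 15  # 6 donors -> 15 pairs, 30 regions each
        assert abs(scores[non_grad].mean()) < 3 / np.sqrt(len(non_grad) * 29)

    def test_determinism(self):
        a = generate_donor_expression(seed=11)
        b = generate_donor_expression(seed=11)
        pd.testing.assert_frame_equal(a[0].intensity, b[0].intensity)
        rem_a, _ = tx.build_region_expression(a[0], a[1], a[2])
        rem_b, _ = tx.build_region_expression(b[0], b[1], b[2])
        pd.testing.assert_frame_equal(rem_a.values, rem_b.values)

    def test_hemisphere_exclusion(self):
        pt, donors, region_meta, truth = generate_donor_expression(seed=12)
        meta = region_meta.copy()
        meta.loc[meta.index[-5:], "hemisphere"] = "R"
        rem, _ = tx.build_region_expression(pt, donors, meta, exclude_hemisphere="R")
        assert not set(rem.values.index) & set(meta.index[-5:])
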