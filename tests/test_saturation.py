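"""Saturation-phase analysis: clustering, correlations, membership tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from decayomics import (
    SimConfig,
    ValidationError,
    build_points,
    cross_phase_membership,
    generate_truth,
    kmeans_1d,
    pearson_with_p,
    phase_correlations,
)
from decayomics.saturation import assign_phases


def make_points(rng, n_per_phase=200, strains=("s1",)):
    """Three well-separated concentration bands with planted correlations."""
    rows = []
    for strain in strains:
        for center, r, label in [(2.0, -0.8, "I"), (4.0, -0.65, "II"), (6.0, 0.0, "III")]:
            z = rng.normal(size=n_per_phase)
            eps = rng.normal(size=n_per_phase)
            log_conc = center + 0.25 * (r * z + np.sqrt(1 - r * r) * eps)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": [f"{label}{i}" for i in range(n_per_phase)],
                        "strain": strain,
                        "log_conc": log_conc,
                        "log_k": z,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestBuildPoints:
    def fits_frame(self, ids, strain, reliable=True):
        k = np.full(len(ids), np.log(2))
        return pd.DataFrame(
            {
                "transcript_id": ids,
                "strain": strain,
                "k": k,
                "t_half": 1.0,
                "reliable": reliable,
            }
        )

    def test_one_point_per_gene_and_strain(self):
        ids = [f"g{i}" for i in range(10)]
        fits = {s: self.fits_frame(ids, s) for s in ("a", "b", "c")}
        conc = pd.DataFrame(
            {"a": np.ones(10), "b": np.ones(10), "c": np.ones(10)}, index=ids
        )
        pts = build_points(fits, conc, set(ids))
        assert len(pts) == 30

    def test_unit_concentration_point_coordinates(self):
        fits = {"a": self.fits_frame(["g"], "a"), "b": self.fits_frame(["g"], "b")}
        conc = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["g"])
        pts = build_points(fits, conc, {"g"})
        assert pts["log_conc"].iloc[0] == pytest.approx(0.0)
        assert pts["log_k"].iloc[0] == pytest.approx(np.log10(np.log(2)))

    def test_unreliable_gene_rejected(self):
        fits = {"a": self.fits_frame(["g"], "a", reliable=False)}
        conc = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValidationError):
            build_points(fits, conc, {"g"})


class TestKmeans1D:
    def test_well_separated_triplets(self):
        vals = np.array([0.0, 0.1, 5.0, 5.1, 10.0, 10.1])
        labels, centers, _ = kmeans_1d(vals, seed=0)
        assert list(labels) == [0, 0, 1, 1, 2, 2]
        np.testing.assert_allclose(centers, [0.05, 5.05, 10.05])

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_1d(np.full(10, 3.0))

    def test_inertia_matches_contiguous_partition_oracle(self, rng):
        # optimal 1-D k-means clusters are contiguous in sorted order
        for trial in range(5):
            vals = np.sort(rng.normal(size=12))
            _, _, inertia = kmeans_1d(vals, seed=trial)
            best = np.inf
            for i, j in itertools.combinations(range(1, 12), 2):
                parts = [vals[:i], vals[i:j], vals[j:]]
                cost = sum(((p - p.mean()) ** 2).sum() for p in parts)
                best = min(best, cost)
            assert inertia == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_labels_ordered_by_center(self, rng):
        vals = rng.normal(size=40)
        labels, centers, _ = kmeans_1d(vals, seed=1)
        assert np.all(np.diff(centers) > 0)
        for lab in range(2):
            assert vals[labels == lab].mean() < vals[labels == lab + 1].mean()


class TestPearson:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, -2.0 * x + 1.0)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_zero_correlation_gives_p_one(self):
        # symmetric cross pattern: r is exactly 0, t = 0, p = 1
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_p_matches_exhaustive_permutation_oracle(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r_obs, p_t = pearson_with_p(x, y)
        perm_r = [
            abs(np.corrcoef(x, np.array(perm))[0, 1])
            for perm in itertools.permutations(y)
        ]
        p_perm = np.mean(np.array(perm_r) >= abs(r_obs) - 1e-12)
        assert p_t == pytest.approx(p_perm, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestPhaseCorrelations:
    def test_planted_three_phase_structure_recovered(self, rng):
        pts = make_points(rng, n_per_phase=1500)
        pts, centers = assign_phases(pts, seed=0)
        stats = phase_correlations(pts).query("strain == 'combined'").set_index("phase")
        assert stats.loc["I", "r"] == pytest.approx(-0.80, abs=0.05)
        assert stats.loc["II", "r"] == pytest.approx(-0.65, abs=0.05)
        assert stats.loc["III", "r"] == pytest.approx(0.0, abs=0.05)

    def test_point_order_irrelevant(self, rng):
        pts = make_points(rng, n_per_phase=100)
        pts, _ = assign_phases(pts, seed=0)
        shuffled = pts.sample(frac=1.0, random_state=3)
        a = phase_correlations(pts).set_index(["strain", "phase"])
        b = phase_correlations(shuffled).set_index(["strain", "phase"])
        pd.testing.assert_frame_equal(a, b.loc[a.index], rtol=1e-12)

    def test_phase_counts_conserved(self, rng):
        pts = make_points(rng, n_per_phase=80, strains=("s1", "s2"))
        pts, _ = assign_phases(pts, seed=0)
        stats = phase_correlations(pts)
        for s in ("s1", "s2"):
            n_total = stats.loc[stats["strain"] == s, "n"].sum()
            assert n_total == (pts["strain"] == s).sum()

    def test_small_phase_reports_nan_with_warning(self, rng):
        pts = pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c"],
                "strain": "s",
                "log_conc": [0.0, 0.1, 5.0],
                "log_k": [1.0, 2.0, 3.0],
                "phase": ["I", "I", "III"],
            }
        )
        with pytest.warns(UserWarning):
            stats = phase_correlations(pts)
        assert stats.set_index(["strain", "phase"]).loc[("s", "III"), "n"] == 1

    def test_sign_pattern_recovered_on_generator_cohorts(self):
        # the generator's three-regime model yields (neg, neg, ~0) reliably
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_transcripts=4000, seed=seed, unexpressed_fraction=0.0)
            tt = generate_truth(cfg).transcripts
            pts = pd.DataFrame(
                {
                    "transcript_id": tt["transcript_id"],
                    "strain": "control",
                    "log_conc": np.log10(tt["conc_control"]),
                    "log_k": np.log10(tt["k_control"]),
                }
            )
            pts, _ = assign_phases(pts, seed=0)
            r = phase_correlations(pts).query("strain == 'combined'").set_index("phase")["r"]
            if r["I"] < -0.5 and r["II"] < -0.3 and abs(r["III"]) < 0.1:
                hits += 1
        assert hits >= 19


class TestCrossMembership:
    def points_for(self, assign_a, assign_b):
        ids = [f"g{i}" for i in range(len(assign_a))]
        return pd.concat(
            [
                pd.DataFrame(
                    {"transcript_id": ids, "strain": "a", "log_conc": 0.0,
                     "log_k": 0.0, "phase": assign_a}
                ),
                pd.DataFrame(
                    {"transcript_id": ids, "strain": "b", "log_conc": 0.0,
                     "log_k": 0.0, "phase": assign_b}
                ),
            ]
        )

    def test_identical_assignments_diagonal(self):
        phases = ["I", "II", "III", "I"]
        table = cross_phase_membership(self.points_for(phases, phases), "a", "b")
        assert table.to_numpy().sum() == 4
        assert np.trace(table.to_numpy()) == 4

    def test_uniform_shift_single_cell(self):
        table = cross_phase_membership(
            self.points_for(["I"] * 5, ["III"] * 5), "a", "b"
        )
        assert table.loc["I", "III"] == 5
        assert table.to_numpy().sum() == 5

    def test_matches_bruteforce_tally(self, rng):
        phases = np.array(["I", "II", "III"])
        a = phases[rng.integers(0, 3, 50)]
        b = phases[rng.integers(0, 3, 50)]
        table = cross_phase_membership(self.points_for(list(a), list(b)), "a", "b")
        for i, pi in enumerate(phases):
            for j, pj in enumerate(phases):
                assert table.loc[pi, pj] == int(((a == pi) & (b == pj)).sum())

    def test_gene_set_mismatch_rejected(self):
        pts = self.points_for(["I", "II"], ["I", "II"])
        pts = pts[~((pts.strain == "b") & (pts.transcript_id == "g1"))]
        with pytest.raises(ValidationError):
            cross_phase_membership(pts, "a", "b")
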