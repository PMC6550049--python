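"""Landmark containers, CSV round-trips, trial averaging, subsets, bilateral matching."""
import numpy as np
import pytest

import edma
from edma import ValidationError

from conftest import make_two_groups


class TestValidation:
    def test_rejects_fewer_than_three_landmarks(self):
        with pytest.raises(ValidationError, match="at least 3"):
            edma.LandmarkConfiguration(
                "s", ("A", "B"), np.array([[0.0, 0, 0], [1.0, 0, 0]])
            )

    def test_rejects_non_finite_coordinate(self):
        with pytest.raises(ValidationError, match="non-finite.*B"):
            edma.LandmarkConfiguration(
                "s", ("A", "B", "C"),
                np.array([[0.0, 0, 0], [np.nan, 0, 0], [0, 1.0, 0]]),
            )

    def test_rejects_coincident_landmarks(self):
        with pytest.raises(ValidationError, match="coincident"):
            edma.LandmarkConfiguration(
                "s", ("A", "B", "C"),
                np.array([[0.0, 0, 0], [0.0, 0, 0], [0, 1.0, 0]]),
            )

    def test_dataset_requires_consistent_landmark_sets(self, triangle_config):
        other = edma.LandmarkConfiguration(
            "s2", ("A", "B", "D"),
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]),
        )
        with pytest.raises(ValidationError, match="landmark set differs"):
            edma.LandmarkDataset(
                [triangle_config, other], {"tri": "g", "s2": "g"}
            )

    def test_dataset_requires_group_labels(self, triangle_config):
        with pytest.raises(ValidationError, match="no group label"):
            edma.LandmarkDataset([triangle_config], {})


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["long", "wide"])
    def test_write_read_lossless(self, tmp_path, dialect):
        a, _, _ = make_two_groups(n=4)
        path = tmp_path / f"ds_{dialect}.csv"
        edma.write_landmark_table(a, path, dialect)
        back = edma.read_landmark_table(path, dialect)
        assert back.specimen_ids == a.specimen_ids
        assert back.landmark_labels == a.landmark_labels
        assert back.group_labels == a.group_labels
        np.testing.assert_allclose(
            back.coords_array(), a.coords_array(), rtol=0, atol=1e-12
        )

    def test_long_wide_long_preserves_coordinates(self, tmp_path, small_dataset):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        edma.write_landmark_table(small_dataset, p1, "long")
        wide = edma.read_landmark_table(p1, "long")
        edma.write_landmark_table(wide, p2, "wide")
        back = edma.read_landmark_table(p2, "wide")
        np.testing.assert_array_equal(
            back.coords_array(), small_dataset.coords_array()
        )

    def test_missing_landmark_names_specimen_and_landmark(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "specimen,group,landmark,x,y,z\n"
            "S1,wt,cdl,0,0,0\nS1,wt,gon,3,0,0\nS1,wt,inf,0,4,0\n"
            "S2,wt,gon,3,0,1\nS2,wt,inf,0,4,1\n"
        )
        with pytest.raises(ValidationError, match="S2.*cdl"):
            edma.read_landmark_table(path)

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "specimen,group,landmark,x,y,z\n"
            "S1,wt,a,0,0,0\nS1,wt,b,3,zero,0\nS1,wt,c,0,4,0\n"
        )
        with pytest.raises(ValidationError, match="non-numeric.*S1.*b"):
            edma.read_landmark_table(path)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(ValidationError, match="no such file"):
            edma.read_landmark_table(tmp_path / "nope.csv")

    def test_write_requires_dataset(self, tmp_path):
        with pytest.raises(ValidationError):
            edma.write_landmark_table(None, tmp_path / "x.csv")


class TestTrialAveraging:
    def test_identical_trials_unflagged(self, small_dataset):
        avg, qc = edma.average_digitization_trials(small_dataset, small_dataset)
        np.testing.assert_array_equal(
            avg.coords_array(), small_dataset.coords_array()
        )
        assert qc.flagged == []
        assert qc.max_displacement == 0.0

    def test_average_is_midpoint_and_threshold_is_exclusive(self, triangle_config):
        shifted = edma.LandmarkConfiguration(
            "tri", triangle_config.landmark_labels,
            triangle_config.coordinates + np.array([[0.02, 0, 0], [0, 0, 0], [0, 0, 0]]),
        )
        a = edma.LandmarkDataset([triangle_config], {"tri": "g"})
        b = edma.LandmarkDataset([shifted], {"tri": "g"})
        avg, qc = edma.average_digitization_trials(a, b)
        np.testing.assert_allclose(
            avg.configurations[0].coordinates[0], [0.01, 0.0, 0.0]
        )
        assert qc.flagged == []  # 0.02 mm <= 0.05 mm
        assert qc.max_displacement == pytest.approx(0.02)

    def test_displacement_above_max_error_is_flagged(self, triangle_config):
        shifted = edma.LandmarkConfiguration(
            "tri", triangle_config.landmark_labels,
            triangle_config.coordinates + np.array([[0, 0, 0], [0.06, 0, 0], [0, 0, 0]]),
        )
        a = edma.LandmarkDataset([triangle_config], {"tri": "g"})
        b = edma.LandmarkDataset([shifted], {"tri": "g"})
        _, qc = edma.average_digitization_trials(a, b)
        assert qc.flagged == [("tri", "B")]

    def test_symmetric_in_trials(self):
        a, b, _ = make_two_groups(n=3, sigma=0.02)
        b = edma.LandmarkDataset(
            [edma.LandmarkConfiguration(c.specimen_id, c.landmark_labels,
                                        c.coordinates + 0.01)
             for c in a.configurations],
            dict(a.group_labels),
        )
        avg1, qc1 = edma.average_digitization_trials(a, b)
        avg2, qc2 = edma.average_digitization_trials(b, a)
        np.testing.assert_array_equal(avg1.coords_array(), avg2.coords_array())
        assert qc1.flagged == qc2.flagged

    def test_mismatched_specimens_error(self, small_dataset):
        sub = small_dataset.with_specimens(small_dataset.configurations[:1])
        with pytest.raises(ValidationError, match="different specimen ids"):
            edma.average_digitization_trials(small_dataset, sub)


class TestSubsets:
    def test_subset_selects_matching_form_matrix_entries(self):
        a, _, _ = make_two_groups(n=2)
        labels = a.landmark_labels[2:8]
        sub = edma.extract_subset(a, edma.SubsetDefinition("region", labels))
        assert sub.landmark_labels == labels
        full_fm = edma.compute_form_matrix(a.configurations[0])
        sub_fm = edma.compute_form_matrix(sub.configurations[0])
        lookup = dict(zip(full_fm.pair_index, full_fm.distances))
        for pair, d in zip(sub_fm.pair_index, sub_fm.distances):
            assert d == lookup[pair]

    def test_sixteen_landmark_subset_has_120_distances(self):
        a, _, _ = make_two_groups(n=2)
        fm = edma.compute_form_matrix(a.configurations[0])
        assert len(fm.distances) == 16 * 15 // 2 == 120

    def test_unknown_label_errors(self, small_dataset):
        with pytest.raises(ValidationError, match="'D'"):
            edma.extract_subset(
                small_dataset, edma.SubsetDefinition("bad", ("A", "B", "D"))
            )

    def test_subset_needs_three_labels(self):
        with pytest.raises(ValidationError, match="at least 3"):
            edma.SubsetDefinition("tiny", ("A", "B"))


class TestBilateral:
    @staticmethod
    def _mirror_dataset(n=5, seed=4):
        """Left landmarks + their exact mirror images across x=0."""
        rng = np.random.default_rng(seed)
        left = rng.uniform(1.0, 5.0, size=(6, 3))
        right = left * np.array([-1.0, 1.0, 1.0])
        labels = tuple(f"L{i}" for i in range(6)) + tuple(f"R{i}" for i in range(6))
        configs = []
        for s in range(n):
            jitter = rng.normal(0, 0.01, size=(6, 3))
            coords = np.vstack([left + jitter, (left + jitter) * [-1, 1, 1]])
            configs.append(edma.LandmarkConfiguration(f"s{s}", labels, coords))
        ds = edma.LandmarkDataset(configs, {f"s{s}": "wt" for s in range(n)})
        pairing = [(f"L{i}", f"R{i}") for i in range(6)]
        return ds, pairing

    def test_mirror_symmetric_sides_have_identical_form_matrices(self):
        ds, pairing = self._mirror_dataset()
        left, right = edma.match_bilateral(ds, pairing)
        assert left.landmark_labels == right.landmark_labels
        for cl, cr in zip(left.configurations, right.configurations):
            dl = edma.compute_form_matrix(cl).distances
            dr = edma.compute_form_matrix(cr).distances
            np.testing.assert_allclose(dl, dr, rtol=0, atol=1e-10)

    def test_scaled_right_side_gives_uniform_fdm(self):
        ds, pairing = self._mirror_dataset()
        scaled_configs = []
        for c in ds.configurations:
            coords = c.coordinates.copy()
            coords[6:] = coords[6:] * 1.1  # uniform scaling about the origin
            scaled_configs.append(
                edma.LandmarkConfiguration(c.specimen_id, c.landmark_labels, coords)
            )
        scaled = edma.LandmarkDataset(scaled_configs, dict(ds.group_labels))
        left, right = edma.match_bilateral(scaled, pairing)
        fdm = edma.compute_fdm(
            edma.estimate_mean_form(right), edma.estimate_mean_form(left)
        )
        np.testing.assert_allclose(fdm.ratios, 1.1, rtol=2e-3)

    def test_incomplete_pairing_label_errors(self):
        ds, pairing = self._mirror_dataset()
        pairing[0] = ("L_missing", "R0")
        with pytest.raises(ValidationError, match="L_missing"):
            edma.match_bilateral(ds, pairing)

    def test_duplicate_pairing_errors(self):
        ds, pairing = self._mirror_dataset()
        pairing[1] = (pairing[0][0], "R1")
        with pytest.raises(ValidationError, match="duplicate"):
            edma.match_bilateral(ds, pairing)
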