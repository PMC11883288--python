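import numpy as np
import pytest

from tissuetracks import (TriangleField, ValidationError,
                          assemble_reconstruction, collect_track_series,
                          fit_track_spline, reconstruct)
from tissuetracks.interpolation import SplineModel, TrackSeries

from conftest import identity_movie


def _field(hour, values):
    return TriangleField(hour=hour, values=np.asarray(values, float),
                         provenance=f"img{hour}")


class TestCollectTrackSeries:
    def test_samples_are_field_values_at_track_triangles(self):
        movie = identity_movie(T=8)
        from tissuetracks import build_lineage_graph, extract_tracks
        tracks = extract_tracks(build_lineage_graph(movie))
        fields = [_field(h, [v, v]) for h, v in [(0, 0.1), (2, 0.2), (5, 0.3), (7, 0.4)]]
        series = collect_track_series(tracks, fields)
        for s in series:
            assert [(h, v) for h, v, _ in s.samples] == [
                (0, 0.1), (2, 0.2), (5, 0.3), (7, 0.4)]

    def test_same_hour_images_averaged(self):
        movie = identity_movie(T=8)
        from tissuetracks import build_lineage_graph, extract_tracks
        tracks = extract_tracks(build_lineage_graph(movie))
        fields = [_field(h, [0.5, 0.5]) for h in (0, 2, 7)]
        two_a = TriangleField(hour=5, values=np.array([0.2, 0.2]), provenance="a")
        two_b = TriangleField(hour=5, values=np.array([0.4, 0.4]), provenance="b")
        series = collect_track_series(tracks, fields + [two_a, two_b])
        assert series[0].hour_means[5] == pytest.approx(0.3)

    def test_too_few_hours_rejected(self):
        movie = identity_movie(T=8)
        from tissuetracks import build_lineage_graph, extract_tracks
        tracks = extract_tracks(build_lineage_graph(movie))
        fields = [_field(h, [0.5, 0.5]) for h in (0, 3, 7)]
        with pytest.raises(ValidationError, match="4 unique time points"):
            collect_track_series(tracks, fields)

    def test_means_match_brute_force(self, complex_dataset):
        ds = complex_dataset
        series = collect_track_series(ds.tracks, ds.fields)
        rng = np.random.default_rng(0)
        by_hour = {f.hour: f for f in ds.fields}
        for tid in rng.choice(len(series), size=10, replace=False):
            tr = ds.tracks.tracks[tid]
            for h, mean in series[tid].hour_means.items():
                assert mean == pytest.approx(float(by_hour[h].values[tr.refs[h]]))


class TestFitTrackSpline:
    def test_constant_reproduced(self):
        s = fit_track_spline(TrackSeries(track_id=0, samples=[
            (h, 0.6, "i") for h in (0, 3, 6, 9)]))
        q = np.linspace(0, 9, 200)
        np.testing.assert_allclose(s(q), 0.6, atol=1e-12)

    def test_linear_reproduced(self):
        hours = [0, 2, 5, 7, 11]
        samples = [(h, 0.05 + 0.07 * h, "i") for h in hours]
        s = fit_track_spline(TrackSeries(track_id=0, samples=samples))
        q = np.linspace(0, 11, 100)
        np.testing.assert_allclose(s(q), 0.05 + 0.07 * q, atol=1e-6)

    def test_c1_continuity_at_interior_knots(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            hours = np.sort(rng.choice(np.arange(12), size=n, replace=False))
            samples = [(int(h), float(v), "i")
                       for h, v in zip(hours, rng.uniform(0.05, 0.95, n))]
            s = fit_track_spline(TrackSeries(track_id=0, samples=samples))
            eps = 1e-4
            for knot in hours[1:-1]:
                fwd = (s(knot + eps) - s(knot)) / eps
                bwd = (s(knot) - s(knot - eps)) / eps
                assert abs(fwd - bwd) <= 1e-3

    def test_endpoints_interpolated_and_clamped_outside(self):
        samples = [(0, 0.2, "i"), (3, 0.8, "i"), (6, 0.4, "i"), (9, 0.7, "i")]
        s = fit_track_spline(TrackSeries(track_id=0, samples=samples))
        assert s(0.0) == pytest.approx(0.2, abs=1e-12)
        assert s(9.0) == pytest.approx(0.7, abs=1e-12)
        assert s(-4.0) == pytest.approx(0.2, abs=1e-12)
        assert s(25.0) == pytest.approx(0.7, abs=1e-12)

    def test_outputs_clamped_to_unit_interval(self):
        # interpolating overshoot would leave [0, 1]; the evaluator must not
        samples = [(0, 0.0, "i"), (1, 0.0, "i"), (2, 1.0, "i"), (3, 1.0, "i"),
                   (4, 0.0, "i"), (5, 0.0, "i")]
        s = fit_track_spline(TrackSeries(track_id=0, samples=samples))
        q = np.linspace(0, 5, 500)
        vals = s(q)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_too_few_hours_rejected(self):
        with pytest.raises(ValidationError, match="4 unique"):
            fit_track_spline(TrackSeries(track_id=0, samples=[
                (0, 0.1, "i"), (1, 0.2, "i"), (2, 0.3, "i")]))


class TestAssemble:
    def test_shared_triangles_averaged(self):
        from tissuetracks import TrackSet
        from tissuetracks.tracking import (ORIGIN_FILL, ORIGIN_FINAL_BACKWARD,
                                           TissueTrack)
        movie = identity_movie(T=6)
        tracks = TrackSet(n_hours=6)
        # triangle 0 is shared by two tracks with different splines; triangle 1
        # belongs to exactly one track
        tracks.add(TissueTrack(refs=np.zeros(6, dtype=np.int64),
                               origin=ORIGIN_FINAL_BACKWARD))
        tracks.add(TissueTrack(refs=np.ones(6, dtype=np.int64),
                               origin=ORIGIN_FINAL_BACKWARD))
        tracks.add(TissueTrack(refs=np.zeros(6, dtype=np.int64), origin=ORIGIN_FILL))
        splines = {
            0: SplineModel(hours=np.arange(6.0), means=np.full(6, 0.2)),
            1: SplineModel(hours=np.arange(6.0), means=np.full(6, 0.9)),
            2: SplineModel(hours=np.arange(6.0), means=np.full(6, 0.6)),
        }
        rec = assemble_reconstruction(tracks, splines, movie)
        assert rec.fields[2].values[0] == pytest.approx(0.4)   # (0.2 + 0.6) / 2
        assert rec.fields[2].values[1] == pytest.approx(0.9)   # single track

    def test_missing_spline_rejected(self):
        movie = identity_movie(T=6)
        from tissuetracks import build_lineage_graph, extract_tracks
        tracks = extract_tracks(build_lineage_graph(movie))
        with pytest.raises(ValidationError, match="track 1"):
            assemble_reconstruction(
                tracks, {0: SplineModel(hours=np.arange(6.0), means=np.full(6, 0.5))},
                movie)

    def test_batch_reconstruct_matches_per_track_assembly(self, simple_dataset):
        ds = simple_dataset
        rec_batch = reconstruct(ds.movie, ds.tracks, ds.fields)
        series = collect_track_series(ds.tracks, ds.fields)
        splines = {s.track_id: fit_track_spline(s) for s in series}
        rec_sep = assemble_reconstruction(ds.tracks, splines, ds.movie)
        for fa, fb in zip(rec_batch.fields, rec_sep.fields):
            np.testing.assert_allclose(fa.values, fb.values, atol=1e-10)

    @pytest.mark.parametrize("dataset", ["simple_dataset", "complex_dataset"])
    def test_noiseless_reconstruction_tracks_ground_truth(self, dataset, request):
        ds = request.getfixturevalue(dataset)
        rec = reconstruct(ds.movie, ds.tracks, ds.fields)
        for h, truth in enumerate(ds.truth):
            err = np.abs(rec.fields[h].values - truth.values)
            assert err.mean() <= 0.05

    def test_all_outputs_in_unit_interval(self, complex_dataset):
        rec = reconstruct(complex_dataset.movie, complex_dataset.tracks,
                          complex_dataset.fields)
        for f in rec.fields:
            assert f.values.min() >= 0.0 and f.values.max() <= 1.0
            assert len(f.values) == complex_dataset.movie.hourly_meshes[f.hour].n_triangles

    def test_reconstruction_save_load_roundtrip(self, simple_dataset, tmp_path):
        from tissuetracks import Reconstruction
        rec = reconstruct(simple_dataset.movie, simple_dataset.tracks,
                          simple_dataset.fields)
        rec.save(str(tmp_path / "rec"))
        loaded = Reconstruction.load(str(tmp_path / "rec"))
        for fa, fb in zip(rec.fields, loaded.fields):
            np.testing.assert_array_equal(fa.values, fb.values)
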