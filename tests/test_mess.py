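import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snakevuln import oracle
from snakevuln.grid import GridSpec
from snakevuln.mess import (
    CovariateStack,
    InsufficientTrainingError,
    MESS_NEGATIVE,
    MESS_POSITIVE,
    NODATA_LABEL,
    TrainingSample,
    classify_records,
    extract_training,
    mess_surface,
    similarity_one,
    similarity_vector,
)
from snakevuln.registry import OccurrenceRecord
from shapely.geometry import box

TRAIN = [1.0, 2.0, 3.0, 4.0, 5.0]


class TestSimilarityScalar:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (3.0, 80.0),   # 2 of 5 strictly below -> f=40 -> 2f
            (1.0, 0.0),    # at the minimum, f=0 branch
            (0.0, -25.0),  # below: 100*(0-1)/(5-1)
            (6.0, -25.0),  # above: 100*(5-6)/(5-1)
            (5.0, 40.0),   # 4 of 5 below -> f=80 -> 2*(100-80)
            (2.5, 80.0),   # 2 of 5 below -> f=40 -> 2f
        ],
    )
    def test_piecewise_branches(self, value, expected):
        assert similarity_one(value, TRAIN) == pytest.approx(expected)

    def test_degenerate_training(self):
        assert similarity_one(2.0, [2.0, 2.0]) == 100.0
        assert similarity_one(2.1, [2.0, 2.0]) == -100.0

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            similarity_one(1.0, [])

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=20),
        st.floats(-200, 200, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_sign_law(self, training, value):
        """Score is negative exactly when the value leaves the envelope."""
        score = similarity_one(value, training)
        lo, hi = min(training), max(training)
        if lo == hi:
            assert (score < 0) == (value != lo)
        else:
            assert (score < 0) == (value < lo or value > hi)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        training = rng.normal(size=11)
        values = rng.normal(scale=2.0, size=500)
        vec = similarity_vector(values, training)
        ref = np.array([oracle.mess_score(float(v), list(training)) for v in values])
        np.testing.assert_allclose(vec, ref, atol=1e-10)


def _stack(seed=0, n=20, n_bands=8):
    grid = GridSpec(0.0, float(n) * 0.5, 0.5, n, n)
    rng = np.random.default_rng(seed)
    bands = {f"b{k}": rng.normal(size=grid.shape) for k in range(n_bands)}
    return CovariateStack(grid, bands)


class TestSurface:
    def test_minimum_aggregation_and_argmin_equality(self):
        stack = _stack()
        training = TrainingSample({k: np.sort(v.ravel()[:10]) for k, v in stack.bands.items()})
        surf = mess_surface(training, stack)
        per_band = np.stack(
            [
                similarity_vector(stack.bands[k].ravel(), training.values[k]).reshape(stack.grid.shape)
                for k in stack.band_names
            ]
        )
        assert np.all(surf.similarity <= per_band.min(axis=0) + 1e-12)
        np.testing.assert_allclose(surf.similarity, per_band.min(axis=0), atol=1e-12)

    def test_all_within_envelope_is_interpolation_everywhere(self):
        stack = _stack(seed=1)
        # train on the extremes of every band: everything interpolates
        training = TrainingSample(
            {k: np.array([v.min(), v.max()]) for k, v in stack.bands.items()}
        )
        surf = mess_surface(training, stack)
        assert np.all(surf.similarity >= 0)
        assert surf.interpolation_mask.all()

    def test_pushed_band_region_goes_negative(self):
        stack = _stack(seed=2, n_bands=3)
        training = TrainingSample(
            {k: np.array([v.min(), v.max()]) for k, v in stack.bands.items()}
        )
        stack.bands["b0"][5:9, 5:9] = stack.bands["b0"].max() + 10.0  # outside envelope
        surf = mess_surface(training, stack)
        region = np.zeros(stack.grid.shape, dtype=bool)
        region[5:9, 5:9] = True
        assert np.all(surf.similarity[region] < 0)
        assert np.all(surf.similarity[~region] >= 0)

    def test_nodata_propagates(self):
        stack = _stack(seed=3, n_bands=2)
        stack.bands["b0"][0, :] = np.nan
        training = TrainingSample(
            {k: np.array([np.nanmin(v), np.nanmax(v)]) for k, v in stack.bands.items()}
        )
        surf = mess_surface(training, stack)
        assert np.all(np.isnan(surf.similarity[0, :]))
        assert not surf.interpolation_mask[0, :].any()

    def test_training_monotonicity_grows_interpolation_region(self):
        """Adding a training record never shrinks the interpolation region."""
        stack = _stack(seed=4, n_bands=4)
        rng = np.random.default_rng(4)
        base = {k: v.ravel()[rng.choice(v.size, 5, replace=False)] for k, v in stack.bands.items()}
        bigger = {k: np.append(base[k], v.ravel()[7]) for k, v in stack.bands.items()}
        m_small = mess_surface(TrainingSample(base), stack).interpolation_mask
        m_big = mess_surface(TrainingSample(bigger), stack).interpolation_mask
        assert np.all(m_big | ~m_small)  # m_small implies m_big


def _ray_cast(poly_coords, x, y):
    """Even-odd ray-casting point-in-polygon oracle (boundary-agnostic)."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x < xin:
                inside = not inside
    return inside


class TestTrainingExtraction:
    def test_partition_counts(self):
        stack = _stack(seed=5, n_bands=2)
        eor = box(1.0, 1.0, 4.0, 4.0)
        records = [
            OccurrenceRecord("s", 2000, 1.25, 1.25),
            OccurrenceRecord("s", 2001, 3.75, 3.75),
            OccurrenceRecord("s", 2002, 2.25, 2.25),
            OccurrenceRecord("s", 2003, 8.25, 8.25),
            OccurrenceRecord("s", 2004, 9.25, 0.25),
        ]
        sample = extract_training(records, eor, stack)
        assert sample.n == 3

    def test_boundary_record_counts_as_inside(self):
        stack = _stack(seed=6, n_bands=2)
        eor = box(1.0, 1.0, 4.0, 4.0)
        records = [
            OccurrenceRecord("s", 2000, 1.0, 2.0),  # exactly on the boundary
            OccurrenceRecord("s", 2001, 2.25, 2.25),
        ]
        assert extract_training(records, eor, stack).n == 2

    def test_partition_matches_ray_cast_oracle(self):
        stack = _stack(seed=7, n_bands=2)
        coords = [(1.1, 1.1), (7.3, 2.0), (6.1, 6.7), (2.2, 7.9)]
        from shapely.geometry import Polygon

        eor = Polygon(coords)
        rng = np.random.default_rng(7)
        records = [
            OccurrenceRecord("s", 2000 + i, float(rng.uniform(0.2, 9.3)), float(rng.uniform(0.2, 9.3)))
            for i in range(40)
        ]
        n_inside_oracle = sum(1 for r in records if _ray_cast(coords, r.lon, r.lat))
        assert extract_training(records, eor, stack).n == n_inside_oracle

    def test_too_few_records_refused(self):
        stack = _stack(seed=8, n_bands=2)
        with pytest.raises(InsufficientTrainingError):
            extract_training([OccurrenceRecord("s", 2000, 2.0, 2.0)], box(1, 1, 4, 4), stack)


class TestClassifyRecords:
    def test_planted_labels(self):
        grid = GridSpec(0.0, 4.0, 1.0, 4, 4)
        sim = np.array(
            [
                [12.5, -3.0, 0.0, 5.0],
                [1.0, 1.0, -1.0, np.nan],
                [0.0, 0.0, 0.0, 0.0],
                [-9.0, -9.0, 50.0, 50.0],
            ]
        )
        from snakevuln.mess import MessSurface

        surf = MessSurface(grid, sim, threshold=0.0)
        records = [
            OccurrenceRecord("s", None, 3.5, 0.5),   # cell (0,0): 12.5
            OccurrenceRecord("s", None, 3.5, 1.5),   # cell (0,1): -3
            OccurrenceRecord("s", None, 3.5, 2.5),   # cell (0,2): 0 -> positive
            OccurrenceRecord("s", None, 2.5, 3.5),   # cell (1,3): nodata
        ]
        assert classify_records(records, surf) == [
            MESS_POSITIVE, MESS_NEGATIVE, MESS_POSITIVE, NODATA_LABEL,
        ]
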