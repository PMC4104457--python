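import math

import numpy as np
import pytest

from vfinger import NoPathError, Volume
from vfinger.geodesic import (GeodesicParams, edge_weight, fast_march, g_intensity,
                              geodesic_costs)
from vfinger.volume import IntensityRange

from oracle import explicit_graph_cost

R255 = IntensityRange(0, 255)


def test_g_intensity_closed_forms():
    p = GeodesicParams()
    assert g_intensity(255, R255, p) == pytest.approx(1.0)
    assert g_intensity(0, R255, p) == pytest.approx(math.exp(10), rel=1e-12)
    mid = g_intensity(127.5, R255, p)
    assert mid == pytest.approx(math.exp(2.5), rel=1e-12)  # 12.18249...
    # decreasing in intensity
    vals = g_intensity(np.linspace(0, 255, 50), R255, p)
    assert np.all(np.diff(vals) < 0)


def test_g_intensity_flat_image_degrades_to_euclidean():
    p = GeodesicParams()
    assert g_intensity(7, IntensityRange(7, 7), p) == pytest.approx(1.0)


def test_edge_weight_examples():
    p = GeodesicParams()
    bright = Volume(np.full((3, 3, 3), 200, dtype=np.uint8))
    assert edge_weight((0, 0, 0), (1, 0, 0), bright, p) == pytest.approx(1.0)
    assert edge_weight((0, 0, 0), (1, 1, 0), bright, p) == pytest.approx(math.sqrt(2))
    data = np.full((3, 3, 3), 200, dtype=np.uint8)
    data[0, 0, 0] = data[1, 0, 0] = 0
    dark = Volume(data)
    assert edge_weight((0, 0, 0), (1, 0, 0), dark, p) == pytest.approx(math.exp(10))
    with pytest.raises(ValueError):
        edge_weight((0, 0, 0), (2, 0, 0), bright, p)
    with pytest.raises(ValueError):
        edge_weight((0, 0, 0), (1, 1, 1), bright, GeodesicParams(connectivity=18))


def test_fast_march_trivial_cases():
    vol = Volume(np.full((1, 1, 5), 200, dtype=np.uint8))
    p = fast_march([(0, 0, 2)], [(0, 0, 2)], vol)
    assert p.voxels == [(0, 0, 2)] and p.cost == 0.0
    p = fast_march([(0, 0, 0)], [(0, 0, 4)], vol)
    assert p.cost == pytest.approx(4.0)
    assert p.voxels == [(0, 0, z) for z in range(5)]


def test_fast_march_path_cost_consistency(rng):
    vol = Volume(rng.integers(0, 256, (8, 8, 8)).astype(np.uint8))
    params = GeodesicParams()
    path = fast_march([(0, 0, 0)], [(7, 7, 7)], vol, params)
    total = sum(
        edge_weight(u, v, vol, params) for u, v in zip(path.voxels, path.voxels[1:])
    )
    assert path.cost == pytest.approx(total, abs=1e-6)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_fast_march_matches_explicit_graph_oracle(rng, connectivity):
    params = GeodesicParams(connectivity=connectivity)
    for _ in range(25):
        dims = tuple(rng.integers(3, 11, 3))
        vol = Volume(rng.integers(0, 256, dims).astype(np.uint8))
        src = tuple(rng.integers(0, dims))
        dst = tuple(rng.integers(0, dims))
        got = fast_march([src], [dst], vol, params).cost
        want = explicit_graph_cost(vol, [src], [dst], params)
        assert got == pytest.approx(want, abs=1e-6)


def test_cost_symmetry(rng):
    params = GeodesicParams()
    for _ in range(10):
        vol = Volume(rng.integers(0, 256, (7, 7, 7)).astype(np.uint8))
        a = tuple(rng.integers(0, 7, 3))
        b = tuple(rng.integers(0, 7, 3))
        ab = fast_march([a], [b], vol, params).cost
        ba = fast_march([b], [a], vol, params).cost
        assert ab == pytest.approx(ba, abs=1e-9)


def test_lambda_monotonicity(rng):
    vol = Volume(rng.integers(0, 200, (6, 6, 6)).astype(np.uint8))
    a, b = (0, 0, 0), (5, 5, 5)
    costs = [fast_march([a], [b], vol, GeodesicParams(lambda_i=lam)).cost
             for lam in (0.0, 5.0, 10.0, 20.0)]
    assert all(c1 <= c2 + 1e-9 for c1, c2 in zip(costs, costs[1:]))


def test_triangle_inequality(rng):
    params = GeodesicParams()
    vol = Volume(rng.integers(0, 256, (7, 7, 7)).astype(np.uint8))
    for _ in range(10):
        a, b, c = (tuple(rng.integers(0, 7, 3)) for _ in range(3))
        ac = fast_march([a], [c], vol, params).cost
        ab = fast_march([a], [b], vol, params).cost
        bc = fast_march([b], [c], vol, params).cost
        assert ac <= ab + bc + 1e-9


def test_region_confinement_and_no_path():
    vol = Volume(np.full((5, 5, 5), 200, dtype=np.uint8))
    mask = np.zeros((5, 5, 5), bool)
    mask[0, 0, :] = True
    path = fast_march([(0, 0, 0)], [(0, 0, 4)], vol, region=mask)
    assert all(v[0] == 0 and v[1] == 0 for v in path.voxels)
    mask2 = mask.copy()
    mask2[0, 0, 2] = False  # cut the corridor
    with pytest.raises(NoPathError):
        fast_march([(0, 0, 0)], [(0, 0, 4)], vol, region=mask2)


def test_geodesic_costs_reports_every_sink(rng):
    vol = Volume(rng.integers(0, 256, (6, 6, 6)).astype(np.uint8))
    params = GeodesicParams()
    sinks = [(5, 5, 5), (0, 5, 0), (3, 3, 3)]
    costs = geodesic_costs([(0, 0, 0)], sinks, vol, params)
    for c, t in zip(costs, sinks):
        assert c == pytest.approx(fast_march([(0, 0, 0)], [t], vol, params).cost,
                                  abs=1e-9)


def test_params_validation():
    with pytest.raises(ValueError):
        GeodesicParams(lambda_i=-1)
    with pytest.raises(ValueError):
        GeodesicParams(connectivity=7)
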