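"""Explicit-graph shortest-path reference for checking the fast-march engine.

Materializes the voxel graph (which the engine deliberately avoids) and runs
scipy's compiled Dijkstra on it; completely independent of the search code
under test.
"""

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from vfinger.geodesic import g_intensity, neighbor_offsets
from vfinger.volume import IntensityRange


def explicit_graph_cost(vol, sources, sinks, params, region_mask=None):
    """Minimum cost from any source to any sink on the explicit voxel graph."""
    img = vol.reduced().astype(float)
    r = IntensityRange(float(img.min()), float(img.max()))
    g = g_intensity(img, r, params)
    dims = img.shape
    offs, steps = neighbor_offsets(params.connectivity)
    idx = np.arange(np.prod(dims)).reshape(dims)
    allowed = np.ones(dims, bool) if region_mask is None else region_mask
    rows, cols, vals = [], [], []
    for o, st in zip(offs, steps):
        sl_u = tuple(slice(max(0, -o[a]), dims[a] - max(0, o[a])) for a in range(3))
        sl_v = tuple(slice(max(0, o[a]), dims[a] + min(0, o[a])) for a in range(3))
        ok = allowed[sl_u].ravel() & allowed[sl_v].ravel()
        rows.append(idx[sl_u].ravel()[ok])
        cols.append(idx[sl_v].ravel()[ok])
        vals.append((st * 0.5 * (g[sl_u].ravel() + g[sl_v].ravel()))[ok])
    G = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(idx.size, idx.size),
    ).tocsr()
    src_idx = [idx[tuple(s)] for s in np.atleast_2d(sources)]
    d = _dijkstra(G, indices=src_idx, min_only=True)
    return min(d[idx[tuple(t)]] for t in np.atleast_2d(sinks))
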