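import math

import numpy as np
import pytest

import treetiles as tt


@pytest.fixture
def fixture_tree():
    return tt.fixture_tree()


@pytest.fixture
def small_tree():
    return tt.parse_newick("((A,B),C);")


@pytest.fixture
def prepared_fixture():
    """Fixture tree after the full preparation pipeline."""
    tree = tt.fixture_tree()
    tree = tt.filter_banned(tree)
    tree = tt.prune_below_species(tree)
    return tt.autoname_nodes(tree)


@pytest.fixture
def fixture_layout(prepared_fixture):
    return tt.layout_tree(prepared_fixture, tt.LayoutConfig(seed=7))


# ---- independent geometric predicates (oracles, not implementation) ----

def in_half_disc(p, center, radius, heading_deg, span=180.0, eps=1e-9):
    """Is p inside the half-disc (or full disc when span >= 360)?"""
    dx, dy = p[0] - center[0], p[1] - center[1]
    if math.hypot(dx, dy) > radius + eps:
        return False
    if span >= 360.0:
        return True
    h = math.radians(heading_deg)
    return dx * math.cos(h) + dy * math.sin(h) >= -eps


def sample_half_disc(rng, center, radius, heading_deg, span=180.0, n=200):
    """Uniform points in a half-disc (or full disc), y-up convention."""
    u = rng.random(n)
    r = radius * np.sqrt(rng.random(n))
    if span >= 360.0:
        theta = 2.0 * math.pi * u
    else:
        theta = math.radians(heading_deg) + math.pi * (u - 0.5)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def segments_cross(segs):
    """Count proper or improper crossings among segments, ignoring pairs
    that share an endpoint. segs: (n, 4) array [x1,y1,x2,y2]. O(n^2)."""
    s = np.asarray(segs, dtype=float)
    n = len(s)
    if n < 2:
        return 0
    p = s[:, :2]
    q = s[:, 2:]
    d = q - p
    crossings = 0
    for i in range(n - 1):
        pi, di = p[i], d[i]
        pj, dj = p[i + 1:], d[i + 1:]
        qi = q[i]
        qj = q[i + 1:]
        denom = di[0] * dj[:, 1] - di[1] * dj[:, 0]
        rel = pj - pi
        t_num = rel[:, 0] * dj[:, 1] - rel[:, 1] * dj[:, 0]
        u_num = rel[:, 0] * di[1] - rel[:, 1] * di[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t_num / denom
            u = u_num / denom
        eps = 1e-12
        proper = (np.abs(denom) > eps) & (t > eps) & (t < 1 - eps) & \
                 (u > eps) & (u < 1 - eps)
        # exclude shared endpoints (touching at a node is legal)
        shares = (np.all(np.isclose(pj, pi), axis=1) |
                  np.all(np.isclose(pj, qi), axis=1) |
                  np.all(np.isclose(qj, pi), axis=1) |
                  np.all(np.isclose(qj, qi), axis=1))
        crossings += int(np.sum(proper & ~shares))
    return crossings
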