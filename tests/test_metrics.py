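"""Per-class landscape metrics: scalar formulas against hand values, patch
labeling against a flood-fill oracle, and the chain's invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landrisk import (
    LandUseRaster,
    MetricWeights,
    build_grid,
    class_metrics,
    disturbance,
    dominance,
    fragility,
    fragmentation,
    label_patches,
    loss_index,
    separation,
)


# -- independent oracle ------------------------------------------------------

def flood_fill_patches(codes, nodata, connectivity):
    """Brute-force connected components by explicit stack-based flood fill."""
    nr, nc = codes.shape
    seen = np.zeros_like(codes, dtype=bool)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    patches = []
    for r0 in range(nr):
        for c0 in range(nc):
            if seen[r0, c0] or codes[r0, c0] == nodata:
                continue
            code = codes[r0, c0]
            stack, members = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                members.append((r, c))
                for dr, dc in neigh:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and not seen[rr, cc] \
                            and codes[rr, cc] == code:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            patches.append((int(code), len(members)))
    return patches


def assert_matches_oracle(codes, connectivity):
    r = LandUseRaster(codes.astype(np.int64), 1000.0)
    ps = label_patches(r, connectivity)
    got = sorted(zip(ps.patches["code"], ps.patches["n_pixels"]))
    want = sorted(flood_fill_patches(codes, r.nodata_code, connectivity))
    assert got == want


# -- scalar formulas ---------------------------------------------------------

@pytest.mark.parametrize(
    "n,a,expected", [(1, 1.0, 1.0), (10, 4.0, 2.5), (1, 3.0, 1 / 3)]
)
def test_fragmentation(n, a, expected):
    assert fragmentation(n, a) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "A,a_i,n_i,expected",
    [(4.0, 4.0, 1, 0.25), (100.0, 25.0, 4, 0.4), (4.0, 3.0, 1, 1 / 3), (4.0, 1.0, 1, 1.0)],
)
def test_separation(A, a_i, n_i, expected):
    assert separation(A, a_i, n_i) == pytest.approx(expected, abs=1e-12)


def test_separation_sqrt_scaling():
    base = separation(100.0, 25.0, 4)
    assert separation(100.0, 25.0, 8) == pytest.approx(base * np.sqrt(2))


@pytest.mark.parametrize(
    "q,m,l,expected",
    [(1, 1, 1, 1.0), (1, 0.5, 0.5, 0.625), (0, 0, 0, 0.0),
     (1, 0.5, 0.75, 0.75), (1, 0.5, 0.25, 0.5)],
)
def test_dominance(q, m, l, expected):
    assert dominance(q, m, l) == pytest.approx(expected, abs=1e-12)


def test_dominance_rejects_out_of_range():
    with pytest.raises(ValueError):
        dominance(1.2, 0, 0)


@pytest.mark.parametrize(
    "c,n,d,expected",
    [(1, 1, 1, 1.0), (1 / 3, 1 / 3, 0.75, 0.41666667), (1, 1, 0.5, 0.9)],
)
def test_disturbance_default_weights(c, n, d, expected):
    assert disturbance(c, n, d) == pytest.approx(expected, abs=1e-8)


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        MetricWeights(0.5, 0.3, 0.3)


@pytest.mark.parametrize(
    "name,expected",
    [("construction", 0.0), ("forest", 0.25), ("grass", 0.5),
     ("cultivated", 0.75), ("water", 1.0)],
)
def test_fragility_rank_normalization(name, expected):
    assert fragility(name) == expected


def test_fragility_unknown_class():
    with pytest.raises(KeyError):
        fragility("wetland")


@pytest.mark.parametrize(
    "e,f,expected", [(5.0, 0.0, 0.0), (0.41666667, 0.5, 0.20833333), (0.9, 1.0, 0.9)]
)
def test_loss_index(e, f, expected):
    assert loss_index(e, f) == pytest.approx(expected, abs=1e-8)


# -- patch labeling ----------------------------------------------------------

class TestLabelPatches:
    def test_uniform_single_patch(self):
        r = LandUseRaster(np.full((3, 3), 3), 1000.0)
        ps = label_patches(r)
        assert len(ps.patches) == 1
        assert ps.patches.loc[0, "area_km2"] == 9.0

    def test_diagonal_connectivity(self):
        codes = np.full((2, 2), 2)
        codes[0, 0] = codes[1, 1] = 4  # diagonal cultivated pixels
        r = LandUseRaster(codes, 1000.0)
        cult4 = label_patches(r, 4).patches.query("name == 'cultivated'")
        cult8 = label_patches(r, 8).patches.query("name == 'cultivated'")
        assert len(cult4) == 2
        assert len(cult8) == 1

    def test_nodata_never_joins(self):
        codes = np.array([[3, -9999, 3]])
        ps = label_patches(LandUseRaster(codes, 1000.0), 8)
        assert len(ps.patches) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_vs_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        codes = rng.choice([1, 2, 3, -9999], size=(64, 64))
        assert_matches_oracle(codes, connectivity)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**25 - 1),
           st.sampled_from([4, 8]))
    def test_small_binary_rasters_vs_oracle(self, nr, nc, bits, connectivity):
        vals = [(bits >> k) & 1 for k in range(nr * nc)]
        codes = (np.array(vals[: nr * nc]).reshape(nr, nc) + 2)  # codes 2/3
        assert_matches_oracle(codes, connectivity)


# -- full table --------------------------------------------------------------

class TestClassMetricsTable:
    def test_worked_fixture(self, toy_raster, toy_grid):
        df = class_metrics(toy_raster, toy_grid)
        g, w = df.loc["grass"], df.loc["water"]
        assert g["C"] == pytest.approx(1 / 3)
        assert g["N"] == pytest.approx(1 / 3)
        assert g["D"] == pytest.approx(0.75)
        assert g["E"] == pytest.approx(0.41666667)
        assert g["R"] == pytest.approx(0.20833333)
        assert w["E"] == pytest.approx(0.9)
        assert w["R"] == pytest.approx(0.9)

    def test_share_columns_sum_to_one(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([1, 2, 3, 4, 5], size=(40, 40))
        r = LandUseRaster(codes, 100.0)
        df = class_metrics(r, build_grid(r, 500.0))
        assert df["M"].sum() == pytest.approx(1.0, abs=1e-12)
        assert df["L"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ((df[["Q", "M", "L"]] >= 0) & (df[["Q", "M", "L"]] <= 1)).all().all()

    def test_construction_loss_always_zero(self):
        rng = np.random.default_rng(4)
        codes = rng.choice([1, 2, 3], size=(30, 30))
        r = LandUseRaster(codes, 100.0)
        df = class_metrics(r, build_grid(r, 300.0))
        assert df.loc["construction", "R"] == 0.0

    def test_more_patches_raise_c_n(self):
        # one grass blob vs four separated blobs, equal total grass area
        one = np.full((8, 8), 4)
        one[:2, :4] = 3
        four = np.full((8, 8), 4)
        for r0, c0 in [(0, 0), (0, 6), (6, 0), (6, 6)]:
            four[r0:r0 + 2, c0] = 3
        m1 = class_metrics(
            LandUseRaster(one, 1000.0), build_grid(LandUseRaster(one, 1000.0), 8000.0)
        )
        m4 = class_metrics(
            LandUseRaster(four, 1000.0), build_grid(LandUseRaster(four, 1000.0), 8000.0)
        )
        assert m4.loc["grass", "C"] > m1.loc["grass", "C"]
        assert m4.loc["grass", "N"] > m1.loc["grass", "N"]
        assert m4.loc["grass", "E"] > m1.loc["grass", "E"]
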