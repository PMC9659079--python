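"""Neutral-landscape synthesis and Markov land-use change.

Generates five-class patchy categorical rasters with controlled composition
and patch count (multi-seed region growing with per-class pixel quotas), and
evolves them through time with a row-stochastic per-pixel transition matrix,
optionally biased toward classes already present in a pixel's 8-neighborhood.
This stands in for a classified multi-date satellite series: the default
configuration mimics a county-scale loess-hill landscape (~1330 km² at 100 m
pixels) dominated by cultivated land, with grass and forest secondary and
water/construction rare, and transitions dominated by cultivated→grass
conversion with a smaller cultivated→construction stream.

Region growing was chosen over Gaussian-field thresholding because the seed
count per class directly steers the patch count n_i that the landscape
metrics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .raster import CLASS_NAMES, DEFAULT_CODEBOOK, LandUseRaster

__all__ = [
    "SyntheticConfig",
    "TransitionSpec",
    "COUNTY_SCALE_DEFAULT",
    "default_transitions",
    "generate_landscape",
    "evolve_landscape",
    "make_series",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the neutral-landscape generator.

    ``composition`` maps class name -> target area fraction (must sum to 1);
    ``mean_patch_size`` is the expected pixels per seed patch and controls
    the patch count; ``clustering`` in [0,1] biases Markov evolution toward
    classes present in the 8-neighborhood.
    """

    n_rows: int = 360
    n_cols: int = 370
    pixel_size: float = 100.0
    composition: dict[str, float] = field(
        default_factory=lambda: {
            "cultivated": 0.4876,
            "grass": 0.3345,
            "forest": 0.1658,
            "construction": 0.0115,
            "water": 0.0006,
        }
    )
    mean_patch_size: float = 120.0
    seed: int = 0
    clustering: float = 0.9

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.mean_patch_size < 1:
            raise ValueError("mean_patch_size must be >= 1")
        comp = self.composition
        if any(v < 0 for v in comp.values()):
            raise ValueError("composition fractions must be >= 0")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {total!r}")
        unknown = set(comp) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class names in composition: {sorted(unknown)}")


@dataclass(frozen=True)
class TransitionSpec:
    """Row-stochastic per-pixel class-transition matrix for one time step.

    ``matrix[i, j]`` is P(class j at t+1 | class i at t), rows/cols ordered
    by ``classes``.
    """

    classes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.classes)
        if m.shape != (k, k):
            raise ValueError(f"matrix must be {k}x{k}, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("transition probabilities must be in [0, 1]")
        rowsums = m.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got {rowsums}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "classes", tuple(self.classes))

    @classmethod
    def identity(cls, classes: Sequence[str] = CLASS_NAMES) -> "TransitionSpec":
        return cls(tuple(classes), np.eye(len(classes)))

    @classmethod
    def from_dict(
        cls,
        rows: dict[str, dict[str, float]],
        classes: Sequence[str] = CLASS_NAMES,
    ) -> "TransitionSpec":
        """Build from sparse {from: {to: p}} rows; missing mass stays put."""
        classes = tuple(classes)
        idx = {c: i for i, c in enumerate(classes)}
        m = np.eye(len(classes))
        for src, dests in rows.items():
            i = idx[src]
            m[i] = 0.0
            moved = 0.0
            for dst, p in dests.items():
                m[i, idx[dst]] = p
                moved += p
            if src not in dests:
                m[i, i] = 1.0 - moved
        return cls(classes, m)


#: County-scale default fixture: 5 dates, 360x370 grid at 100 m
#: (1332 km²), cultivated-dominant start.
COUNTY_SCALE_DEFAULT = SyntheticConfig()


def default_transitions(n_steps: int = 4) -> list[TransitionSpec]:
    """Per-step transition specs emulating the observed dynamics: most
    conversion flows out of cultivated land, overwhelmingly into grass with
    a minor construction stream, plus weak grass↔cultivated/forest churn."""
    spec = TransitionSpec.from_dict(
        {
            "cultivated": {"grass": 0.055, "construction": 0.004, "forest": 0.002},
            "grass": {"cultivated": 0.030, "forest": 0.012, "construction": 0.002},
            "forest": {"grass": 0.010},
            "water": {"construction": 0.005},
            "construction": {"cultivated": 0.020},
        }
    )
    return [spec] * n_steps


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

_NEIGH4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def generate_landscape(config: SyntheticConfig) -> LandUseRaster:
    """Grow a patchy categorical landscape matching ``config.composition``.

    Seeds per class = round(target pixels / mean_patch_size), at least one
    for any class with positive target.  Growth claims are popped uniformly
    at random from a global frontier; a class stops claiming once its pixel
    quota is met, until only quota-exhausted classes can still grow (then
    quotas are released so enclosed holes get filled).  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    n_pix = nr * nc
    name_to_code = {v: k for k, v in DEFAULT_CODEBOOK.items()}

    targets = {c: f * n_pix for c, f in config.composition.items() if f > 0}
    if not targets:
        raise ValueError("composition has no positive entries")
    # integer quotas summing to n_pix (largest remainder)
    quota = {c: int(np.floor(t)) for c, t in targets.items()}
    rem = n_pix - sum(quota.values())
    for c in sorted(targets, key=lambda c: targets[c] - quota[c], reverse=True)[:rem]:
        quota[c] += 1

    if len(targets) == 1:
        only = next(iter(targets))
        codes = np.full((nr, nc), name_to_code[only], dtype=np.int64)
        return LandUseRaster(codes, config.pixel_size)

    grid = np.full(n_pix, -1, dtype=np.int64)  # flat class-code grid
    filled = {c: 0 for c in targets}

    # seed placement: distinct random pixels
    n_seeds = {
        c: max(1, int(round(targets[c] / config.mean_patch_size))) for c in targets
    }
    order = sorted(targets, key=lambda c: name_to_code[c])
    all_seeds = rng.choice(n_pix, size=sum(n_seeds.values()), replace=False)
    frontier: list[tuple[int, int]] = []  # (flat pixel, claiming class code)
    pos = 0
    for c in order:
        code = name_to_code[c]
        for s in all_seeds[pos : pos + n_seeds[c]]:
            grid[s] = code
            filled[c] += 1
            frontier.append((int(s), code))
        pos += n_seeds[c]

    code_to_name = DEFAULT_CODEBOOK
    quotas_active = True
    while True:
        # push fresh claims from newly assigned pixels lazily: frontier holds
        # assigned pixels; expand by popping one and claiming one random
        # unassigned neighbor, re-pushing while neighbors remain.
        if not frontier:
            if grid.min() >= 0:
                break
            if quotas_active:
                quotas_active = False
                # restart frontier from all assigned pixels bordering holes
                holes = grid.reshape(nr, nc) < 0
                border = ndimage.binary_dilation(holes).reshape(-1) & (grid >= 0)
                frontier = [(int(i), int(grid[i])) for i in np.flatnonzero(border)]
                continue
            raise AssertionError("region growing stalled")  # pragma: no cover
        j = int(rng.integers(len(frontier)))
        pix, code = frontier[j]
        cname = code_to_name[code]
        if quotas_active and filled[cname] >= quota[cname]:
            frontier[j] = frontier[-1]
            frontier.pop()
            continue
        r, c0 = divmod(pix, nc)
        free = []
        for dr, dc in _NEIGH4:
            r2, c2 = r + dr, c0 + dc
            if 0 <= r2 < nr and 0 <= c2 < nc:
                p2 = r2 * nc + c2
                if grid[p2] < 0:
                    free.append(p2)
        if not free:
            frontier[j] = frontier[-1]
            frontier.pop()
            continue
        p2 = free[int(rng.integers(len(free)))] if len(free) > 1 else free[0]
        grid[p2] = code
        filled[cname] += 1
        frontier.append((p2, code))

    return LandUseRaster(grid.reshape(nr, nc), config.pixel_size)


# ---------------------------------------------------------------------------
# Markov evolution
# ---------------------------------------------------------------------------

def evolve_landscape(
    raster: LandUseRaster,
    spec: TransitionSpec,
    seed: int,
    clustering: float = 0.0,
) -> LandUseRaster:
    """One Markov step: each non-nodata pixel draws its next class from its
    row of ``spec.matrix``; with ``clustering`` γ>0 the row is re-weighted by
    (1−γ) + γ·[class present in the pixel's 8-neighborhood] and renormalized,
    which makes conversions coalesce into patches. Deterministic per seed."""
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    name_to_code = {v: k for k, v in raster.codebook.items()}
    class_codes = [name_to_code[c] for c in spec.classes if c in name_to_code]
    present = raster.present_codes()
    spec_codes = {name_to_code[c] for c in spec.classes if c in name_to_code}
    missing = present - spec_codes
    if missing:
        raise ValueError(
            f"raster codes {sorted(missing)} have no row in the transition spec"
        )

    rng = np.random.default_rng(seed)
    codes = raster.codes
    valid = raster.valid_mask
    nr, nc = codes.shape
    k = len(spec.classes)
    code_of = np.array([name_to_code[c] for c in spec.classes], dtype=np.int64)
    # map code -> row index
    row_of = np.full(int(codes.max()) + 2, -1, dtype=np.int64)
    row_of[code_of] = np.arange(k)
    rows = np.where(valid, row_of[np.maximum(codes, 0)], -1)

    probs = spec.matrix[np.maximum(rows, 0)]  # (nr, nc, k)
    if clustering > 0.0:
        neigh = np.empty((nr, nc, k), dtype=bool)
        st = np.ones((3, 3), dtype=bool)
        for ji, code in enumerate(code_of):
            neigh[..., ji] = ndimage.binary_dilation(codes == code, structure=st)
        w = probs * ((1.0 - clustering) + clustering * neigh)
        tot = w.sum(axis=2, keepdims=True)
        probs = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), probs)

    cum = np.cumsum(probs, axis=2)
    u = rng.random((nr, nc))
    draw = (u[..., None] > cum).sum(axis=2)
    draw = np.minimum(draw, k - 1)
    new_codes = np.where(valid, code_of[draw], raster.nodata_code)
    return raster.with_codes(new_codes.astype(codes.dtype))


def make_series(
    config: SyntheticConfig,
    specs: Sequence[TransitionSpec],
    seed: int | None = None,
) -> list[LandUseRaster]:
    """Initial landscape plus one Markov step per spec (dates = len(specs)+1).

    The base seed (default ``config.seed``) spawns one independent substream
    per stage, so each date is individually reproducible.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    sub = ss.spawn(len(specs) + 1)
    first = generate_landscape(
        SyntheticConfig(
            n_rows=config.n_rows,
            n_cols=config.n_cols,
            pixel_size=config.pixel_size,
            composition=config.composition,
            mean_patch_size=config.mean_patch_size,
            seed=int(sub[0].generate_state(1)[0] % (2**31)),
            clustering=config.clustering,
        )
    )
    series = [first]
    for t, spec in enumerate(specs):
        step_seed = int(sub[t + 1].generate_state(1)[0] % (2**31))
        series.append(
            evolve_landscape(series[-1], spec, step_seed, clustering=config.clustering)
        )
    assert all(r.shape == first.shape for r in series)
    return series
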