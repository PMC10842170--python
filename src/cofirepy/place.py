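"""Spatial rate maps and place-cell classification.

Rate maps average each cell's 10-Hz activity over ~2.5 x 2.5 cm spatial bins
of the arena; linearized maps use 30 angular bins of 12 degrees around the
arena center, ignoring radial distance.  A cell is classified as a place
cell when both spatial coherence and information content exceed the
chance distribution obtained by circularly time-shifting its activity
relative to the trajectory (z > 1.96, one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateMap",
    "LinearRateMap",
    "PlaceCellResult",
    "compute_rate_map",
    "rate_map_bin_index",
    "linearize_rate_map",
    "spatial_coherence",
    "information_content",
    "shuffle_significance",
    "classify_place_cell",
    "ensemble_place_cells",
    "place_map_similarity",
]

DEFAULT_BIN_CM = 2.5
OCCUPANCY_THRESHOLD_S = 0.2  # bins visited less than this are masked
N_ANGULAR_BINS = 30
Z_CRITERION = 1.96


@dataclass
class RateMap:
    """Occupancy-normalized spatial activity map (events/s per bin)."""

    rate: np.ndarray       # (ny, nx)
    occupancy: np.ndarray  # s per bin
    valid: np.ndarray      # occupancy above threshold
    bin_cm: float
    extent: float          # arena extent, cm (maps are square over [0, extent]^2)
    signed: bool = False   # True for derived maps (e.g. of PTI rates)

    def __post_init__(self):
        if not self.signed and (self.rate[self.valid] < 0).any():
            raise ValueError("rates must be nonnegative")

    def occupancy_probability(self) -> np.ndarray:
        """p(x) over valid bins (sums to 1)."""
        occ = np.where(self.valid, self.occupancy, 0.0)
        total = occ.sum()
        if total <= 0:
            raise ValueError("no valid occupancy")
        return occ / total


@dataclass
class LinearRateMap:
    """Mean activity in 30 angular bins of 12 degrees (radial distance ignored)."""

    rate: np.ndarray       # (30,)
    occupancy: np.ndarray  # s per bin

    def __post_init__(self):
        if len(self.rate) != N_ANGULAR_BINS:
            raise ValueError(f"need {N_ANGULAR_BINS} angular bins")


@dataclass
class PlaceCellResult:
    coherence: float
    info_content: float
    z_coherence: float
    z_info: float

    @property
    def is_place_cell(self) -> bool:
        return bool(self.z_coherence > Z_CRITERION and self.z_info > Z_CRITERION)


def _bin_edges(extent: float, bin_cm: float) -> np.ndarray:
    n = int(np.ceil(extent / bin_cm))
    return np.arange(n + 1) * bin_cm


def compute_rate_map(
    recording,
    cell: int,
    bin_cm: float = DEFAULT_BIN_CM,
    occupancy_threshold: float = OCCUPANCY_THRESHOLD_S,
    activity: np.ndarray | None = None,
) -> RateMap:
    """Average activity per spatial bin: summed events / occupancy time.

    ``activity`` overrides the cell's raster row (used e.g. for maps of
    position-tuning-independent rates, which may be negative; validity
    masking is identical).
    """
    pos = recording.trajectory.positions
    if len(pos) == 0:
        raise ValueError("empty trajectory")
    act = recording.raster[cell] if activity is None else np.asarray(activity, float)
    edges = _bin_edges(recording.arena.extent, bin_cm)
    n = len(edges) - 1
    ix = np.clip(np.digitize(pos[:, 0], edges) - 1, 0, n - 1)
    iy = np.clip(np.digitize(pos[:, 1], edges) - 1, 0, n - 1)
    flat = iy * n + ix
    counts = np.bincount(flat, minlength=n * n).reshape(n, n)
    events = np.bincount(flat, weights=act, minlength=n * n).reshape(n, n)
    occupancy = counts * recording.trajectory.dt
    valid = occupancy >= occupancy_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid, events / occupancy, 0.0)
    if activity is None and (rate[valid] < 0).any():
        raise ValueError("negative activity in raster")
    return RateMap(rate=rate, occupancy=occupancy, valid=valid,
                   bin_cm=bin_cm, extent=recording.arena.extent,
                   signed=activity is not None)


def rate_map_bin_index(recording, rmap: RateMap):
    """Per-frame (row, col, inside) indices of the trajectory into a map's grid."""
    pos = recording.trajectory.positions
    edges = _bin_edges(rmap.extent, rmap.bin_cm)
    n = len(edges) - 1
    ix = np.digitize(pos[:, 0], edges) - 1
    iy = np.digitize(pos[:, 1], edges) - 1
    inside = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
    return np.clip(iy, 0, n - 1), np.clip(ix, 0, n - 1), inside


def linearize_rate_map(recording, cell: int, activity: np.ndarray | None = None) -> LinearRateMap:
    """Angular rate map: 12-degree bins around the arena center.

    A frame exactly at the center is assigned to bin 0 (degenerate angle).
    """
    pos = recording.trajectory.positions
    if len(pos) == 0:
        raise ValueError("empty trajectory")
    act = recording.raster[cell] if activity is None else np.asarray(activity, float)
    c = recording.arena.extent / 2.0
    dx, dy = pos[:, 0] - c, pos[:, 1] - c
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    ang[(dx == 0) & (dy == 0)] = 0.0
    bins = np.minimum((ang / (2 * np.pi) * N_ANGULAR_BINS).astype(int), N_ANGULAR_BINS - 1)
    counts = np.bincount(bins, minlength=N_ANGULAR_BINS)
    events = np.bincount(bins, weights=act, minlength=N_ANGULAR_BINS)
    occupancy = counts * recording.trajectory.dt
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, events / np.maximum(occupancy, 1e-12), 0.0)
    return LinearRateMap(rate=rate, occupancy=occupancy)


def spatial_coherence(rmap: RateMap) -> float:
    """Pearson r between each bin's rate and the mean rate of its up-to-8
    valid neighbors; NaN when fewer than 2 usable bins or zero variance."""
    rate, valid = rmap.rate, rmap.valid
    ny, nx = rate.shape
    a, b = [], []
    for y in range(ny):
        for x in range(nx):
            if not valid[y, x]:
                continue
            acc, k = 0.0, 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx and valid[yy, xx]:
                        acc += rate[yy, xx]
                        k += 1
            if k:
                a.append(rate[y, x])
                b.append(acc / k)
    if len(a) < 2:
        return np.nan
    a, b = np.asarray(a), np.asarray(b)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def information_content(rmap: RateMap) -> float:
    """Spatial information: sum_x p(x) (r_x / R) log2(r_x / R), bits.

    R is the occupancy-weighted mean rate; bins with r_x = 0 contribute 0.
    NaN for a silent cell (R = 0).  Invariant to uniform rate rescaling.
    """
    p = rmap.occupancy_probability()
    r = np.where(rmap.valid, rmap.rate, 0.0)
    R = float((p * r).sum())
    if R <= 0:
        return np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r / R
        terms = np.where(r > 0, p * ratio * np.log2(np.where(r > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def _metric_fn(metric):
    if callable(metric):
        return metric
    return {"coherence": spatial_coherence, "info": information_content}[metric]


def shuffle_significance(
    recording,
    cell: int,
    metric="info",
    n_shuffles: int = 100,
    min_shift_s: float = 20.0,
    rng: np.random.Generator | None = None,
    bin_cm: float = DEFAULT_BIN_CM,
    activity: np.ndarray | None = None,
) -> float:
    """Shuffle z-score of a rate-map metric: (val - mean) / std of the values
    obtained after circularly time-shifting the activity trace relative to the
    trajectory by random offsets of at least ``min_shift_s`` seconds."""
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng() if rng is None else rng
    fn = _metric_fn(metric)
    act = recording.raster[cell] if activity is None else np.asarray(activity, float)
    n = len(act)
    min_shift = int(min_shift_s / recording.trajectory.dt)
    if 2 * min_shift >= n:
        raise ValueError("recording too short for the minimum shuffle shift")
    val = fn(compute_rate_map(recording, cell, bin_cm=bin_cm, activity=act))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shift = int(rng.integers(min_shift, n - min_shift))
        shifted = np.roll(act, shift)
        null[s] = fn(compute_rate_map(recording, cell, bin_cm=bin_cm, activity=shifted))
    null = null[np.isfinite(null)]
    if len(null) < 2 or null.std(ddof=0) == 0:
        return np.nan
    return float((val - null.mean()) / null.std(ddof=0))


def classify_place_cell(
    recording,
    cell: int,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    bin_cm: float = DEFAULT_BIN_CM,
) -> PlaceCellResult:
    """Both-metric place-cell test: coherence and information content must each
    exceed their shuffle distribution at z > 1.96."""
    rng = np.random.default_rng() if rng is None else rng
    rmap = compute_rate_map(recording, cell, bin_cm=bin_cm)
    coh = spatial_coherence(rmap)
    info = information_content(rmap)
    z_coh = shuffle_significance(recording, cell, "coherence", n_shuffles, rng=rng, bin_cm=bin_cm)
    z_info = shuffle_significance(recording, cell, "info", n_shuffles, rng=rng, bin_cm=bin_cm)
    return PlaceCellResult(coherence=coh, info_content=info,
                           z_coherence=np.nan_to_num(z_coh, nan=-np.inf),
                           z_info=np.nan_to_num(z_info, nan=-np.inf))


def ensemble_place_cells(
    recordings,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    bin_cm: float = DEFAULT_BIN_CM,
) -> np.ndarray:
    """Per-cell place flags over a day: a cell counts as a place cell when it
    passes the both-metric criterion in at least one of the day's trials
    (classification per visit, in either environment)."""
    rng = np.random.default_rng() if rng is None else rng
    n_cells = recordings[0].n_cells
    flags = np.zeros(n_cells, bool)
    for rec in recordings:
        for c in range(n_cells):
            if not flags[c]:
                res = classify_place_cell(rec, c, n_shuffles=n_shuffles, rng=rng,
                                          bin_cm=bin_cm)
                flags[c] = res.is_place_cell
    return flags


def place_map_similarity(
    map_a: RateMap, map_b: RateMap, min_bins: int = 10, crop: bool = False
) -> tuple[float, float]:
    """Pearson r over jointly valid bins, plus Fisher's z = atanh(r).

    r is clamped to +/-(1 - 1e-6) before the transform.  Requires identical
    bin geometry and at least ``min_bins`` jointly valid bins; with ``crop``,
    maps from arenas of slightly different size are compared over their
    common top-left sub-grid (corresponding pixels).
    """
    a_rate, b_rate = map_a.rate, map_b.rate
    a_valid, b_valid = map_a.valid, map_b.valid
    if map_a.bin_cm != map_b.bin_cm:
        raise ValueError("rate maps have different bin sizes")
    if a_rate.shape != b_rate.shape:
        if not crop:
            raise ValueError("rate maps have mismatched geometry")
        ny = min(a_rate.shape[0], b_rate.shape[0])
        nx = min(a_rate.shape[1], b_rate.shape[1])
        a_rate, b_rate = a_rate[:ny, :nx], b_rate[:ny, :nx]
        a_valid, b_valid = a_valid[:ny, :nx], b_valid[:ny, :nx]
    map_a = RateMap(rate=a_rate, occupancy=np.ones_like(a_rate), valid=a_valid,
                    bin_cm=map_a.bin_cm, extent=map_a.extent)
    map_b = RateMap(rate=b_rate, occupancy=np.ones_like(b_rate), valid=b_valid,
                    bin_cm=map_b.bin_cm, extent=map_b.extent)
    joint = map_a.valid & map_b.valid
    if joint.sum() < min_bins:
        raise ValueError(f"fewer than {min_bins} jointly valid bins")
    a, b = map_a.rate[joint], map_b.rate[joint]
    if a.std() == 0 or b.std() == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(a, b)[0, 1])
    rc = np.clip(r, -(1 - 1e-6), 1 - 1e-6)
    return r, float(np.arctanh(rc))
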