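"""Synthetic multi-day, two-environment ensemble recordings.

Generates the kind of data a miniscope CA1 experiment yields after source
extraction: binary deconvolved-activity rasters at 10 Hz for a few hundred
cells, together with the animal's trajectory, soma coordinates, and
environment/day labels.  The generative model reproduces the statistical
structure the downstream analyses assume:

* multimodal place tuning in a ~20-25% place-cell subset (1-3 Gaussian
  fields per cell per environment, fields drawn independently per
  environment so that place maps "remap");
* an internally organized cofiring backbone: cells are grouped into a few
  "assemblies" whose slow latent gain fluctuations cofluctuate, producing
  positive 1-s Kendall correlations that persist across environments (the
  reregistration backbone);
* a minority anti-cofiring subpopulation gated by a slow two-state latent:
  while the latent is up, engaged anti cells are strongly facilitated (or,
  for a minority, suppressed) while the bulk population receives a mild
  opposite gating, producing a long tail of negative 1-s Kendall
  correlations between anti cells and the rest of the ensemble (both cells
  of an anti-cofiring pair are active overall, just rarely together);
* overdispersion: a slow log-normal multiplicative gain per cell (AR(1)
  with ~10-s autocorrelation) makes firing trial-to-trial variable beyond
  a memoryless draw from the tuning map;
* partial cell overlap across the nine recording days (three days per week
  for three weeks), calibrated so that about half the cells survive a
  two-week gap.

Two protocol modes differ in how the anti-cofiring subset relates to the
environments.  In ``remap`` mode each environment gets an independent latent
registration (the conventional remapping hypothesis); in ``reregister`` mode
a single latent cofiring structure is reused in both environments with an
environment-specific registration: a fixed subset of the anti-cofiring cells
swaps gating sign between the two environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "GroundTruthEnsemble",
    "EnsembleRecording",
    "Protocol",
    "CYLINDER",
    "SQUARE",
    "generate_trajectory",
    "make_ground_truth",
    "generate_ensemble_pair",
    "composite_environment",
]

ENV_LABELS = ("cylinder", "square", "homecage")
GRID_UNITS = 24          # random-walk grid resolution across an arena
WALK_DT = 0.1            # s, one move per 10-Hz frame
SPEED_MIN, SPEED_MAX = 0.1, 1.0   # grid units per move


@dataclass(frozen=True)
class ArenaSpec:
    """Arena geometry: circle/square in cm, or an abstract composite grid."""

    shape: str                 # circle | square | ring | composite
    extent: float              # diameter / side, cm (grid units for composite)
    walls: str = ""
    grid: tuple[int, int] | None = None  # composite: tiling of source maps

    def __post_init__(self):
        if self.shape not in ("circle", "square", "ring", "composite"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.extent <= 0:
            raise ValueError("arena extent must be positive")
        if self.shape == "composite" and self.grid is None:
            raise ValueError("composite arenas need an integer tiling grid")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        half = self.extent / 2.0
        c = xy - half
        if self.shape == "circle":
            return (c ** 2).sum(axis=1) <= half ** 2 + 1e-9
        return (np.abs(c) <= half + 1e-9).all(axis=1)


CYLINDER = ArenaSpec("circle", 32.0, walls="transparent")
SQUARE = ArenaSpec("square", 28.5, walls="opaque black, patterned")


@dataclass
class Trajectory:
    """Uniformly sampled positions (cm) with constant time step."""

    times: np.ndarray      # s
    positions: np.ndarray  # (n, 2) cm
    dt: float = WALK_DT

    def __post_init__(self):
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must align")
        if len(self.times) > 1 and not np.allclose(np.diff(self.times), self.dt):
            raise ValueError("time step must be constant")

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed, cm/s (same length as positions; first repeated)."""
        if len(self.positions) < 2:
            return np.zeros(len(self.positions))
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1) / self.dt
        return np.concatenate([[d[0]], d])


def generate_trajectory(
    arena: ArenaSpec,
    duration: float,
    seed: int | np.random.Generator,
    dt: float = WALK_DT,
) -> Trajectory:
    """Bounded random walk emulating open-field foraging.

    One move is drawn every ``dt``: the per-axis step is a random element of
    {-1, 0, 1} grid units scaled by a speed variable that itself performs a
    random walk (increments from {-0.1, 0, 0.1}, clamped to [0.1, 1.0]).
    Positions are reflected at the arena boundary.  One grid unit is
    extent / 24, so the walk's speed range scales with arena size.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    unit = arena.extent / GRID_UNITS
    if unit <= 0:
        raise ValueError("arena too small for one step")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.empty((n, 2))
    # start anywhere inside
    while True:
        p = rng.uniform(0, arena.extent, size=2)
        if arena.contains(p)[0]:
            break
    speed = SPEED_MIN
    half = arena.extent / 2.0
    for t in range(n):
        pos[t] = p
        step = rng.integers(-1, 2, size=2) * speed * unit
        speed = float(np.clip(speed + rng.choice((-0.1, 0.0, 0.1)), SPEED_MIN, SPEED_MAX))
        q = p + step
        if arena.shape == "circle":
            r = np.linalg.norm(q - half)
            if r > half:  # reflect radially back inside
                q = half + (q - half) * (2 * half / r - 1) * (1 / 1)
                q = half + (q - half) * min(1.0, (half - 1e-9) / max(np.linalg.norm(q - half), 1e-12))
        else:
            for ax in range(2):
                if q[ax] < 0:
                    q[ax] = -q[ax]
                elif q[ax] > arena.extent:
                    q[ax] = 2 * arena.extent - q[ax]
                q[ax] = float(np.clip(q[ax], 0, arena.extent))
        p = q
    times = np.arange(n) * dt
    return Trajectory(times=times, positions=pos, dt=dt)


@dataclass
class GroundTruthEnsemble:
    """Latent parameters of a synthetic ensemble (kept for recovery tests)."""

    arenas: dict[str, ArenaSpec]
    tuning: dict[str, np.ndarray]        # env -> (n_cells, nb, nb) expected events/s
    bin_cm: float
    place_cell: np.ndarray               # bool flags
    anti_cell: np.ndarray                # bool flags (anti-cofiring subpopulation)
    anti_sign: dict[str, np.ndarray]     # env -> +/-1 gating sign per cell (0 = disengaged)
    anti_counter: float                  # opposite-gating strength on the bulk population
    assembly: dict[str, np.ndarray]      # env -> assembly id per cell (-1 = none)
    assembly_strength: float
    env_gain: dict[str, np.ndarray]      # env -> per-cell rate multiplier (rate remapping)
    soma_um: np.ndarray                  # (n_cells, 2)
    mean_rate: np.ndarray                # events/s, spatial mean per cell (cylinder)
    overdispersion_sigma: float
    overdispersion_tau: float            # s
    latent_amplitude: float
    latent_dwell: tuple[float, float]    # s, (min, max)
    mode: str = "reregister"

    @property
    def n_cells(self) -> int:
        return len(self.place_cell)


@dataclass
class EnsembleRecording:
    """One 5-min trial: raster + trajectory + metadata; the atom of analysis."""

    raster: np.ndarray          # (n_cells, n_frames) nonnegative, 10 Hz
    trajectory: Trajectory
    environment: str
    trial: int
    day: int                    # 1..9 (recording day index)
    week: int                   # 1..3
    soma_um: np.ndarray
    arena: ArenaSpec
    cell_ids: np.ndarray        # indices into the ground-truth registry

    def __post_init__(self):
        if self.raster.shape[1] != len(self.trajectory.positions):
            raise ValueError("raster and trajectory frame counts differ")
        if self.environment not in ENV_LABELS:
            raise ValueError(f"environment must be one of {ENV_LABELS}")
        if (self.raster < 0).any():
            raise ValueError("raster must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.trajectory.dt


@dataclass(frozen=True)
class Protocol:
    """Recording protocol: which days, and trials per environment per day."""

    days: tuple[int, ...] = (1, 2, 3, 8, 9, 10, 15, 16, 17)
    trials_per_env: int = 2
    duration: float = 300.0
    include_homecage: bool = False

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(1 + (d - 1) // 7 for d in self.days)


def _multimodal_map(arena: ArenaSpec, bin_cm: float, rng, n_fields, peak_rate, floor):
    nb = int(np.ceil(arena.extent / bin_cm))
    yy, xx = np.meshgrid(
        (np.arange(nb) + 0.5) * bin_cm, (np.arange(nb) + 0.5) * bin_cm, indexing="ij"
    )
    m = np.full((nb, nb), floor)
    for _ in range(n_fields):
        while True:
            c = rng.uniform(0, arena.extent, 2)
            if arena.contains(c)[0]:
                break
        width = rng.uniform(2.5, 4.0)  # field sd, cm; narrow keeps in-field rates high
        m += peak_rate * np.exp(-((xx - c[0]) ** 2 + (yy - c[1]) ** 2) / (2 * width ** 2))
    return m


_OCCUPANCY_CACHE: dict = {}


def _stationary_occupancy(arena: ArenaSpec, bin_cm: float, duration: float = 40000.0):
    """Long-run occupancy probability per spatial bin of the foraging walk.

    The walk dwells on ~10-s timescales, so a long horizon is needed for a
    stable estimate; the result is cached per arena geometry.
    """
    key = (arena.shape, arena.extent, bin_cm)
    if key in _OCCUPANCY_CACHE:
        return _OCCUPANCY_CACHE[key]
    traj = generate_trajectory(arena, duration, np.random.default_rng(987654321))
    nb = int(np.ceil(arena.extent / bin_cm))
    ix = np.clip((traj.positions[:, 0] / bin_cm).astype(int), 0, nb - 1)
    iy = np.clip((traj.positions[:, 1] / bin_cm).astype(int), 0, nb - 1)
    occ = np.bincount(iy * nb + ix, minlength=nb * nb).reshape(nb, nb).astype(float)
    occ /= occ.sum()
    _OCCUPANCY_CACHE[key] = occ
    return occ


def make_ground_truth(
    n_cells: int = 300,
    place_fraction: float = 0.225,
    anti_fraction: float = 0.15,
    mode: str = "reregister",
    seed: int | np.random.Generator = 0,
    bin_cm: float = 2.5,
    overdispersion_sigma: float = 0.5,
    overdispersion_tau: float = 10.0,
    latent_amplitude: float = 0.9,
    anti_counter: float = 0.15,
    latent_dwell: tuple[float, float] = (5.0, 20.0),
    reregister_flip_fraction: float = 0.5,
    n_assemblies: int = 4,
    assembly_strength: float = 0.35,
    assembly_fraction: float = 0.7,
    env_gain_sigma: float = 0.25,
    env_gain_sigma_anti: float = 0.8,
    fov_um: float = 400.0,
) -> GroundTruthEnsemble:
    """Draw a ground-truth ensemble for the two-environment protocol.

    Place cells get 1-3 Gaussian fields per environment (independent between
    environments); the remaining cells are spatially untuned.  A fraction of
    cells forms the anti-cofiring subpopulation with gating signs +/-1; in
    ``reregister`` mode the square environment's signs equal the cylinder's
    with a fixed random subset flipped, in ``remap`` mode they are drawn
    independently.  The remaining cofiring structure comes from assemblies:
    groups of cells sharing a slow latent gain; assembly membership is
    environment-independent under ``reregister`` and redrawn per environment
    under ``remap``.

    Environments also differ in per-cell activity levels (rate remapping):
    each cell's rate in the square is its cylinder rate times a log-normal
    multiplier, with a wider spread for the anti-cofiring subpopulation --
    the environment identity signal is carried disproportionately by the
    anti-cofiring cells.
    """
    if mode not in ("remap", "reregister"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arenas = {"cylinder": CYLINDER, "square": SQUARE}
    place = rng.random(n_cells) < place_fraction
    anti = rng.random(n_cells) < anti_fraction
    peak = rng.lognormal(mean=np.log(1.5), sigma=0.4, size=n_cells)
    base = rng.lognormal(mean=np.log(0.5), sigma=0.5, size=n_cells)
    tuning = {}
    for env, arena in arenas.items():
        nb = int(np.ceil(arena.extent / bin_cm))
        maps = np.empty((n_cells, nb, nb))
        for c in range(n_cells):
            if place[c]:
                n_fields = rng.integers(1, 3)
                maps[c] = _multimodal_map(arena, bin_cm, rng, n_fields, peak[c], 0.02 * base[c])
            else:
                maps[c] = base[c]
        # normalize to the cell's base rate under the walk's long-run
        # occupancy: place cells are spatially structured, not more active
        occ = _stationary_occupancy(arena, bin_cm)
        sm = (maps * occ).sum(axis=(1, 2))
        maps *= (base / np.where(sm > 0, sm, 1.0))[:, None, None]
        tuning[env] = maps

    def draw_assemblies():
        a = rng.integers(0, max(n_assemblies, 1), size=n_cells)
        a[rng.random(n_cells) >= assembly_fraction] = -1
        return a

    assembly_cyl = draw_assemblies()
    assembly_sq = assembly_cyl if mode == "reregister" else draw_assemblies()

    def draw_engagement():
        # engaged anti cells mostly oppose the bulk (+1); a minority invert
        s = np.zeros(n_cells)
        s[anti] = rng.choice((1.0, 1.0, 1.0, -1.0, 0.0), size=int(anti.sum()))
        return s

    sign_cyl = draw_engagement()
    sign_sq = sign_cyl.copy()
    if mode == "reregister":
        flip = anti & (rng.random(n_cells) < reregister_flip_fraction)
        resampled = draw_engagement()
        sign_sq[flip] = resampled[flip]
    else:
        sign_sq = draw_engagement()
    soma = rng.uniform(0, fov_um, size=(n_cells, 2))
    while True:  # soma coordinates pairwise distinct
        d = np.linalg.norm(soma[:, None] - soma[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        dup = np.argwhere(d == 0)
        if not len(dup):
            break
        soma[dup[:, 0]] += rng.uniform(-1, 1, size=(len(dup), 2))
    sigma_env = np.where(anti, env_gain_sigma_anti, env_gain_sigma)
    env_gain = {
        "cylinder": np.ones(n_cells),
        "square": np.exp(sigma_env * rng.standard_normal(n_cells) - sigma_env ** 2 / 2),
    }
    mean_rate = tuning["cylinder"].mean(axis=(1, 2))
    return GroundTruthEnsemble(
        arenas=arenas, tuning=tuning, bin_cm=bin_cm, place_cell=place, anti_cell=anti,
        anti_sign={"cylinder": sign_cyl, "square": sign_sq}, anti_counter=anti_counter,
        assembly={"cylinder": assembly_cyl, "square": assembly_sq},
        assembly_strength=assembly_strength, env_gain=env_gain, soma_um=soma,
        mean_rate=mean_rate, overdispersion_sigma=overdispersion_sigma,
        overdispersion_tau=overdispersion_tau, latent_amplitude=latent_amplitude,
        latent_dwell=latent_dwell, mode=mode,
    )


def _latent_path(n_frames: int, dt: float, dwell: tuple[float, float], rng) -> np.ndarray:
    """Two-state telegraph process; dwell times uniform in ``dwell`` seconds."""
    state = rng.integers(0, 2)
    out = np.empty(n_frames, np.int8)
    t = 0
    while t < n_frames:
        k = int(rng.uniform(*dwell) / dt)
        out[t : t + k] = state
        state = 1 - state
        t += k
    return out


def _ar1_gain(n_cells, n_frames, dt, sigma, tau, rng):
    """Log-normal multiplicative gain with AR(1) autocorrelation time ``tau`` s."""
    if sigma == 0:
        return np.ones((n_cells, n_frames))
    rho = np.exp(-dt / tau)
    z = np.empty((n_cells, n_frames))
    z[:, 0] = rng.standard_normal(n_cells)
    innov = rng.standard_normal((n_cells, n_frames)) * np.sqrt(1 - rho ** 2)
    for t in range(1, n_frames):
        z[:, t] = rho * z[:, t - 1] + innov[:, t]
    return np.exp(sigma * z - sigma ** 2 / 2)


def _tuning_rate(truth: GroundTruthEnsemble, env: str, traj: Trajectory, cells) -> np.ndarray:
    arena = truth.arenas[env]
    maps = truth.tuning[env][cells]
    nb = maps.shape[1]
    ix = np.clip((traj.positions[:, 0] / truth.bin_cm).astype(int), 0, nb - 1)
    iy = np.clip((traj.positions[:, 1] / truth.bin_cm).astype(int), 0, nb - 1)
    return maps[:, iy, ix]


def simulate_trial(
    truth: GroundTruthEnsemble,
    env: str,
    trial: int,
    day: int,
    week: int,
    cells: np.ndarray,
    rng: np.random.Generator,
    duration: float = 300.0,
    overdispersion: bool = True,
    latents: bool = True,
) -> EnsembleRecording:
    """Simulate one trial for the cells present that day."""
    if env == "homecage":
        arena = truth.arenas["cylinder"]
        traj = generate_trajectory(arena, duration, rng)
        rate = np.repeat(truth.mean_rate[cells, None], len(traj.positions), axis=1)
        env_for_sign = "cylinder"
    else:
        arena = truth.arenas[env]
        traj = generate_trajectory(arena, duration, rng)
        rate = _tuning_rate(truth, env, traj, cells) * truth.env_gain[env][cells, None]
        env_for_sign = env
    n_frames = rate.shape[1]
    if overdispersion:
        rate = rate * _ar1_gain(len(cells), n_frames, traj.dt, truth.overdispersion_sigma,
                                truth.overdispersion_tau, rng)
    if latents and truth.latent_amplitude > 0:
        lat = _latent_path(n_frames, traj.dt, truth.latent_dwell, rng).astype(float)
        sign = truth.anti_sign[env_for_sign][cells]
        coef = np.where(truth.anti_cell[cells],
                        truth.latent_amplitude * sign,
                        -truth.anti_counter)
        up = lat * 2 - 1  # -1 / +1
        gate = 1.0 + coef[:, None] * up[None, :]
        rate = rate * np.clip(gate, 0.0, None)
    if latents and truth.assembly_strength > 0:
        member = truth.assembly[env_for_sign][cells]
        n_asm = int(member.max()) + 1 if member.size and member.max() >= 0 else 0
        if n_asm:
            gates = np.ones((len(cells), n_frames))
            for a in range(n_asm):
                rows = member == a
                if rows.any():
                    al = _latent_path(n_frames, traj.dt, truth.latent_dwell, rng) * 2 - 1
                    gates[rows] = 1.0 + truth.assembly_strength * al[None, :]
            rate = rate * np.clip(gates, 0.0, None)
    p = np.clip(rate * traj.dt, 0.0, 1.0)
    raster = (rng.random(p.shape) < p).astype(np.uint8)
    return EnsembleRecording(
        raster=raster, trajectory=traj, environment=env, trial=trial, day=day,
        week=week, soma_um=truth.soma_um[cells], arena=arena, cell_ids=cells,
    )


def generate_ensemble_pair(
    truth: GroundTruthEnsemble,
    protocol: Protocol = Protocol(),
    mode: str | None = None,
    seed: int | np.random.Generator = 0,
    daily_survival: float = 0.952,
    overdispersion: bool = True,
    latents: bool = True,
) -> list[EnsembleRecording]:
    """Simulate the full interleaved two-environment protocol.

    Per day: ``trials_per_env`` visits to each environment in interleaved
    order (cylinder, square, cylinder, square, ...), optionally bracketed by a
    home-cage recording.  Cross-day dropout is a Bernoulli survival chain with
    per-day survival ``daily_survival`` (0.952**14 ~ 0.5, i.e. about half of
    the cells remain identified across a two-week gap).
    """
    if mode is not None and mode != truth.mode:
        raise ValueError(f"truth was built for mode {truth.mode!r}, got {mode!r}")
    if protocol.trials_per_env < 1:
        raise ValueError("protocol needs at least one trial per environment")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = truth.n_cells
    alive = np.ones(n, bool)
    recs: list[EnsembleRecording] = []
    prev_day = protocol.days[0]
    for day_idx, day in enumerate(protocol.days):
        gap = day - prev_day
        if gap > 0:
            alive &= rng.random(n) < daily_survival ** gap
        prev_day = day
        cells = np.flatnonzero(alive)
        week = protocol.weeks[day_idx]
        envs = ("cylinder", "square") * protocol.trials_per_env
        trial_counter = {"cylinder": 0, "square": 0}
        if protocol.include_homecage:
            recs.append(simulate_trial(truth, "homecage", 0, day_idx + 1, week, cells,
                                       rng, protocol.duration, overdispersion, latents))
        for env in envs:
            recs.append(simulate_trial(truth, env, trial_counter[env], day_idx + 1, week,
                                       cells, rng, protocol.duration, overdispersion, latents))
            trial_counter[env] += 1
    return recs


def composite_environment(maps_by_repetition: list[list[np.ndarray]]) -> list[np.ndarray]:
    """Tile four cells' rate maps into one large (2x2) map per repetition.

    ``maps_by_repetition[k]`` holds the four source maps (identical bin
    geometry) of repetition ``k``; slot order is (top-left, top-right,
    bottom-left, bottom-right).  Returns one large map per repetition, so a
    composite cell built from cells recorded in 4 visits exposes 4 maps.
    """
    out = []
    for rep_maps in maps_by_repetition:
        if len(rep_maps) != 4:
            raise ValueError("each repetition needs exactly 4 source maps")
        shapes = {m.shape for m in rep_maps}
        if len(shapes) != 1:
            raise ValueError("source maps must share bin geometry")
        a, b, c, d = rep_maps
        out.append(np.block([[a, b], [c, d]]))
    return out
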