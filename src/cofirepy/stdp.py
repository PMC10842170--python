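"""Heuristic spiking E-I ring network with spike-timing-dependent plasticity.

A layer of position-tuned input units drives a recurrently connected
excitatory population that also excites, and is inhibited by, a small
inhibitory population.  The recurrent E->E, E->I and I->E weights are all
plastic under pair-based STDP rules (the I->E rule carries an additional
constant depression term); input->E weights are fixed after initialization.
Units are leaky integrate-and-fire with a per-step leak factor exp(-dt), an
absolute refractory period, and additive pink noise on voltages and input
firing probabilities.

The track is the interval [0, 10) with circular (ring) topology.  Laps are
constant-velocity traversals; spatial tuning of the excitatory units is
quantified on 10 discrete track locations with two similarity metrics
(nearest-neighbor and halfway), both of the form
``S = 1 - (a_max - a_control) / (a_max + a_control)`` so that S = 1 for flat
tuning and S -> 0 for perfect single-location tuning.

Two code paths compute the dynamics: transparent single-step Python
operations (`input_drive`, `advance_timestep`, `stdp_update`) used by the
unit tests and hand-worked oracles, and a fused numba kernel used by
`run_laps`; a test asserts step-for-step agreement between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "NetworkParams",
    "InputTuning",
    "NetworkState",
    "SimulationRecord",
    "initialize_network",
    "sample_input_tuning",
    "input_drive",
    "advance_timestep",
    "stdp_update",
    "run_laps",
    "rate_maps_from_record",
    "spatial_similarity_metrics",
    "similarity_by_lap_block",
    "plateau_onset",
    "two_track_experiment",
    "pink_noise",
]

TRACK_LENGTH = 10.0
ALL_PATHWAYS = ("EE", "EI", "IE")


@dataclass(frozen=True)
class NetworkParams:
    """Simulation parameters; defaults are the published table values."""

    n_input: int = 1000
    n_excit: int = 500
    n_inhib: int = 50
    p_input: float = 0.20     # binomial p for the number of tuning centers per input unit
    p_input_e: float = 1.0    # input -> E connection probability
    p_ee: float = 0.25        # E -> E connection probability
    p_ei: float = 0.175      # E -> I connection probability
    p_ie: float = 0.30        # I -> E connection probability
    eta: float = 0.0005       # learning rate
    alpha: float = 0.05       # pink-noise strength
    dt: float = 0.007         # simulation time step
    r_pf: float = 8.0         # in-field firing rate
    sigma2: float = 0.1       # tuning width (variance)
    tau_if: float = 0.02      # absolute refractory period
    t_if: float = 1.0         # spiking threshold
    dt_kendall: float = 0.25  # bin length for cofiring correlations
    wmax_input_e: float = 0.05  # maximum initial input->E weight
    w_max: float = 0.50       # hard upper bound on any weight
    # Implementation choices not fixed by the parameter table:
    lap_duration: float = 5.0          # s per constant-velocity lap
    n_centers_binomial_n: int = 5      # centers per input unit ~ Binomial(n, p_input), >= 1
    n_track_bins: int = 10             # discrete locations for rate maps
    trace_on_nonspike: bool = False    # alternative trace-increment convention
    structural_plasticity: bool = True   # STDP may also create initially absent synapses
    ie_bias: float = 0.01              # constant depression in the I->E rule
    ie_symmetric: bool = True          # I->E rule potentiates on both spike orderings

    def __post_init__(self):
        for name in ("p_input", "p_input_e", "p_ee", "p_ei", "p_ie"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("eta", "alpha", "dt", "r_pf", "sigma2", "tau_if", "t_if",
                     "wmax_input_e", "w_max", "lap_duration"):
            if getattr(self, name) <= 0 and name not in ("eta", "alpha"):
                raise ValueError(f"{name} must be positive")

    @property
    def wmax_ee(self) -> float:
        # Scaling by 1/p conserves the expected initial weight per potential
        # connection (wmax_input_e / 2) across the weight populations.
        return self.wmax_input_e / self.p_ee

    @property
    def wmax_ei(self) -> float:
        return self.wmax_input_e / self.p_ei

    @property
    def wmax_ie(self) -> float:
        return self.wmax_input_e / self.p_ie

    @property
    def leak(self) -> float:
        return math.exp(-self.dt)

    @property
    def refractory_steps(self) -> int:
        return max(1, int(self.tau_if / self.dt))

    @property
    def steps_per_lap(self) -> int:
        return int(round(self.lap_duration / self.dt))


@dataclass
class InputTuning:
    """Gaussian position tuning of the input layer (>= 1 center per unit)."""

    centers: list[np.ndarray]  # per input unit, centers in [0, 10)
    sigma2: float

    def __post_init__(self):
        if any(len(c) == 0 for c in self.centers):
            raise ValueError("every input unit needs at least one tuning center")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(concatenated centers, offsets) layout for the numba kernel."""
        offsets = np.zeros(len(self.centers) + 1, np.int64)
        for i, c in enumerate(self.centers):
            offsets[i + 1] = offsets[i] + len(c)
        return np.concatenate(self.centers).astype(np.float64), offsets

    def evaluate(self, x: float) -> np.ndarray:
        """T_i(x): summed circular Gaussian tuning of every input unit at x."""
        if not 0 <= x < TRACK_LENGTH:
            raise ValueError(f"position {x} outside [0, {TRACK_LENGTH})")
        out = np.empty(len(self.centers))
        for i, c in enumerate(self.centers):
            d = np.abs(x - c)
            d = np.minimum(d, TRACK_LENGTH - d)
            out[i] = np.exp(-d * d / self.sigma2).sum()
        return out


def sample_input_tuning(params: NetworkParams, rng: np.random.Generator) -> InputTuning:
    """Draw tuning-center counts ~ Binomial(n, p_input) resampled to >= 1, centers ~ U[0, 10)."""
    centers = []
    for _ in range(params.n_input):
        k = 0
        while k == 0:
            k = rng.binomial(params.n_centers_binomial_n, params.p_input)
        centers.append(rng.uniform(0.0, TRACK_LENGTH, size=k))
    return InputTuning(centers=centers, sigma2=params.sigma2)


@dataclass
class NetworkState:
    """All weights, voltages, spike flags, traces and refractory timers.

    Weight matrices are stored [postsynaptic, presynaptic].
    """

    w_input_e: np.ndarray  # (n_E, n_input), non-plastic
    w_ee: np.ndarray       # (n_E, n_E), zero diagonal
    w_ei: np.ndarray       # (n_I, n_E)
    w_ie: np.ndarray       # (n_E, n_I)
    v_e: np.ndarray
    v_i: np.ndarray
    f_e: np.ndarray        # spike flags carried into the next step (float 0/1)
    f_i: np.ndarray
    tr_e: np.ndarray       # exponentially decaying spike traces
    tr_i: np.ndarray
    ref_e: np.ndarray      # remaining refractory steps (int)
    ref_i: np.ndarray
    mask_ee: np.ndarray = None  # structural connectivity (uint8); STDP confined to it
    mask_ei: np.ndarray = None
    mask_ie: np.ndarray = None

    def copy(self) -> "NetworkState":
        return NetworkState(**{k: getattr(self, k).copy() for k in self.__dataclass_fields__})

    def check(self, params: NetworkParams) -> None:
        """Assert the structural invariants (bounds, zero E-E diagonal, nonneg traces)."""
        for w in (self.w_ee, self.w_ei, self.w_ie):
            assert w.min() >= 0 and w.max() <= params.w_max + 1e-12
        assert np.all(np.diagonal(self.w_ee) == 0)
        assert self.tr_e.min() >= 0 and self.tr_i.min() >= 0


@dataclass
class SimulationRecord:
    """Spike rasters, positions and lap indices from a recorded run."""

    spikes_e: np.ndarray  # (steps, n_E) uint8
    spikes_i: np.ndarray  # (steps, n_I) uint8
    x: np.ndarray         # (steps,)
    lap: np.ndarray       # (steps,) nondecreasing lap index

    def __post_init__(self):
        assert len(self.x) == len(self.spikes_e) == len(self.lap)
        assert np.all(np.diff(self.lap) >= 0)


def initialize_network(params: NetworkParams, seed: int | np.random.Generator) -> NetworkState:
    """Random initial weights: present connections drawn U(0, wmax) at connection
    probability p, with wmax = wmax_input_e / p; input->E is dense at p_input_e."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def sample(shape, p, wmax):
        w = rng.uniform(0.0, wmax, size=shape)
        w *= rng.random(size=shape) < p
        return w

    w_input_e = sample((params.n_excit, params.n_input), params.p_input_e, params.wmax_input_e)
    w_ee = sample((params.n_excit, params.n_excit), params.p_ee, params.wmax_ee)
    np.fill_diagonal(w_ee, 0.0)
    w_ei = sample((params.n_inhib, params.n_excit), params.p_ei, params.wmax_ei)
    w_ie = sample((params.n_excit, params.n_inhib), params.p_ie, params.wmax_ie)
    z = np.zeros
    if params.structural_plasticity:
        ones = np.ones
        mask_ee, mask_ei, mask_ie = (ones(w_ee.shape, np.uint8),
                                     ones(w_ei.shape, np.uint8), ones(w_ie.shape, np.uint8))
        np.fill_diagonal(mask_ee, 0)
    else:
        mask_ee = (w_ee > 0).astype(np.uint8)
        mask_ei = (w_ei > 0).astype(np.uint8)
        mask_ie = (w_ie > 0).astype(np.uint8)
    return NetworkState(
        w_input_e=w_input_e, w_ee=w_ee, w_ei=w_ei, w_ie=w_ie,
        v_e=z(params.n_excit), v_i=z(params.n_inhib),
        f_e=z(params.n_excit), f_i=z(params.n_inhib),
        tr_e=z(params.n_excit), tr_i=z(params.n_inhib),
        ref_e=z(params.n_excit, np.int64), ref_i=z(params.n_inhib, np.int64),
        mask_ee=mask_ee, mask_ei=mask_ei, mask_ie=mask_ie,
    )


def input_drive(
    tuning: InputTuning,
    x: float,
    params: NetworkParams,
    noise: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Firing probabilities P_i(x) = [T_i(x) + alpha*eps] * dt * r_pf and Bernoulli spikes.

    Negative probabilities are clipped to 0 (and capped at 1).
    """
    t = tuning.evaluate(x)
    if noise is not None:
        t = t + params.alpha * np.asarray(noise)
    p = np.clip(t * params.dt * params.r_pf, 0.0, 1.0)
    if rng is None:
        spikes = np.zeros_like(p)
    else:
        spikes = (rng.random(p.shape) < p).astype(float)
    return p, spikes


def advance_timestep(
    state: NetworkState,
    input_spikes: np.ndarray,
    params: NetworkParams,
    noise_e: np.ndarray | float = 0.0,
    noise_i: np.ndarray | float = 0.0,
) -> NetworkState:
    """One integrate-and-fire step (in place): leak, synaptic drive, refractory
    clamp, threshold/reset, then trace decay+increment.  Spike flags produced
    here take effect on the next step.  STDP is applied separately."""
    p = params
    state.v_e = state.v_e * p.leak + state.w_input_e @ input_spikes \
        + state.w_ee @ state.f_e - state.w_ie @ state.f_i + p.alpha * noise_e
    state.v_i = state.v_i * p.leak + state.w_ei @ state.f_e + p.alpha * noise_i
    if np.isnan(state.v_e).any() or np.isnan(state.v_i).any():
        raise FloatingPointError("NaN voltage encountered")
    # absolute refractory period: voltage held at 0
    state.v_e[state.ref_e > 0] = 0.0
    state.v_i[state.ref_i > 0] = 0.0
    state.ref_e = np.maximum(state.ref_e - 1, 0)
    state.ref_i = np.maximum(state.ref_i - 1, 0)
    spk_e = state.v_e > p.t_if
    spk_i = state.v_i > p.t_if
    state.v_e[spk_e] = 0.0
    state.v_i[spk_i] = 0.0
    state.ref_e[spk_e] = p.refractory_steps
    state.ref_i[spk_i] = p.refractory_steps
    # traces track the spiking history of the flags active at this step
    inc_e = (1.0 - state.f_e) if p.trace_on_nonspike else state.f_e
    inc_i = (1.0 - state.f_i) if p.trace_on_nonspike else state.f_i
    state.tr_e = state.tr_e * p.leak + inc_e
    state.tr_i = state.tr_i * p.leak + inc_i
    state._next_f_e = spk_e.astype(float)  # staged; committed by commit_spikes()
    state._next_f_i = spk_i.astype(float)
    return state


def commit_spikes(state: NetworkState) -> None:
    """Promote the spikes staged by `advance_timestep` to the next step's flags."""
    state.f_e = state._next_f_e
    state.f_i = state._next_f_i


def stdp_update(
    state: NetworkState,
    params: NetworkParams,
    enabled: tuple[str, ...] = ALL_PATHWAYS,
) -> NetworkState:
    """Apply the three pair-based STDP rules (post index i, pre index j):

      dW_EE[i,j] = eta * (fE_i * vE_j - fE_j * vE_i)
      dW_EI[i,j] = eta * (fI_i * vE_j - fE_j * vI_i)
      dW_IE[i,j] = eta * (fE_i * vI_j + fI_j * vE_i - ie_bias)   (default)
      dW_IE[i,j] = eta * (fE_i * vI_j - fI_j * vE_i - ie_bias)   (ie_symmetric=False)

    The default inhibitory rule potentiates whenever pre- and postsynaptic
    spikes occur close in time in either order, with a constant decay -- the
    standard homeostatic inhibitory-STDP form.  It drives the inhibitory
    weights toward an excitation/inhibition balance with a low target rate,
    which is what lets position-specific firing emerge; the fully
    antisymmetric variant (``ie_symmetric=False``) provides no such balance
    and leaves the network in a saturated, untuned state.

    Disabled pathways are frozen.  Weights are clamped to [0, w_max] and the
    E-E diagonal is kept at zero.
    """
    p = params
    fe, fi, ve, vi = state.f_e, state.f_i, state.tr_e, state.tr_i
    if "EE" in enabled:
        state.w_ee += state.mask_ee * p.eta * (np.outer(fe, ve) - np.outer(ve, fe))
        np.clip(state.w_ee, 0.0, p.w_max, out=state.w_ee)
        np.fill_diagonal(state.w_ee, 0.0)
    if "EI" in enabled:
        state.w_ei += state.mask_ei * p.eta * (np.outer(fi, ve) - np.outer(vi, fe))
        np.clip(state.w_ei, 0.0, p.w_max, out=state.w_ei)
    if "IE" in enabled:
        sgn = 1.0 if p.ie_symmetric else -1.0
        state.w_ie += state.mask_ie * p.eta * (np.outer(fe, vi) + sgn * np.outer(ve, fi)
                                               - p.ie_bias)
        np.clip(state.w_ie, 0.0, p.w_max, out=state.w_ie)
    return state


def pink_noise(rng: np.random.Generator, n_series: int, n_steps: int) -> np.ndarray:
    """Unit-variance 1/f (pink) noise, one independent series per row.

    Spectral synthesis: white Gaussian spectrum scaled by 1/sqrt(f), zero DC.
    """
    white = rng.standard_normal((n_series, n_steps))
    spec = np.fft.rfft(white, axis=1)
    f = np.arange(spec.shape[1], dtype=float)
    f[0] = 1.0
    spec /= np.sqrt(f)
    spec[:, 0] = 0.0
    out = np.fft.irfft(spec, n=n_steps, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# ---------------------------------------------------------------------------
# fused numba kernel (one lap per call)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_lap(
    x_steps, centers_flat, centers_off,
    w_in, w_ee, w_ei, w_ie, mask_ee, mask_ei, mask_ie,
    v_e, v_i, f_e, f_i, tr_e, tr_i, ref_e, ref_i,
    u_in, noise_in, noise_e, noise_i,
    leak, alpha, dt, r_pf, sigma2, t_if, ref_steps, eta, w_max, ie_bias, ie_sign,
    plastic_ee, plastic_ei, plastic_ie, trace_on_nonspike,
    rec_e, rec_i,
):
    n_steps = x_steps.shape[0]
    n_in = centers_off.shape[0] - 1
    n_e = v_e.shape[0]
    n_i = v_i.shape[0]
    spk_in = np.empty(n_in, np.int64)
    spk_e_idx = np.empty(n_e, np.int64)
    spk_i_idx = np.empty(n_i, np.int64)
    half = TRACK_LENGTH / 2.0
    for t in range(n_steps):
        x = x_steps[t]
        # --- input layer ---
        n_spk_in = 0
        for i in range(n_in):
            ti = 0.0
            for k in range(centers_off[i], centers_off[i + 1]):
                d = abs(x - centers_flat[k])
                if d > half:
                    d = TRACK_LENGTH - d
                ti += math.exp(-d * d / sigma2)
            p = (ti + alpha * noise_in[t, i]) * dt * r_pf
            if p < 0.0:
                p = 0.0
            elif p > 1.0:
                p = 1.0
            if u_in[t, i] < p:
                spk_in[n_spk_in] = i
                n_spk_in += 1
        # --- voltages ---
        for i in range(n_e):
            v_e[i] = v_e[i] * leak + alpha * noise_e[t, i]
        for i in range(n_i):
            v_i[i] = v_i[i] * leak + alpha * noise_i[t, i]
        for s in range(n_spk_in):
            j = spk_in[s]
            for i in range(n_e):
                v_e[i] += w_in[i, j]
        for j in range(n_e):
            if f_e[j] > 0.0:
                for i in range(n_e):
                    v_e[i] += w_ee[i, j]
                for i in range(n_i):
                    v_i[i] += w_ei[i, j]
        for j in range(n_i):
            if f_i[j] > 0.0:
                for i in range(n_e):
                    v_e[i] -= w_ie[i, j]
        # --- refractory, threshold, reset ---
        for i in range(n_e):
            if ref_e[i] > 0:
                v_e[i] = 0.0
                ref_e[i] -= 1
            if v_e[i] > t_if:
                v_e[i] = 0.0
                ref_e[i] = ref_steps
                rec_e[t, i] = 1
        for i in range(n_i):
            if ref_i[i] > 0:
                v_i[i] = 0.0
                ref_i[i] -= 1
            if v_i[i] > t_if:
                v_i[i] = 0.0
                ref_i[i] = ref_steps
                rec_i[t, i] = 1
        # --- traces (driven by the flags active this step) ---
        for i in range(n_e):
            inc = (1.0 - f_e[i]) if trace_on_nonspike else f_e[i]
            tr_e[i] = tr_e[i] * leak + inc
        for i in range(n_i):
            inc = (1.0 - f_i[i]) if trace_on_nonspike else f_i[i]
            tr_i[i] = tr_i[i] * leak + inc
        # --- STDP (sparse in spikes; single clamp per touched entry,
        #     matching stdp_update) ---
        n_spk_e = 0
        for i in range(n_e):
            if f_e[i] > 0.0:
                spk_e_idx[n_spk_e] = i
                n_spk_e += 1
        n_spk_i = 0
        for i in range(n_i):
            if f_i[i] > 0.0:
                spk_i_idx[n_spk_i] = i
                n_spk_i += 1
        if plastic_ee:
            for s in range(n_spk_e):
                i = spk_e_idx[s]
                for j in range(n_e):
                    if mask_ee[i, j]:
                        w = w_ee[i, j] + eta * (tr_e[j] - f_e[j] * tr_e[i])
                        w_ee[i, j] = w_max if w > w_max else (0.0 if w < 0.0 else w)
                w_ee[i, i] = 0.0
            for s in range(n_spk_e):
                j = spk_e_idx[s]
                for i in range(n_e):
                    if f_e[i] == 0.0 and mask_ee[i, j]:
                        w = w_ee[i, j] - eta * tr_e[i]
                        w_ee[i, j] = w_max if w > w_max else (0.0 if w < 0.0 else w)
        if plastic_ei:
            for s in range(n_spk_i):
                i = spk_i_idx[s]
                for j in range(n_e):
                    if mask_ei[i, j]:
                        w = w_ei[i, j] + eta * (tr_e[j] - f_e[j] * tr_i[i])
                        w_ei[i, j] = w_max if w > w_max else (0.0 if w < 0.0 else w)
            for s in range(n_spk_e):
                j = spk_e_idx[s]
                for i in range(n_i):
                    if f_i[i] == 0.0 and mask_ei[i, j]:
                        w = w_ei[i, j] - eta * tr_i[i]
                        w_ei[i, j] = w_max if w > w_max else (0.0 if w < 0.0 else w)
        if plastic_ie:
            bias = eta * ie_bias
            for i in range(n_e):
                fe_i = f_e[i]
                for j in range(n_i):
                    if mask_ie[i, j]:
                        w = w_ie[i, j] + eta * (fe_i * tr_i[j] + ie_sign * f_i[j] * tr_e[i]) - bias
                        w_ie[i, j] = w_max if w > w_max else (0.0 if w < 0.0 else w)
        # --- promote spikes to next-step flags ---
        for i in range(n_e):
            f_e[i] = rec_e[t, i]
        for i in range(n_i):
            f_i[i] = rec_i[t, i]


def run_laps(
    state: NetworkState,
    tuning: InputTuning,
    n_laps: int,
    params: NetworkParams,
    seed: int | np.random.Generator,
    plasticity: tuple[str, ...] = ALL_PATHWAYS,
    record: bool = True,
) -> tuple[NetworkState, SimulationRecord | None]:
    """Run constant-velocity laps around the ring (in place on ``state``).

    Noise and input spikes are drawn from ``seed``; with ``record`` the E and I
    spike rasters, position and lap index per step are returned.
    """
    if n_laps < 0:
        raise ValueError("n_laps must be >= 0")
    if n_laps == 0:
        return state, (SimulationRecord(
            np.zeros((0, params.n_excit), np.uint8), np.zeros((0, params.n_inhib), np.uint8),
            np.zeros(0), np.zeros(0, np.int64)) if record else None)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spl = params.steps_per_lap
    x_lap = (np.arange(spl) / spl) * TRACK_LENGTH
    centers_flat, centers_off = tuning.flat()
    total = n_laps * spl
    rec_e_all = np.zeros((total, params.n_excit), np.uint8) if record else None
    rec_i_all = np.zeros((total, params.n_inhib), np.uint8) if record else None
    rec_e = np.zeros((spl, params.n_excit), np.uint8)
    rec_i = np.zeros((spl, params.n_inhib), np.uint8)
    for lap in range(n_laps):
        u_in = rng.random((spl, params.n_input))
        noise_in = pink_noise(rng, params.n_input, spl).T.copy()
        noise_e = pink_noise(rng, params.n_excit, spl).T.copy()
        noise_i = pink_noise(rng, params.n_inhib, spl).T.copy()
        rec_e[:] = 0
        rec_i[:] = 0
        _run_lap(
            x_lap, centers_flat, centers_off,
            state.w_input_e, state.w_ee, state.w_ei, state.w_ie,
            state.mask_ee, state.mask_ei, state.mask_ie,
            state.v_e, state.v_i, state.f_e, state.f_i,
            state.tr_e, state.tr_i, state.ref_e, state.ref_i,
            u_in, noise_in, noise_e, noise_i,
            params.leak, params.alpha, params.dt, params.r_pf, params.sigma2,
            params.t_if, params.refractory_steps, params.eta, params.w_max,
            params.ie_bias, 1.0 if params.ie_symmetric else -1.0,
            "EE" in plasticity, "EI" in plasticity, "IE" in plasticity,
            params.trace_on_nonspike,
            rec_e, rec_i,
        )
        if record:
            rec_e_all[lap * spl:(lap + 1) * spl] = rec_e
            rec_i_all[lap * spl:(lap + 1) * spl] = rec_i
    if not record:
        return state, None
    x_all = np.tile(x_lap, n_laps)
    lap_idx = np.repeat(np.arange(n_laps), spl)
    return state, SimulationRecord(rec_e_all, rec_i_all, x_all, lap_idx)


# ---------------------------------------------------------------------------
# single-track metrics
# ---------------------------------------------------------------------------

def rate_maps_from_record(
    record: SimulationRecord, params: NetworkParams, laps: slice | np.ndarray | None = None
) -> np.ndarray:
    """Per-E-neuron mean activity over the discrete track locations (n_E, n_bins)."""
    sel = np.ones(len(record.x), bool)
    if laps is not None:
        lap_ids = np.unique(record.lap)[laps] if isinstance(laps, slice) else np.asarray(laps)
        sel = np.isin(record.lap, lap_ids)
    x = record.x[sel]
    spikes = record.spikes_e[sel]
    bins = np.minimum((x / TRACK_LENGTH * params.n_track_bins).astype(int), params.n_track_bins - 1)
    n_bins = params.n_track_bins
    counts = np.zeros(n_bins)
    maps = np.zeros((spikes.shape[1], n_bins))
    for b in range(n_bins):
        in_bin = bins == b
        counts[b] = in_bin.sum()
        if counts[b]:
            maps[:, b] = spikes[in_bin].sum(axis=0) / (counts[b] * params.dt)
    return maps


def spatial_similarity_metrics(rate_map: np.ndarray) -> tuple[float, float]:
    """(nearest-neighbor, halfway) similarity of a circular rate map.

    S = 1 - (a_max - a_ctrl)/(a_max + a_ctrl); control is the mean of the two
    circular neighbors of the peak bin (nearest-neighbor) or the circularly
    opposite bin (halfway).  Undefined (NaN) for an all-zero map.
    """
    m = np.asarray(rate_map, float)
    if m.ndim != 1 or len(m) < 3:
        raise ValueError("rate map must be 1-D with at least 3 bins")
    if m.max() <= 0:
        return (np.nan, np.nan)
    k = int(np.argmax(m))
    n = len(m)
    a_max = m[k]
    nn_ctrl = 0.5 * (m[(k - 1) % n] + m[(k + 1) % n])
    half_ctrl = m[(k + n // 2) % n]

    def s(ctrl):
        return 1.0 - (a_max - ctrl) / (a_max + ctrl)

    return (float(s(nn_ctrl)), float(s(half_ctrl)))


def similarity_by_lap_block(
    record: SimulationRecord, params: NetworkParams, block: int = 10
) -> dict[str, np.ndarray]:
    """Population-mean similarity metrics per consecutive ``block``-lap window,
    each computed from only that window's activity."""
    n_laps = int(record.lap.max()) + 1
    starts = np.arange(0, n_laps - block + 1, block)
    nn, half = [], []
    for s in starts:
        maps = rate_maps_from_record(record, params, laps=np.arange(s, s + block))
        vals = np.array([spatial_similarity_metrics(m) for m in maps])
        nn.append(np.nanmean(vals[:, 0]))
        half.append(np.nanmean(vals[:, 1]))
    return {
        "lap_end": starts + block,
        "nearest_neighbor": np.array(nn),
        "halfway": np.array(half),
    }


def plateau_onset(lap_end: np.ndarray, curves: np.ndarray) -> float:
    """Lap at which a tuning metric reaches its plateau.

    ``curves`` holds one metric trajectory per seed (n_seeds, n_blocks).
    A block counts as on-plateau once its seed-mean has reached the final
    block's level: it lies within the two blocks' summed across-seed standard
    errors of the final value, or beyond it in the direction of the overall
    trend (a slight overshoot of the final level still counts as having
    reached it).  Returns the end lap of the first such block.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    mean = curves.mean(axis=0)
    n = curves.shape[0]
    sem = curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    tol = sem + sem[-1]
    final = mean[-1]
    if mean[0] >= final:  # metric decreases as tuning sharpens
        ok = mean <= final + tol
    else:
        ok = mean >= final - tol
    return float(lap_end[np.argmax(ok)])


def place_field_emergence(
    params: NetworkParams,
    n_seeds: int = 10,
    n_laps: int = 100,
    block: int = 10,
    base_seed: int = 0,
    plasticity: tuple[str, ...] = ALL_PATHWAYS,
) -> dict:
    """Run ``n_seeds`` independent networks for ``n_laps`` laps and measure the
    emergence of location-specific firing.

    Returns the per-seed similarity-metric trajectories (one value per
    ``block``-lap window, each computed from only that window's activity) and
    the plateau-onset lap: the first block at which both metrics are
    indistinguishable from their final values (see `plateau_onset`).
    """
    nn, hf = [], []
    lap_end = None
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        tuning = sample_input_tuning(params, rng)
        state = initialize_network(params, rng)
        state, rec = run_laps(state, tuning, n_laps, params, rng, plasticity=plasticity)
        res = similarity_by_lap_block(rec, params, block=block)
        lap_end = res["lap_end"]
        nn.append(res["nearest_neighbor"])
        hf.append(res["halfway"])
    nn, hf = np.array(nn), np.array(hf)
    onset = max(plateau_onset(lap_end, nn), plateau_onset(lap_end, hf))
    return {
        "lap_end": lap_end,
        "nearest_neighbor": nn,
        "halfway": hf,
        "plateau_lap": onset,
    }


# ---------------------------------------------------------------------------
# two-track remapping experiment
# ---------------------------------------------------------------------------

def _binned_activity(record, params, laps):
    """E spikes averaged in dt_kendall bins over the selected laps (n_E, n_bins)."""
    sel = np.isin(record.lap, laps)
    spikes = record.spikes_e[sel].astype(float)
    steps_per_bin = max(1, int(params.dt_kendall / params.dt))
    n_bins = spikes.shape[0] // steps_per_bin
    spikes = spikes[: n_bins * steps_per_bin]
    return spikes.reshape(n_bins, steps_per_bin, -1).mean(axis=1).T


def _map_correlation(maps_a, maps_b):
    rs = []
    for a, b in zip(maps_a, maps_b):
        if a.std() > 0 and b.std() > 0:
            rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(rs)) if rs else np.nan


def two_track_experiment(
    params: NetworkParams,
    condition: str,
    seed: int,
    plasticity: tuple[str, ...] = ALL_PATHWAYS,
    train_plasticity: tuple[str, ...] = ALL_PATHWAYS,
    n_train_laps: int = 30,
    n_test_laps: int = 30,
) -> dict[str, float]:
    """Train on track A, then re-expose to A ('A_then_Aprime') or to a novel
    track B ('A_then_B'); tracks differ only in input tunings, with the
    input->E weights shared.

    Returns place-field similarity (mean per-neuron Pearson r between 10-bin
    rate maps of the last 50% of laps of each exposure) and cofiring
    similarity (Pearson r between the E-E Kendall tau vectors computed on
    dt_kendall-binned activity of the same laps).
    """
    from .coactivity import kendall_tau_matrix

    if condition not in ("A_then_Aprime", "A_then_B"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    tuning_a = sample_input_tuning(params, rng)
    tuning_b = sample_input_tuning(params, rng) if condition == "A_then_B" else tuning_a
    state = initialize_network(params, rng)
    state, rec_train = run_laps(state, tuning_a, n_train_laps, params, rng,
                                plasticity=train_plasticity)
    state, rec_test = run_laps(state, tuning_b, n_test_laps, params, rng,
                               plasticity=plasticity)
    last_train = np.arange(n_train_laps - n_test_laps // 2, n_train_laps)
    last_test = np.arange(n_test_laps - n_test_laps // 2, n_test_laps)
    maps_a = rate_maps_from_record(rec_train, params, laps=last_train)
    maps_2 = rate_maps_from_record(rec_test, params, laps=last_test)
    pf_similarity = _map_correlation(maps_a, maps_2)
    tau_a = kendall_tau_matrix(_binned_activity(rec_train, params, last_train))
    tau_2 = kendall_tau_matrix(_binned_activity(rec_test, params, last_test))
    iu = np.triu_indices(params.n_excit, 1)
    a, b = tau_a[iu], tau_2[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    cofiring_similarity = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 2 else np.nan
    return {"pf_similarity": pf_similarity, "cofiring_similarity": cofiring_similarity}
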