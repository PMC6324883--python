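"""Synthetic patch-clamp traces for cross-linker trapping experiments.

The generator produces current traces with the statistical and kinetic
structure the downstream analysis assumes, so that every stage of the
pipeline is testable without a recording:

* a gating receptor population (resting / active / desensitized) driven by
  piecewise-constant solution exchange protocols;
* pseudo-first-order covalent modification of engineered cysteines by an MTS
  reagent, at rate ``k_on * [MTS] * accessibility(state, linker)``;
* DTT-driven reversal of trapping whose rate falls steeply with linker span;
* Gaussian recording noise and optional linear run-down.

Receptor states are tracked as the product of a gating state and a
modification flag (free / trapped), a six-state linear Markov population.
In ``ode`` mode the occupancies follow the exact matrix-exponential solution
segment by segment; in ``stochastic`` mode a finite population of N
receptors is stepped with per-sample multinomial transitions, which is the
exact population chain at the sampling resolution and converges to the ODE
mean at large N.

The accessibility bridge from linker span to trapping rate is a window
model: accessibility is the probability that the (state-dependent,
Gaussian-distributed) SG-SG separation lies within the reactive window
[3 A, span].  This is a stand-in for unknown state-resolved accessibilities;
see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import norm

from .linkers import CATALOG, CrossLinker, get_linker

STATES = ("resting", "active", "desensitized")
N_GATING = len(STATES)
N_STATES = 2 * N_GATING  # (free, trapped) x gating


# -- solutions and protocols -----------------------------------------------


@dataclass(frozen=True)
class Solution:
    """Contents of one barrel of the perfusion system.

    Concentrations: glutamate and kainate and DTT in mM, CTZ in uM, the MTS
    reagent in molar.  The identity of the MTS reagent is supplied to
    :func:`simulate`; solutions carry only its concentration.
    """

    glutamate: float = 0.0
    kainate: float = 0.0
    mts: float = 0.0
    dtt: float = 0.0
    ctz: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for f in ("glutamate", "kainate", "mts", "dtt", "ctz"):
            if getattr(self, f) < 0:
                raise ValueError(f"negative concentration for {f}")

    @property
    def agonist(self) -> bool:
        return self.glutamate > 0 or self.kainate > 0


@dataclass(frozen=True)
class Episode:
    """One acquisition episode: piecewise-constant solution timeline."""

    duration: float  # s
    segments: tuple  # ((start_s, Solution), ...) with starts increasing from 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")
        if not self.segments or self.segments[0][0] != 0.0:
            raise ValueError("segments must start at t=0")
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if starts[-1] >= self.duration:
            raise ValueError("segment beyond episode duration")

    def bounds(self) -> list[tuple[float, float, Solution]]:
        out = []
        for k, (start, sol) in enumerate(self.segments):
            end = (self.segments[k + 1][0] if k + 1 < len(self.segments)
                   else self.duration)
            out.append((start, end, sol))
        return out


@dataclass(frozen=True)
class Protocol:
    episodes: tuple  # of Episode
    sample_rate: float = 20000.0  # Hz
    holding_potential: float = -40.0  # mV
    kind: str = ""

    def __post_init__(self) -> None:
        if not self.episodes:
            raise ValueError("protocol needs at least one episode")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def response_window(self, episode_index: int) -> tuple[float, float]:
        """(start, end) of the first agonist-containing segment."""
        for start, end, sol in self.episodes[episode_index].bounds():
            if sol.agonist:
                return (start, end)
        raise ValueError(f"episode {episode_index} has no agonist segment")

    def baseline_window(self, episode_index: int,
                        width: float = 0.05) -> tuple[float, float]:
        start, _ = self.response_window(episode_index)
        return (max(0.0, start - width), start)


RINGER = Solution(label="Ringer")


def _control_episode(duration: float, pulse_start: float, pulse_s: float,
                     pulse_sol: Solution, rest_sol: Solution) -> Episode:
    segs = [(0.0, rest_sol), (pulse_start, pulse_sol)]
    end = pulse_start + pulse_s
    if end < duration:
        segs.append((end, rest_sol))
    return Episode(duration, tuple(segs))


def build_protocol(kind: str, **params) -> Protocol:
    """Construct one of the standard solution-exchange protocols.

    Kinds
    -----
    ``trap_1min``
        Four 200-ms control glutamate jumps (in DTT), one long trapping pulse
        in glutamate + MTS (default 60 s), then >=10 post-trap control pulses
        at 1 Hz.
    ``pulse_train_6p7Hz``
        50-ms pulses of glutamate + MTS at 6.7 Hz separated by ~100-ms
        washes in Ringer.
    ``recovery_series``
        100-ms glutamate pulses at 1 Hz in reducing (DTT) conditions.
    ``ka_glu``
        A kainate control pulse followed by a glutamate control pulse.
    ``ctz_washout``
        Trap under CTZ + MTS, wash out CTZ, then re-trap in glutamate + MTS;
        the protection-control scenario.
    """
    glu = params.pop("glutamate", 10.0)          # mM
    dtt = params.pop("dtt", 1.0)                 # mM
    ctz = params.pop("ctz", 0.0)                 # uM
    conc = params.pop("conc", 1e-6)              # M, MTS
    sample_rate = params.pop("sample_rate", 20000.0)

    wash = Solution(dtt=dtt, ctz=ctz, label="wash")
    control = Solution(glutamate=glu, dtt=dtt, ctz=ctz, label="Glu")

    if kind == "trap_1min":
        n_pre = params.pop("n_pre", 4)
        n_post = params.pop("n_post", 10)
        trap_s = params.pop("trap_s", 60.0)
        if n_pre <= 0 or n_post <= 0 or trap_s <= 0:
            raise ValueError("counts and trap duration must be positive")
        trap = Solution(glutamate=glu, mts=conc, ctz=ctz, label="Glu+MTS")
        pre = [_control_episode(0.5, 0.1, 0.2, control, wash)
               for _ in range(n_pre)]
        trap_ep = Episode(trap_s + 0.1, ((0.0, trap), (trap_s, wash)))
        post = [_control_episode(1.0, 0.1, 0.2, control, wash)
                for _ in range(n_post)]
        eps = pre + [trap_ep] + post
    elif kind in ("pulse_train_6p7Hz", "pulse_train"):
        rate = params.pop("rate_hz", 6.7)
        pulse_s = params.pop("pulse_s", 0.05)
        n_pulses = params.pop("n_pulses", 40)
        if n_pulses <= 0 or rate <= 0 or pulse_s <= 0:
            raise ValueError("counts, rate and pulse duration must be positive")
        period = 1.0 / rate
        if period <= pulse_s:
            raise ValueError("pulse longer than train period")
        pulse = Solution(glutamate=glu, mts=conc, ctz=ctz, label="Glu+MTS")
        eps = [Episode(period, ((0.0, pulse), (pulse_s, RINGER)))
               for _ in range(n_pulses)]
    elif kind == "recovery_series":
        n_pulses = params.pop("n_pulses", 60)
        rate = params.pop("rate_hz", 1.0)
        pulse_s = params.pop("pulse_s", 0.1)
        if n_pulses <= 0:
            raise ValueError("n_pulses must be positive")
        eps = [_control_episode(1.0 / rate, 0.1, pulse_s, control, wash)
               for _ in range(n_pulses)]
    elif kind == "ka_glu":
        ka = params.pop("kainate", 1.0)
        ka_sol = Solution(kainate=ka, dtt=dtt, ctz=ctz, label="KA")
        eps = [_control_episode(0.5, 0.1, 0.2, ka_sol, wash),
               _control_episode(0.5, 0.1, 0.2, control, wash)]
    elif kind == "ctz_washout":
        trap_s = params.pop("trap_s", 60.0)
        washout_s = params.pop("washout_s", 30.0)
        n_post = params.pop("n_post", 4)
        if n_post <= 0:
            raise ValueError("n_post must be positive")
        ctz_on = params.pop("ctz_um", 100.0)
        wash_c = Solution(dtt=dtt, ctz=ctz_on, label="wash+CTZ")
        ctrl_c = Solution(glutamate=glu, dtt=dtt, ctz=ctz_on, label="Glu+CTZ")
        trap1 = Solution(glutamate=glu, mts=conc, ctz=ctz_on, label="Glu+MTS+CTZ")
        trap2 = Solution(glutamate=glu, mts=conc, label="Glu+MTS")
        eps = [_control_episode(0.5, 0.1, 0.2, ctrl_c, wash_c),
               Episode(trap_s, ((0.0, trap1),)),
               Episode(washout_s, ((0.0, RINGER),)),
               Episode(trap_s, ((0.0, trap2),))]
        eps += [_control_episode(1.0, 0.1, 0.2, control, wash)
                for _ in range(n_post)]
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    if params:
        raise TypeError(f"unused protocol parameters: {sorted(params)}")
    return Protocol(tuple(eps), sample_rate=sample_rate, kind=kind)


# -- kinetic models --------------------------------------------------------


@dataclass(frozen=True)
class GatingModel:
    """Three-state gating population (resting / active / desensitized).

    Rates are per second.  In agonist, receptors activate (``k_act``),
    desensitize (``k_des``) and resensitize (``k_res``, which sets the
    equilibrium steady-state/peak ratio); on agonist removal they deactivate
    (``k_deact``, default tau ~1.7 ms as under CTZ) and recover from
    desensitization (``k_rec``).  CTZ in the solution zeroes ``k_des`` when
    ``ctz_blocks_desensitization``.  ``kainate_efficacy`` scales the open
    conductance under the partial agonist kainate.
    """

    k_act: float = 5000.0
    k_deact: float = 1.0 / 1.7e-3
    k_des: float = 180.0
    k_res: float = 65.2
    k_rec: float = 20.0
    ctz_blocks_desensitization: bool = True
    full_conductance: float = 1.0
    two_subunit_fraction: float = 0.4
    kainate_efficacy: float = 0.46

    def __post_init__(self) -> None:
        for f in ("k_act", "k_deact", "k_des", "k_res", "k_rec"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @classmethod
    def with_equilibrium_desensitization(cls, ss_active_fraction: float,
                                         **kw) -> "GatingModel":
        """Set k_res so the in-agonist active fraction equilibrates at the
        given value (e.g. 0.266 for strongly desensitizing receptors)."""
        k_des = kw.pop("k_des", cls.k_des)
        k_res = k_des * ss_active_fraction / (1.0 - ss_active_fraction)
        return cls(k_des=k_des, k_res=k_res, **kw)


def _as_accessibility(spec) -> Callable[[str, CrossLinker], float]:
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        const = float(spec)
        return lambda state, linker: const
    if isinstance(spec, Mapping):
        return lambda state, linker: float(spec[state])
    raise TypeError("accessibility must be callable, scalar, or state map")


def window_accessibility(state_distance: Mapping[str, tuple[float, float]],
                         min_span: float = 3.0):
    """Window accessibility model.

    ``state_distance`` maps each gating state to the (mean, sd) of the
    Gaussian SG-SG separation it samples; accessibility for a linker of span
    L is P(min_span <= d <= L).  Encodes "a linker can only react when the
    two thiols come within its reach" as a state-dependent rate factor.
    """
    def acc(state: str, linker: CrossLinker) -> float:
        mu, sd = state_distance[state]
        lo = norm.cdf((min_span - mu) / sd)
        hi = norm.cdf((linker.span - mu) / sd)
        return float(max(0.0, hi - lo))
    return acc


# Default state-dependent SG-SG separation distributions (mean, sd in A)
# for the inter-dimer V666C geometry: compact at rest, dilated when active,
# widest when desensitized.
DEFAULT_STATE_DISTANCE = {"resting": (10.0, 3.0),
                          "active": (15.0, 3.0),
                          "desensitized": (14.0, 5.0)}

# Fractional current of a trapped receptor, per linker.  Mid-length rulers
# clamp the inter-dimer geometry hard (near-zero residual current); the very
# short disulfide bridge barely perturbs gating and the longest ruler leaves
# room to gate.  The monofunctional control leaves function intact.
DEFAULT_TRAP_EFFICACY = {"disulfide": 0.85, "M1M": 0.05, "M3M": 0.03,
                         "bMTSp": 0.05, "M6M": 0.05, "M8M": 0.08,
                         "M10M": 0.25, "MTSEA": 1.0}

# DTT reversal rates (1/s): fast for the disulfide, tau ~30 s for M1M,
# ~10 min for M3M, effectively irreversible for spans >= 13 A.
DEFAULT_REVERSAL_RATE = {"disulfide": 1.0 / 3.0, "M1M": 1.0 / 30.0,
                         "M3M": 1.0 / 600.0, "bMTSp": 0.0, "M6M": 0.0,
                         "M8M": 0.0, "M10M": 0.0, "MTSEA": 1.0 / 30.0}


def default_reversal_rate(linker: CrossLinker) -> float:
    if linker.name in DEFAULT_REVERSAL_RATE:
        return DEFAULT_REVERSAL_RATE[linker.name]
    # log-linear interpolation on span over the calibrated points, zero
    # beyond the last reversible span
    pts = [(2.0, 1.0 / 3.0), (7.0, 1.0 / 30.0), (9.0, 1.0 / 600.0)]
    if linker.span <= pts[0][0]:
        return pts[0][1]
    if linker.span >= 13.0:
        return 0.0
    spans = np.array([p[0] for p in pts] + [13.0])
    logk = np.log([p[1] for p in pts] + [1e-5])
    return float(np.exp(np.interp(linker.span, spans, logk)))


@dataclass(frozen=True)
class ModificationModel:
    """State-dependent covalent modification and its reversal.

    ``k_on`` is the bimolecular modification rate (M^-1 s^-1); the trapping
    rate in state s is ``k_on * [MTS] * accessibility(s, linker)``.
    ``accessibility`` may be a callable ``(state, linker) -> [0, 1]``, a
    scalar, or a per-state map; the default is the window model over
    :data:`DEFAULT_STATE_DISTANCE`.  ``trap_efficacy`` maps linker name to
    the fractional current of a trapped receptor.  ``k_rev`` maps the linker
    to the DTT reversal rate (1/s) and falls steeply with span.
    """

    k_on: float = 1.0e5
    accessibility: object = None
    trap_efficacy: Mapping[str, float] | float = None
    k_rev: Callable[[CrossLinker], float] | float = None

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")

    def accessibility_fn(self) -> Callable[[str, CrossLinker], float]:
        spec = self.accessibility
        if spec is None:
            return window_accessibility(DEFAULT_STATE_DISTANCE)
        return _as_accessibility(spec)

    def efficacy(self, linker: CrossLinker) -> float:
        te = self.trap_efficacy
        if te is None:
            e = DEFAULT_TRAP_EFFICACY.get(linker.name, 0.0)
        elif isinstance(te, Mapping):
            e = te.get(linker.name, 0.0)
        else:
            e = float(te)
        if not 0.0 <= e <= 1.0:
            raise ValueError("trap_efficacy must lie in [0, 1]")
        return e

    def reversal_rate(self, linker: CrossLinker) -> float:
        kr = self.k_rev
        if kr is None:
            return default_reversal_rate(linker)
        if callable(kr):
            return float(kr(linker))
        return float(kr)


# -- rate matrix -----------------------------------------------------------


def rate_matrix(gating: GatingModel, mod: ModificationModel,
                solution: Solution, linker: CrossLinker) -> np.ndarray:
    """Generator Q (column convention, dp/dt = Q p) of the 6-state chain.

    State order: (resting, active, desensitized) free, then trapped.
    """
    acc = mod.accessibility_fn()
    Q = np.zeros((N_STATES, N_STATES))

    def add(i: int, j: int, rate: float) -> None:
        # transition j -> i
        if rate > 0:
            Q[i, j] += rate
            Q[j, j] -= rate

    k_des = gating.k_des
    if solution.ctz > 0 and gating.ctz_blocks_desensitization:
        k_des = 0.0
    for block in (0, N_GATING):  # free, trapped share gating rates
        R, A, D = block, block + 1, block + 2
        if solution.agonist:
            add(A, R, gating.k_act)
            add(D, A, k_des)
            add(A, D, gating.k_res)
        else:
            add(R, A, gating.k_deact)
            add(R, D, gating.k_rec)
    if solution.mts > 0:
        for s, state in enumerate(STATES):
            add(s + N_GATING, s, mod.k_on * solution.mts * acc(state, linker))
    if solution.dtt > 0:
        k_rev = mod.reversal_rate(linker)
        for s in range(N_GATING):
            add(s, s + N_GATING, k_rev)
    return Q


def conductance_weights(gating: GatingModel, mod: ModificationModel,
                        solution: Solution, linker: CrossLinker) -> np.ndarray:
    """Per-state open-conductance weight of the 6-state vector.

    The active state conducts whenever occupied (including the deactivation
    tail after agonist removal); occupancy driven by the partial agonist
    kainate conducts at ``kainate_efficacy`` of a glutamate-driven opening.
    """
    eff_agonist = 1.0
    if solution.kainate > 0 and solution.glutamate == 0:
        eff_agonist = gating.kainate_efficacy
    w = np.zeros(N_STATES)
    w[1] = gating.full_conductance * eff_agonist           # active, free
    w[1 + N_GATING] = w[1] * mod.efficacy(linker)          # active, trapped
    return w


# -- traces ----------------------------------------------------------------


@dataclass
class Trace:
    """One simulated episode: time (s, within episode), current (pA)."""

    time: np.ndarray
    current: np.ndarray
    episode: int
    start_time: float
    protocol: Protocol
    seed: int | None = None
    occupancy: np.ndarray | None = None  # (n, 6) state fractions, ode mode

    @property
    def sample_rate(self) -> float:
        return self.protocol.sample_rate


def _segment_times(t0: float, t1: float, fs: float, eps_start: float):
    i0 = int(np.ceil((eps_start + t0) * fs - 1e-9))
    i1 = int(np.ceil((eps_start + t1) * fs - 1e-9))
    return i0, i1


def _propagate_linear(Q: np.ndarray, p0: np.ndarray, times: np.ndarray,
                      chunk: int = 200_000):
    """p(t) = expm(Q t) p0 evaluated at many times via eigendecomposition."""
    w, V = np.linalg.eig(Q)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vi = None
    if Vi is not None and np.linalg.cond(V) < 1e10:
        c = Vi @ p0.astype(complex)
        out = np.empty((len(times), len(p0)))
        for lo in range(0, len(times), chunk):
            tt = times[lo:lo + chunk]
            out[lo:lo + len(tt)] = np.real(
                np.exp(np.outer(tt, w)) * c[None, :] @ V.T)
        return out
    # defective generator: step with matrix exponentials (rare path)
    out = np.empty((len(times), len(p0)))
    prev_t, p = 0.0, p0.copy()
    for k, t in enumerate(times):
        p = expm(Q * (t - prev_t)) @ p
        prev_t = t
        out[k] = p
    return out


def simulate(gating: GatingModel, mod: ModificationModel, protocol: Protocol,
             linker: CrossLinker | str, noise_sd: float = 0.0,
             rundown_per_min: float = 0.0, seed: int | None = None,
             mode: str = "ode", n_receptors: int | None = None,
             amplitude_pa: float = 200.0,
             initial: np.ndarray | None = None) -> list[Trace]:
    """Simulate the protocol; returns one :class:`Trace` per episode.

    ``ode`` mode evolves state fractions deterministically (exact piecewise
    matrix-exponential solution; occupancies are attached to each trace).
    ``stochastic`` mode steps an N-receptor population with per-sample
    multinomial transitions and requires ``n_receptors``.

    ``amplitude_pa`` is the peak current of the fully active, unmodified
    population; currents are inward (negative) at the default -40 mV.
    """
    if isinstance(linker, str):
        linker = get_linker(linker)
    if mode not in ("ode", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic" and not n_receptors:
        raise ValueError("stochastic mode requires n_receptors")
    rng = np.random.default_rng(seed)
    fs = protocol.sample_rate

    if initial is None:
        p = np.zeros(N_STATES)
        p[0] = 1.0
    else:
        p = np.asarray(initial, float).copy()
    counts = None
    if mode == "stochastic":
        counts = rng.multinomial(n_receptors, p)

    traces: list[Trace] = []
    eps_start = 0.0
    for ei, episode in enumerate(protocol.episodes):
        n = int(round(episode.duration * fs))
        t_local = np.arange(n) / fs
        occ = np.empty((n, N_STATES))
        for t0, t1, sol in episode.bounds():
            Q = rate_matrix(gating, mod, sol, linker)
            sel = (t_local >= t0 - 1e-12) & (t_local < t1 - 1e-12)
            tt = t_local[sel] - t0
            if mode == "ode":
                if tt.size:
                    occ[sel] = _propagate_linear(Q, p, tt)
                p = _propagate_linear(Q, p, np.array([t1 - t0]))[0]
            else:
                T = expm(Q.T / fs)  # row-stochastic single-receptor kernel
                T = np.clip(T, 0.0, None)
                T /= T.sum(axis=1, keepdims=True)
                idx = np.flatnonzero(sel)
                # include the step carrying the state across the segment end
                n_steps = int(round((t1 - t0) * fs))
                step_of = {int(round((t_local[i] - t0) * fs)): i for i in idx}
                for s in range(n_steps):
                    if s in step_of:
                        occ[step_of[s]] = counts / n_receptors
                    new = np.zeros(N_STATES, dtype=np.int64)
                    for i in range(N_STATES):
                        if counts[i]:
                            new += rng.multinomial(counts[i], T[i])
                    counts = new
                p = counts / n_receptors

        # current assembly
        current = np.zeros(n)
        for t0, t1, sol in episode.bounds():
            sel = (t_local >= t0 - 1e-12) & (t_local < t1 - 1e-12)
            w = conductance_weights(gating, mod, sol, linker)
            current[sel] = -amplitude_pa * occ[sel] @ w
        if rundown_per_min:
            factor = np.clip(1.0 - rundown_per_min * (eps_start + t_local) / 60.0,
                             0.0, None)
            current *= factor
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=n)
        traces.append(Trace(t_local, current, ei, eps_start, protocol,
                            seed=seed, occupancy=occ if mode == "ode" else None))
        eps_start += episode.duration
    return traces


def traces_to_frame(traces: Sequence[Trace]):
    """Long-format DataFrame (time_s, current_pA, episode)."""
    import pandas as pd
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({"time_s": tr.time + tr.start_time,
                                    "current_pA": tr.current,
                                    "episode": tr.episode}))
    return pd.concat(frames, ignore_index=True)
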