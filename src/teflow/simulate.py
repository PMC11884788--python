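"""Langevin reaction-cascade simulator.

Generates synthetic paired single-cell trajectories with the
statistical structure the TE analysis assumes: an input E (stimulus
dose, switched on at t = 0 with optional receptor-desensitization
decay) drives a cause species S, which drives a result species R
through saturating first-order kinetics,

    dS/dt = k_es * E(t) * (1 - S) - d_s * S  [+ feedback]  + noise
    dR/dt = (k_sr * S + k_er * E(t)) * (1 - R) - d_r * R   + noise

with optional couplings: R -> S feedback (negative by default,
optionally routed through a hidden intermediate M for delay), an
E -> R bypass, or a common-input topology without the S -> R edge.
Activities live in [0, capacity]; noisy excursions are reflected at the
bounds.  The deterministic drift is advanced by classical 4th-order
Runge-Kutta over each integration step and the diffusion term is added
as a Gaussian increment of standard deviation sigma*sqrt(dt)
(Langevin / Euler-Maruyama treatment of the noise).

Cell-to-cell variability is lognormal (mean-preserving) on the rate
parameters and on the per-cell input amplitude.  Trajectories are
sampled on the 1-minute grid with 3 pre-stimulation frames, packaged as
:class:`~teflow.data.PairedDataset` (S = cause channel, R = result
channel), and are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import ConditionMeta, PairedDataset, TimeGrid, TraceMatrix
from .gaussian import TEQuery, cov_triplet, gaussian_te

__all__ = [
    "NetworkModel",
    "SimProtocol",
    "build_network",
    "simulate",
    "simulate_pooled",
    "ground_truth_te",
]

PRESETS = ("tandem", "feedback", "bypass", "common_input", "custom")

_SPECIES = ("E", "S", "R", "M")
_EDGE_PARAMS = {
    ("E", "S"): "k_es",
    ("S", "R"): "k_sr",
    ("E", "R"): "k_er",
    ("R", "S"): "k_rs",
    ("R", "M"): "k_rm",
    ("M", "S"): "k_ms",
}


@dataclass(frozen=True)
class NetworkModel:
    """Parameterized reaction cascade; rates in 1/min, activities in [0, capacity]."""

    k_es: float = 0.8   # E -> S activation gain
    k_sr: float = 2.0   # S -> R gain
    k_er: float = 0.0   # E -> R bypass gain
    k_rs: float = 0.0   # R -> S feedback gain (magnitude)
    k_rm: float = 0.0   # R -> M (hidden state) gain
    k_ms: float = 0.0   # M -> S delayed-feedback gain
    feedback_sign: int = -1
    d_s: float = 0.25
    d_r: float = 0.5
    d_m: float = 0.25
    sigma_s: float = 0.10
    sigma_r: float = 0.015
    sigma_m: float = 0.0
    cell_cv: float = 0.1     # lognormal CV on rate parameters, per cell
    input_cv: float = 0.08   # lognormal CV on the per-cell input amplitude
    input_K: float = 5.0     # dose (ng/ml) at half-maximal input
    input_decay: float = 0.03  # 1/min, receptor desensitization
    capacity: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k_es", "k_sr", "k_er", "k_rs", "k_rm", "k_ms",
            "d_s", "d_r", "d_m", "sigma_s", "sigma_r", "sigma_m",
            "cell_cv", "input_cv", "input_K", "input_decay",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capacity <= 0:
            raise ValueError("capacity must be > 0")
        if self.feedback_sign not in (-1, 1):
            raise ValueError("feedback_sign must be -1 or +1")

    @property
    def has_hidden(self) -> bool:
        return self.k_rm > 0 or self.k_ms > 0

    @property
    def edges(self) -> frozenset:
        """Active coupling edges, for adjacency checks."""
        return frozenset(e for e, p in _EDGE_PARAMS.items() if getattr(self, p) > 0)

    def input_level(self, dose: float) -> float:
        """Saturating dose -> input mapping, in input units."""
        if dose <= 0:
            return 0.0
        return dose / (dose + self.input_K)


@dataclass(frozen=True)
class SimProtocol:
    """Stimulation/sampling design: doses, cells per dose, timing, seed."""

    doses: tuple = (0.1, 1.0, 10.0, 100.0)
    n_cells: int = 300
    t_start: float = -3.0
    duration: float = 60.0
    dt_sample: float = 1.0
    dt: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0 or self.dt_sample <= 0:
            raise ValueError("time steps must be positive")
        ratio = self.dt_sample / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt must divide the sampling interval")
        if self.t_start >= 0:
            raise ValueError("t_start must be before stimulation (negative)")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.regular(self.t_start, self.duration, self.dt_sample)


def build_network(preset: str = "tandem", **params) -> NetworkModel:
    """Construct a validated preset network.

    ``tandem``: E->S->R only.  ``feedback``: tandem plus R->S (negative
    by default).  ``bypass``: tandem plus a direct E->R edge.
    ``common_input``: E->S and E->R with no S-R coupling.  ``custom``:
    explicit ``edges={('E','S'): gain, ...}`` over species E,S,R,M.
    Keyword overrides apply on top of the preset.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if preset == "custom":
        edges = params.pop("edges", None)
        if edges is None:
            raise ValueError("custom preset requires an edges mapping")
        gains = {}
        for (src, dst), gain in edges.items():
            if src not in _SPECIES or dst not in _SPECIES:
                raise ValueError(f"edge ({src}->{dst}) uses an undeclared species")
            if (src, dst) not in _EDGE_PARAMS:
                raise ValueError(f"unsupported edge ({src}->{dst})")
            if gain < 0:
                raise ValueError("edge gains must be >= 0")
            gains[_EDGE_PARAMS[(src, dst)]] = float(gain)
        base = {"k_es": 0.0, "k_sr": 0.0, "k_er": 0.0, "k_rs": 0.0, "k_rm": 0.0, "k_ms": 0.0}
        base.update(gains)
        base.update(params)
        return NetworkModel(**base)
    overrides = dict(params)
    if preset == "tandem":
        base = {}
    elif preset == "feedback":
        # the feedback loop needs a mid-range working point (stronger
        # drive against the negative feedback) and result-channel noise
        # to transmit backwards
        base = {"k_rs": 1.5, "k_es": 2.0, "sigma_s": 0.03, "sigma_r": 0.10}
    elif preset == "bypass":
        base = {"k_er": 1.5}
    else:  # common_input
        base = {"k_sr": 0.0, "k_er": 0.8}
    base.update(overrides)
    return NetworkModel(**base)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)


def _drift(model, S, R, M, E, p):
    fb_src = M if model.has_hidden else R
    k_fb = p["k_ms"] if model.has_hidden else p["k_rs"]
    if model.feedback_sign < 0:
        fb = -k_fb * fb_src * S
    else:
        fb = k_fb * fb_src * (model.capacity - S)
    dS = p["k_es"] * E * (model.capacity - S) - p["d_s"] * S + fb
    dR = (p["k_sr"] * S + p["k_er"] * E) * (model.capacity - R) - p["d_r"] * R
    dM = p["k_rm"] * R * (model.capacity - M) - p["d_m"] * M
    return dS, dR, dM


def _reflect(x, cap):
    x = np.where(x < 0, -x, x)
    x = np.where(x > cap, 2 * cap - x, x)
    return np.clip(x, 0, cap)


def _integrate(model: NetworkModel, dose: float, n_cells: int, protocol: SimProtocol, rng: np.random.Generator):
    """Vectorized RK4 + additive-noise integration for one dose group.

    Returns (S_samples, R_samples) of shape (n_cells, n_grid) on the
    sampling grid.  The pre- and post-stimulation segments are
    integrated separately so the input step at t = 0 falls exactly on a
    step boundary (drift order is preserved on each smooth segment).
    """
    cv = model.cell_cv
    p = {
        name: getattr(model, name) * _lognormal_factors(rng, cv, n_cells)
        for name in ("k_es", "k_sr", "k_er", "k_rs", "k_rm", "k_ms", "d_s", "d_r", "d_m")
    }
    u = model.input_level(dose) * _lognormal_factors(rng, model.input_cv, n_cells)
    grid = protocol.grid
    dt = protocol.dt
    sqdt = np.sqrt(dt)
    per_sample = int(round(protocol.dt_sample / dt))
    cap = model.capacity

    S = np.zeros(n_cells)
    R = np.zeros(n_cells)
    M = np.zeros(n_cells)
    out_S = np.empty((n_cells, len(grid)))
    out_R = np.empty((n_cells, len(grid)))
    out_S[:, 0] = S
    out_R[:, 0] = R

    noisy = (model.sigma_s, model.sigma_r, model.sigma_m)

    zero_u = np.zeros_like(u)

    def step(t, S, R, M, pre):
        # E(t) is evaluated with the field of the segment being
        # integrated: identically zero on pre-stimulation intervals,
        # decaying step on post-stimulation intervals (the stimulation
        # time 0 is a sample point, so every interval is one or the other)
        def E_at(tt):
            if pre:
                return zero_u
            return u * np.exp(-model.input_decay * max(tt, 0.0))

        k1 = _drift(model, S, R, M, E_at(t), p)
        k2 = _drift(model, S + 0.5 * dt * k1[0], R + 0.5 * dt * k1[1], M + 0.5 * dt * k1[2], E_at(t + 0.5 * dt), p)
        k3 = _drift(model, S + 0.5 * dt * k2[0], R + 0.5 * dt * k2[1], M + 0.5 * dt * k2[2], E_at(t + 0.5 * dt), p)
        k4 = _drift(model, S + dt * k3[0], R + dt * k3[1], M + dt * k3[2], E_at(t + dt), p)
        Sn = S + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        Rn = R + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        Mn = M + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not (np.all(np.isfinite(Sn)) and np.all(np.isfinite(Rn)) and np.all(np.isfinite(Mn))):
            raise RuntimeError(
                f"unstable integration at t={t:.2f} min (dose {dose}); "
                "reduce dt or the rate parameters"
            )
        if max(np.abs(Sn).max(), np.abs(Rn).max(), np.abs(Mn).max()) > 10 * cap:
            raise RuntimeError(
                f"trajectory escaped bounds at t={t:.2f} min (dose {dose}); "
                "reduce dt or the rate parameters"
            )
        if noisy[0] > 0:
            Sn = Sn + noisy[0] * sqdt * rng.standard_normal(n_cells)
        if noisy[1] > 0:
            Rn = Rn + noisy[1] * sqdt * rng.standard_normal(n_cells)
        if noisy[2] > 0:
            Mn = Mn + noisy[2] * sqdt * rng.standard_normal(n_cells)
        return _reflect(Sn, cap), _reflect(Rn, cap), _reflect(Mn, cap)

    for g in range(1, len(grid)):
        t = grid.times[g - 1]
        pre = grid.times[g] <= 0
        for _ in range(per_sample):
            S, R, M = step(t, S, R, M, pre)
            t += dt
        out_S[:, g] = S
        out_R[:, g] = R
    return out_S, out_R


def simulate(model: NetworkModel, protocol: SimProtocol, seed: int | None = None) -> list:
    """Simulate paired S/R trajectory datasets, one per dose.

    Fully reproducible from ``seed`` (falls back to ``protocol.seed``).
    """
    if seed is None:
        seed = protocol.seed
    ss = np.random.SeedSequence(seed)
    out = []
    for dose, child in zip(protocol.doses, ss.spawn(len(protocol.doses))):
        rng = np.random.default_rng(child)
        S, R = _integrate(model, dose, protocol.n_cells, protocol, rng)
        ids = tuple(f"c{k:05d}" for k in range(protocol.n_cells))
        grid = protocol.grid
        cond = ConditionMeta(egf_dose=dose)
        out.append(
            PairedDataset(
                TraceMatrix(S, grid, "S", ids),
                TraceMatrix(R, grid, "R", ids),
                cond,
            )
        )
    return out


def simulate_pooled(model: NetworkModel, protocol: SimProtocol, seed: int | None = None) -> PairedDataset:
    """Dose-mixed dataset (all doses row-stacked, provenance retained)."""
    from .data import concat_datasets

    return concat_datasets(simulate(model, protocol, seed))


def ground_truth_te(
    model: NetworkModel,
    query: TEQuery,
    n_mc: int = 100_000,
    dose: float | None = 10.0,
    protocol: SimProtocol | None = None,
    seed: int | None = 0,
    n_batches: int = 10,
):
    """Monte-Carlo reference value of the Gaussian-approximation TE.

    Simulates ``n_mc`` cells (single dose, or the protocol's dose mix if
    ``dose`` is None), evaluates the Gaussian TE per batch and returns
    ``(mean, standard_error)``.  Used as the oracle in pipeline-recovery
    tests, never as part of the estimator itself.
    """
    if n_batches < 2 or n_mc // n_batches < 100:
        raise ValueError("n_mc too small for the requested batching")
    proto = protocol or SimProtocol(duration=max(query.t, 1.0), n_cells=n_mc // n_batches)
    proto = replace(
        proto,
        n_cells=n_mc // n_batches,
        duration=max(query.t, proto.dt_sample),
        doses=proto.doses if dose is None else (dose,),
    )
    ss = np.random.SeedSequence(seed)
    vals = []
    for child in ss.spawn(n_batches):
        if dose is None:
            ds = simulate_pooled(model, proto, seed=child.generate_state(1)[0] >> 1)
        else:
            ds = simulate(model, proto, seed=child.generate_state(1)[0] >> 1)[0]
        from .gaussian import query_columns

        a, b, c = query_columns(ds, query)
        vals.append(gaussian_te(cov_triplet(a, b, c)))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_batches))
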