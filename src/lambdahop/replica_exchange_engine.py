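"""Metropolis Monte Carlo sampling of a replica ladder with neighbour swaps.

Each ladder slot holds one walker sampling the Boltzmann distribution of the
scaled Hamiltonian ``v_s + s*v_S + lam*v_sS``.  A sweep is one wrapped-uniform
proposal on ``phi`` followed by an independent Gaussian proposal on every
solvent coordinate (the solvent coordinates are mutually uncoupled, so
per-coordinate acceptance is valid).  Every ``swap_interval`` sweeps,
configuration swaps are attempted on alternating even/odd edge sets with the
standard Metropolis criterion; Hamiltonians stay put and configurations move,
so a "walker" is a configuration lineage diffusing through the ladder.

Everything is driven by one ``numpy.random.Generator``, so a seed fixes the
full trajectory bit-for-bit.  The sweep kernel is vectorized across replicas;
a 16-replica, 2e5-sweep run takes seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError
from .protocol_ladders import Ladder
from .surrogate_model import (
    Configuration,
    SurrogateSystem,
    coupling_phi_part,
    solute_potential,
    wrap_angle,
)

DEFAULT_DELTA_PHI = 0.3   # rad, half-width of the wrapped-uniform phi proposal
DEFAULT_SIGMA_Y = 0.5     # Gaussian proposal sd on each solvent coordinate
DEFAULT_BURN_IN = 1000    # sweeps discarded before recording

_WELL_CENTRE = {"Z": 0.0, "E": np.pi}


@dataclass
class SampleSet:
    """Per-slot time series of phi and decomposed energies.

    Arrays have shape (n_slots, n_samples); sample ``j`` of slot ``k`` was
    recorded ``(j + 1) * sample_interval`` sweeps after burn-in.
    """

    ladder: Ladder
    system: SurrogateSystem
    phi: np.ndarray
    v_s: np.ndarray
    v_S: np.ndarray
    v_sS: np.ndarray
    sample_interval: int
    init_isomer: str
    seed: int

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]

    def target_phi(self) -> np.ndarray:
        """phi series of the target state (slot 1)."""
        return self.phi[0]

    def save(self, path: str) -> None:
        np.savez(
            path,
            phi=self.phi, v_s=self.v_s, v_S=self.v_S, v_sS=self.v_sS,
            meta=np.frombuffer(json.dumps({
                "ladder": self.ladder.to_text(self.system.T0),
                "system": self.system.to_dict(),
                "sample_interval": self.sample_interval,
                "init_isomer": self.init_isomer,
                "seed": self.seed,
            }).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str) -> "SampleSet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            return cls(
                ladder=Ladder.from_text(meta["ladder"]),
                system=SurrogateSystem.from_dict(meta["system"]),
                phi=data["phi"], v_s=data["v_s"], v_S=data["v_S"], v_sS=data["v_sS"],
                sample_interval=int(meta["sample_interval"]),
                init_isomer=meta["init_isomer"], seed=int(meta["seed"]),
            )


@dataclass
class SwapTrace:
    """Swap bookkeeping: per-edge attempt/accept counts and walker history.

    ``walker_history[t, k]`` is the walker id (0-based) occupying slot ``k``
    after swap round ``t``; each row is a permutation of 0..N_rep-1.
    """

    attempts: np.ndarray
    accepts: np.ndarray
    walker_history: np.ndarray
    swap_interval: int

    @property
    def n_edges(self) -> int:
        return len(self.attempts)

    @property
    def n_rounds(self) -> int:
        return self.walker_history.shape[0]

    def save(self, path: str) -> None:
        np.savez(path, attempts=self.attempts, accepts=self.accepts,
                 walker_history=self.walker_history,
                 swap_interval=np.array([self.swap_interval]))

    @classmethod
    def load(cls, path: str) -> "SwapTrace":
        with np.load(path) as data:
            return cls(attempts=data["attempts"], accepts=data["accepts"],
                       walker_history=data["walker_history"],
                       swap_interval=int(data["swap_interval"][0]))


def swap_acceptance(delta: float) -> float:
    """Metropolis probability min(1, e^{-delta}) for a reduced-energy change."""
    return float(np.exp(-delta)) if delta > 0 else 1.0


def mc_sweep(system: SurrogateSystem, config: Configuration,
             ladder_point: tuple[float, float], rng: np.random.Generator,
             delta_phi: float = DEFAULT_DELTA_PHI,
             sigma_y: float = DEFAULT_SIGMA_Y) -> Configuration:
    """One Metropolis pass over a single configuration (thin wrapper)."""
    s_intra, lam = ladder_point
    if not (0.0 < s_intra <= 1.0) or not (0.0 <= lam <= 1.0):
        raise ProtocolError(f"invalid ladder point ({s_intra}, {lam})")
    state = _EnsembleState.from_configs(system, [config])
    state.sweep(np.array([s_intra]), np.array([lam]), rng, delta_phi, sigma_y)
    return Configuration(phi=float(state.phi[0]), y=state.y[0].copy())


class _EnsembleState:
    """Mutable vectorized state of all replicas plus cached energy terms."""

    def __init__(self, system: SurrogateSystem, phi: np.ndarray, y: np.ndarray):
        self.system = system
        self.phi = phi.astype(float)
        self.y = y.astype(float)
        self._refresh_cache()

    @classmethod
    def from_configs(cls, system: SurrogateSystem, configs) -> "_EnsembleState":
        phi = np.array([c.phi for c in configs])
        y = np.stack([np.asarray(c.y, dtype=float) for c in configs]) \
            if len(configs) and len(configs[0].y) else np.zeros((len(configs), 0))
        return cls(system, phi, y)

    def _refresh_cache(self) -> None:
        self.v_S = np.asarray(solute_potential(self.system, self.phi))
        self.vsS_phi = np.asarray(coupling_phi_part(self.system, self.phi))
        self.sum_y2 = np.einsum("ij,ij->i", self.y, self.y)

    @property
    def v_s(self) -> np.ndarray:
        return 0.5 * self.system.k_s * self.sum_y2

    @property
    def v_sS(self) -> np.ndarray:
        return self.vsS_phi + 0.5 * self.system.g * self.sum_y2

    def sweep(self, s: np.ndarray, lam: np.ndarray, rng: np.random.Generator,
              delta_phi: float, sigma_y: float) -> None:
        """One in-place Metropolis pass using freshly drawn randoms."""
        n_rep, n_s = self.y.shape
        dphi = rng.uniform(-delta_phi, delta_phi, n_rep)
        u_phi = rng.random(n_rep)
        noise = rng.normal(0.0, sigma_y, (n_rep, n_s)) if n_s else None
        u_y = rng.random((n_rep, n_s)) if n_s else None
        self._sweep_with(s, lam, dphi, u_phi, noise, u_y)

    def _sweep_with(self, s, lam, dphi, u_phi, noise, u_y) -> None:
        beta = self.system.beta
        # --- phi move (wrapped uniform proposal, symmetric) ---
        phi_new = wrap_angle(self.phi + dphi)
        v_S_new = np.asarray(solute_potential(self.system, phi_new))
        vsS_new = np.asarray(coupling_phi_part(self.system, phi_new))
        du = beta * (s * (v_S_new - self.v_S) + lam * (vsS_new - self.vsS_phi))
        acc = u_phi < np.exp(-np.maximum(du, 0.0))
        self.phi[acc] = phi_new[acc]
        self.v_S[acc] = v_S_new[acc]
        self.vsS_phi[acc] = vsS_new[acc]
        # --- y moves (independent quadratic coordinates) ---
        if noise is not None and noise.shape[1]:
            stiff = self.system.k_s + lam * self.system.g  # (n_rep,)
            y_new = self.y + noise
            du_y = 0.5 * beta * stiff[:, None] * (y_new * y_new - self.y * self.y)
            acc_y = u_y < np.exp(-np.maximum(du_y, 0.0))
            self.y[acc_y] = y_new[acc_y]
            self.sum_y2 = np.einsum("ij,ij->i", self.y, self.y)


def _initial_state(system: SurrogateSystem, n_rep: int, init_isomer: str) -> _EnsembleState:
    if init_isomer not in _WELL_CENTRE:
        raise ProtocolError(f"init_isomer must be 'E' or 'Z', got {init_isomer!r}")
    phi = np.full(n_rep, _WELL_CENTRE[init_isomer])
    y = np.zeros((n_rep, system.N_s))
    return _EnsembleState(system, phi, y)


def run_replica_exchange(system: SurrogateSystem, ladder: Ladder, n_sweeps: int,
                         swap_interval: int = 10, init_isomer: str = "Z",
                         seed: int = 0, burn_in: int = DEFAULT_BURN_IN,
                         sample_interval: int | None = None,
                         delta_phi: float = DEFAULT_DELTA_PHI,
                         sigma_y: float = DEFAULT_SIGMA_Y,
                         scale_phi_width: bool = True) -> tuple[SampleSet, SwapTrace]:
    """Run the full replica-exchange chain and record samples and swaps.

    All walkers start at the bottom of the ``init_isomer`` well with y = 0;
    ``burn_in`` sweeps (with swapping active) are discarded.  Samples are
    recorded every ``sample_interval`` sweeps (default: ``swap_interval``).
    Deterministic given ``seed``.

    With ``scale_phi_width`` (default) the phi proposal half-width of slot m
    is ``delta_phi / sqrt(s_m)``, capped at pi: tempered slots have flatter
    torsional surfaces and proportionally wider thermal wells, so matching
    the proposal to the local well width keeps per-slot acceptance roughly
    uniform and removes a diffusion bottleneck at the hot end.  Proposal
    widths are a per-slot property, so per-slot detailed balance is intact.
    """
    if not (n_sweeps >= swap_interval >= 1):
        raise ProtocolError("need n_sweeps >= swap_interval >= 1")
    n_rep = ladder.n_rep
    if n_rep < 1:
        raise ProtocolError("empty ladder")
    if sample_interval is None:
        sample_interval = swap_interval

    s = ladder.s_intra
    lam = ladder.lam
    rng = np.random.default_rng(seed)
    state = _initial_state(system, n_rep, init_isomer)
    beta = system.beta

    n_edges = max(n_rep - 1, 0)
    attempts = np.zeros(n_edges, dtype=np.int64)
    accepts = np.zeros(n_edges, dtype=np.int64)
    walkers = np.arange(n_rep)
    walker_rows: list[np.ndarray] = []
    rec_phi: list[np.ndarray] = []
    rec_vS: list[np.ndarray] = []
    rec_vsS: list[np.ndarray] = []
    rec_vs: list[np.ndarray] = []

    even_edges = np.arange(0, n_edges, 2)
    odd_edges = np.arange(1, n_edges, 2)
    ds = s[:-1] - s[1:] if n_edges else np.zeros(0)
    dlam = lam[:-1] - lam[1:] if n_edges else np.zeros(0)

    def attempt_swaps(round_idx: int) -> None:
        edges = even_edges if round_idx % 2 == 0 else odd_edges
        if len(edges) == 0:
            return
        v_sS = state.v_sS
        delta = beta * (ds[edges] * (state.v_S[edges + 1] - state.v_S[edges])
                        + dlam[edges] * (v_sS[edges + 1] - v_sS[edges]))
        acc = rng.random(len(edges)) < np.exp(-np.maximum(delta, 0.0))
        attempts[edges] += 1
        accepts[edges] += acc
        hit = edges[acc]
        if len(hit):
            for arr in (state.phi, state.v_S, state.vsS_phi, state.sum_y2, walkers):
                arr[hit], arr[hit + 1] = arr[hit + 1].copy(), arr[hit].copy()
            state.y[hit], state.y[hit + 1] = state.y[hit + 1].copy(), state.y[hit].copy()

    phi_width = np.minimum(delta_phi / np.sqrt(s), np.pi) if scale_phi_width \
        else np.full(n_rep, delta_phi)

    chunk = 256
    total = burn_in + n_sweeps
    sweep_idx = 0
    round_idx = 0
    n_s = system.N_s
    while sweep_idx < total:
        n_now = min(chunk, total - sweep_idx)
        dphi_block = rng.uniform(-1.0, 1.0, (n_now, n_rep)) * phi_width[None, :]
        uphi_block = rng.random((n_now, n_rep))
        noise_block = rng.normal(0.0, sigma_y, (n_now, n_rep, n_s)) if n_s else None
        uy_block = rng.random((n_now, n_rep, n_s)) if n_s else None
        for j in range(n_now):
            state._sweep_with(s, lam, dphi_block[j], uphi_block[j],
                              None if noise_block is None else noise_block[j],
                              None if uy_block is None else uy_block[j])
            sweep_idx += 1
            if sweep_idx % swap_interval == 0:
                attempt_swaps(round_idx)
                round_idx += 1
                if sweep_idx > burn_in:
                    walker_rows.append(walkers.copy())
            if sweep_idx > burn_in and (sweep_idx - burn_in) % sample_interval == 0:
                rec_phi.append(state.phi.copy())
                rec_vS.append(state.v_S.copy())
                rec_vsS.append(state.v_sS.copy())
                rec_vs.append(state.v_s.copy())

    samples = SampleSet(
        ladder=ladder, system=system,
        phi=np.array(rec_phi).T, v_s=np.array(rec_vs).T,
        v_S=np.array(rec_vS).T, v_sS=np.array(rec_vsS).T,
        sample_interval=sample_interval, init_isomer=init_isomer, seed=seed,
    )
    trace = SwapTrace(
        attempts=attempts, accepts=accepts,
        walker_history=(np.array(walker_rows, dtype=np.int32)
                        if walker_rows else np.zeros((0, n_rep), dtype=np.int32)),
        swap_interval=swap_interval,
    )
    return samples, trace
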