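"""Replica-exchange health metrics and the sampling-failure detector.

Exchange ratios proxy the energy-distribution overlap between neighbours;
round-trip times measure walker diffusion along the ladder; the
initial-condition-dependence check compares target-state E/Z free energies
from an E-started and a Z-started run and declares "n/a" whenever a run
never visits one of the isomers in its target state (the signature of a
stuck ladder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DiagnosticsError
from .free_energy_estimators import PopulationResult, delta_g_ez_from_populations
from .replica_exchange_engine import SampleSet, SwapTrace

DEFAULT_SIGMA_GATE = 3.0


def exchange_ratios(trace: SwapTrace) -> np.ndarray:
    """Per-edge accepted/attempted swap fractions."""
    if np.any(trace.attempts == 0):
        raise DiagnosticsError("zero swap attempts on at least one edge")
    return trace.accepts / trace.attempts


def exchange_ratio_range(trace: SwapTrace) -> tuple[float, float]:
    """(min, max) exchange ratio across edges."""
    r = exchange_ratios(trace)
    return float(r.min()), float(r.max())


def format_exchange_range(trace: SwapTrace) -> str:
    """Render the across-edge range as 'lo-hi%'."""
    lo, hi = exchange_ratio_range(trace)
    return f"{100 * lo:.0f}-{100 * hi:.0f}%"


@dataclass(frozen=True)
class RoundTripResult:
    """Pooled walker round-trip statistics, in sweeps."""

    mean: float | None
    stderr: float | None
    count: int
    mean_rounds: float | None = None  # same quantity in swap-attempt rounds

    @property
    def is_na(self) -> bool:
        return self.count == 0


def round_trip_times(trace: SwapTrace) -> RoundTripResult:
    """Mean bottom->top->bottom traversal time of the walkers.

    A round trip is one walker's consecutive visit sequence
    slot 1 -> slot N_rep -> slot 1; durations are pooled over walkers and
    reported in sweeps (and swap rounds).  Zero completed trips is a valid
    result (count 0, undefined mean), not an error.
    """
    hist = trace.walker_history
    n_rounds, n_rep = hist.shape
    if n_rep < 2:
        raise DiagnosticsError("round trips need at least 2 replicas")
    durations: list[int] = []
    # slot occupied by each walker over time: invert the permutation rows
    for w in range(n_rep):
        at = np.argmax(hist == w, axis=1) if n_rounds else np.zeros(0, dtype=int)
        # phase 0: waiting to leave bottom; 1: heading to top; 2: heading home
        start = None
        phase = 0
        for t in range(n_rounds):
            slot = at[t]
            if phase == 0:
                if slot == 0:
                    start = t
                    phase = 1
            elif phase == 1:
                if slot == n_rep - 1:
                    phase = 2
            else:
                if slot == 0:
                    durations.append(t - start)
                    start = t
                    phase = 1
    if not durations:
        return RoundTripResult(mean=None, stderr=None, count=0)
    d = np.asarray(durations, dtype=float)
    mean_rounds = float(d.mean())
    stderr = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else None
    return RoundTripResult(
        mean=mean_rounds * trace.swap_interval,
        stderr=None if stderr is None else stderr * trace.swap_interval,
        count=int(d.size),
        mean_rounds=mean_rounds,
    )


def dihedral_histogram(samples: SampleSet, slot: int = 0, n_bins: int = 36):
    """Probability-normalized histogram of one slot's phi over (-pi, pi]."""
    if n_bins < 8:
        raise DiagnosticsError("n_bins must be >= 8")
    phi = samples.phi[slot]
    if phi.size == 0:
        raise DiagnosticsError("empty sample set")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phi, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def isomer_populations(samples: SampleSet) -> np.ndarray:
    """Per-slot fraction of samples in the E basin."""
    return np.mean(np.abs(samples.phi) >= 0.5 * np.pi, axis=1)


@dataclass(frozen=True)
class ConvergenceVerdict:
    """Initial-condition-dependence result."""

    verdict: str                        # "converged" | "not-converged" | "n/a"
    gap: float | None                   # dG(E start) - dG(Z start), kcal/mol
    result_e: PopulationResult
    result_z: PopulationResult


def initial_condition_dependence(run_e: SampleSet, run_z: SampleSet,
                                 sigma_gate: float = DEFAULT_SIGMA_GATE) -> ConvergenceVerdict:
    """Compare target-state dG_E/Z of an E-started and a Z-started run.

    "n/a" whenever either run never visits one isomer in its target state;
    otherwise converged iff |gap| <= sigma_gate x combined standard error.
    """
    t = run_e.system.T0
    res_e = delta_g_ez_from_populations(run_e.target_phi(), T=t)
    res_z = delta_g_ez_from_populations(run_z.target_phi(), T=run_z.system.T0)
    if res_e.is_na or res_z.is_na:
        return ConvergenceVerdict("n/a", None, res_e, res_z)
    gap = res_e.value - res_z.value
    se = np.sqrt((res_e.stderr or 0.0) ** 2 + (res_z.stderr or 0.0) ** 2)
    verdict = "converged" if abs(gap) <= sigma_gate * se or gap == 0.0 else "not-converged"
    return ConvergenceVerdict(verdict, gap, res_e, res_z)
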