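"""Free-energy machinery: populations, MBAR, BAR strata, PMF, mixture identity.

The estimators operate on stored energy components, never on re-simulation:
the reduced energy of any sample at any ladder point (s, lam) is
``beta * (v_s + s*v_S + lam*v_sS)``, linear in the components, so the full
cross-state energy matrix is assembled exactly from one run's record.

Conventions
-----------
* ``delta_g_ez`` is RT ln(P_E / P_Z): positive means E favoured.
* Dimensionless state free energies ``f_k = -ln Z_k`` are gauge-fixed by
  ``f_1 = 0`` (slot 1 = target state).
* A stratum free energy ``dF_k = ln(Z_{k+1} / Z_k) = f_k - f_{k+1}`` (RT
  units); their plain sum telescopes to the end-to-end value, which
  :func:`hydration_delta_g_from_f` converts to F(target) - F(last slot)
  in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

from .errors import EstimatorError
from .protocol_ladders import Ladder
from .replica_exchange_engine import SampleSet
from .surrogate_model import R_GAS

DEFAULT_N_BLOCKS = 10


# ---------------------------------------------------------------------------
# population estimator
# ---------------------------------------------------------------------------

def classify_isomer(phi) -> np.ndarray:
    """True where phi belongs to the Z basin (|phi| < pi/2)."""
    return np.abs(np.asarray(phi)) < 0.5 * np.pi


@dataclass(frozen=True)
class PopulationResult:
    """ΔG_E/Z from isomer counts; ``value`` is None when a basin is unvisited."""

    value: float | None
    stderr: float | None
    n_e: int
    n_z: int

    @property
    def is_na(self) -> bool:
        return self.value is None


def delta_g_ez_from_populations(phi_series, T: float = 300.0,
                                n_blocks: int = DEFAULT_N_BLOCKS) -> PopulationResult:
    """RT ln(N_E / N_Z) from a target-state phi series, with block-average error.

    Returns an "n/a" result (value None) when either isomer is never visited,
    mirroring the diagnostics convention for stuck ladders.
    """
    phi = np.asarray(phi_series, dtype=float)
    if phi.size == 0:
        raise EstimatorError("empty phi series")
    rt = R_GAS * T
    is_z = classify_isomer(phi)
    n_z = int(is_z.sum())
    n_e = int(phi.size - n_z)
    if n_e == 0 or n_z == 0:
        return PopulationResult(value=None, stderr=None, n_e=n_e, n_z=n_z)
    value = rt * float(np.log(n_e / n_z))

    blocks = np.array_split(is_z, n_blocks)
    vals = []
    for b in blocks:
        bz = int(b.sum())
        be = int(b.size - bz)
        if bz > 0 and be > 0:
            vals.append(rt * np.log(be / bz))
    if len(vals) >= 2:
        stderr = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    else:
        stderr = None
    return PopulationResult(value=value, stderr=stderr, n_e=n_e, n_z=n_z)


# ---------------------------------------------------------------------------
# reduced-energy matrix + MBAR
# ---------------------------------------------------------------------------

@dataclass
class ReducedEnergyMatrix:
    """u[k, n]: reduced energy of pooled sample n at ladder state k."""

    u: np.ndarray
    n_k: np.ndarray
    phi: np.ndarray = field(default=None)  # pooled phi, aligned with columns

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=np.int64)
        if self.u.ndim != 2:
            raise EstimatorError("u must be 2-D (states x samples)")
        if int(self.n_k.sum()) != self.u.shape[1]:
            raise EstimatorError("sum of N_k must equal the pooled sample count")
        if not np.all(np.isfinite(self.u)):
            raise EstimatorError("non-finite reduced energies")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]


def statistical_inefficiency(series, max_lag: int | None = None) -> float:
    """g = 1 + 2 tau_int of a scalar series, with positive-sum truncation.

    The integrated autocorrelation time is accumulated until the estimated
    autocorrelation first drops below zero (initial-positive-sequence rule);
    ``g`` is the subsampling interval that makes samples roughly independent.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return 1.0
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    max_lag = max_lag or n // 2
    g = 1.0
    for t in range(1, max_lag):
        c = float(np.dot(x[:-t], x[t:]) / (n - t)) / var
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def decorrelation_interval(samples: SampleSet, slot: int = 0) -> int:
    """Subsampling stride (in recorded samples) from v_sS at one slot."""
    return int(np.ceil(statistical_inefficiency(samples.v_sS[slot])))


def reduced_energy_matrix(samples: SampleSet, subsample: int | str = 1) -> ReducedEnergyMatrix:
    """Build the full cross-state matrix from stored energy components.

    ``subsample`` may be an explicit stride or ``"auto"`` to use the
    integrated autocorrelation of the target-state coupling energy.
    """
    if subsample == "auto":
        subsample = decorrelation_interval(samples)
    sl = slice(None, None, max(int(subsample), 1))
    v_s = samples.v_s[:, sl].ravel()
    v_S = samples.v_S[:, sl].ravel()
    v_sS = samples.v_sS[:, sl].ravel()
    phi = samples.phi[:, sl].ravel()
    beta = samples.system.beta
    s = samples.ladder.s_intra[:, None]
    lam = samples.ladder.lam[:, None]
    u = beta * (v_s[None, :] + s * v_S[None, :] + lam * v_sS[None, :])
    n_per = samples.phi[:, sl].shape[1]
    n_k = np.full(samples.ladder.n_rep, n_per, dtype=np.int64)
    return ReducedEnergyMatrix(u=u, n_k=n_k, phi=phi)


@dataclass
class MBARResult:
    """Self-consistent dimensionless free energies and target-state weights."""

    f_k: np.ndarray
    converged: bool
    residual: float
    log_denom: np.ndarray  # ln sum_l N_l exp(f_l - u_ln), per pooled sample

    def target_weights(self, matrix: ReducedEnergyMatrix, state: int = 0) -> np.ndarray:
        """Normalized per-sample weights for reweighting onto one state."""
        logw = -matrix.u[state] - self.log_denom
        logw -= logsumexp(logw)
        return np.exp(logw)


def _mbar_objective(f_free: np.ndarray, u: np.ndarray, n_k: np.ndarray):
    """Convex MBAR objective and gradient, gauge f_1 = 0 (f_free = f_2..K)."""
    f = np.concatenate(([0.0], f_free))
    with np.errstate(divide="ignore"):
        log_nf = np.where(n_k > 0, np.log(np.maximum(n_k, 1e-300)) + f, -np.inf)  # (K,)
    log_denom = logsumexp(log_nf[:, None] - u, axis=0)  # (N,)
    obj = float(np.sum(log_denom) - np.dot(n_k, f))
    # gradient wrt f_k: sum_n W_nk N_k - N_k, for k >= 2
    logw = log_nf[1:, None] - u[1:, :] - log_denom[None, :]
    grad = np.exp(logsumexp(logw, axis=1)) - n_k[1:]
    return obj, grad, log_denom


def mbar_solve(matrix: ReducedEnergyMatrix, tol: float = 1e-10,
               max_iter: int = 10000, damping: float = 0.5) -> MBARResult:
    """Solve the MBAR self-consistent equations.

    Damped self-consistent iteration, then a quasi-Newton polish on the
    convex log-sum-exp objective.  States with zero samples are reweighted
    passively (they contribute no terms to the mixture denominator).
    """
    u = matrix.u
    n_k = matrix.n_k.astype(float)
    k_states, n_tot = u.shape
    if k_states < 1 or n_tot < 1:
        raise EstimatorError("need at least one state and one sample")
    if int((n_k > 0).sum()) < 1:
        raise EstimatorError("no state contributed samples")

    # common column shift for numerical safety (gauge-invariant)
    shift = u.min(axis=0)
    u = u - shift[None, :]

    active = n_k > 0
    log_n = np.where(active, np.log(np.where(active, n_k, 1.0)), -np.inf)

    def sc_update(f):
        log_denom = logsumexp((log_n + f)[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    # damped self-consistent warm start
    f = np.zeros(k_states)
    resid = np.inf
    for _ in range(min(200, max_iter)):
        f_new = sc_update(f)
        resid = float(np.max(np.abs(f_new - f)))
        f = f + (1.0 - damping) * (f_new - f)
        if resid < tol:
            break

    # quasi-Newton polish on the convex objective, then iterate the
    # self-consistent map to the requested fixed-point tolerance
    if k_states > 1 and resid >= tol:
        res = minimize(
            lambda x: _mbar_objective(x, u, n_k)[:2], f[1:], jac=True,
            method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        f = np.concatenate(([0.0], res.x))
        for _ in range(max_iter):
            f_new = sc_update(f)
            resid = float(np.max(np.abs(f_new - f)))
            f = f_new
            if resid < tol:
                break

    converged = resid < max(tol, 1e-12) * 10
    if not converged:
        raise EstimatorError(f"MBAR did not converge: residual {resid:.3e}")
    log_denom = logsumexp((log_n + f)[:, None] - u, axis=0)
    # undo the column shift inside the stored denominator so that
    # target_weights can consume the original (unshifted) u matrix:
    # ln sum_l N_l e^{f_l - u_orig} = ln sum_l N_l e^{f_l - u_shifted} - shift
    return MBARResult(f_k=f, converged=converged, residual=resid,
                      log_denom=log_denom - shift)


# ---------------------------------------------------------------------------
# BAR (two-state Bennett) and strata
# ---------------------------------------------------------------------------

def bar_delta_f(work_fwd, work_rev, tol: float = 1e-12) -> float:
    """Two-state Bennett solution for dF = -ln(Z_j / Z_i), RT units.

    ``work_fwd`` are u_j - u_i on state-i samples; ``work_rev`` are
    u_i - u_j on state-j samples.  Solved as the scalar self-consistent
    root; equals two-state MBAR at convergence.  With non-overlapping work
    distributions a warning is emitted and the best-effort root returned.
    """
    w_f = np.asarray(work_fwd, dtype=float)
    w_r = np.asarray(work_rev, dtype=float)
    if w_f.size == 0 or w_r.size == 0:
        raise EstimatorError("both work sets must be nonempty")
    m = float(np.log(w_f.size / w_r.size))

    if np.min(w_f) > -np.min(w_r) + 50.0 or np.max(w_f) < -np.max(w_r) - 50.0:
        warnings.warn("BAR work distributions barely overlap; estimate unreliable",
                      RuntimeWarning, stacklevel=2)

    def fermi_sum(x):
        # sum_F 1/(1+e^{m+w_F-x}) - sum_R 1/(1+e^{-(m-w_R-x)}) ... derived from
        # the Bennett stationarity condition; roots checked against MBAR.
        a = m + w_f - x
        b = -(m - w_r - x)
        sf = np.sum(1.0 / (1.0 + np.exp(np.clip(a, -500, 500))))
        sr = np.sum(1.0 / (1.0 + np.exp(np.clip(b, -500, 500))))
        return sf - sr

    lo = float(min(np.min(w_f), np.min(-w_r))) - 10.0
    hi = float(max(np.max(w_f), np.max(-w_r))) + 10.0
    flo, fhi = fermi_sum(lo), fermi_sum(hi)
    if flo * fhi > 0:
        # widen; the function is monotone in x
        lo, hi = lo - 500, hi + 500
        flo, fhi = fermi_sum(lo), fermi_sum(hi)
        if flo * fhi > 0:
            warnings.warn("BAR root not bracketed; returning exponential-average fallback",
                          RuntimeWarning, stacklevel=2)
            return float(-(logsumexp(-w_f) - np.log(w_f.size)))
    return float(brentq(fermi_sum, lo, hi, xtol=tol))


def neighbor_strata(samples: SampleSet, subsample: int | str = 1) -> np.ndarray:
    """dF_k = ln(Z_{k+1}/Z_k) for every neighbouring pair, via BAR.

    Forward/reverse work values are assembled exactly from stored energy
    components ("instantaneous switching" costs nothing extra since u is
    linear in (s, lam)).
    """
    mat = reduced_energy_matrix(samples, subsample=subsample)
    n_k = mat.n_k
    starts = np.concatenate(([0], np.cumsum(n_k)))
    out = np.empty(samples.ladder.n_rep - 1)
    for k in range(samples.ladder.n_rep - 1):
        sl_i = slice(starts[k], starts[k + 1])
        sl_j = slice(starts[k + 1], starts[k + 2])
        w_f = mat.u[k + 1, sl_i] - mat.u[k, sl_i]
        w_r = mat.u[k, sl_j] - mat.u[k + 1, sl_j]
        # BAR returns -ln(Z_j/Z_i); dF_k is +ln(Z_{k+1}/Z_k)
        out[k] = -bar_delta_f(w_f, w_r)
    return out


def stratified_delta_f(strata) -> float:
    """Plain telescoping sum of the per-stratum dF_k (RT units)."""
    return float(np.sum(np.asarray(strata, dtype=float)))


def hydration_delta_g_from_f(delta_f_total: float, T: float = 300.0) -> float:
    """Convert the end-to-end dF = sum_k ln(Z_{k+1}/Z_k) = ln(Z_last/Z_target)
    into F(target) - F(last) = RT * dF in kcal/mol: the hydration direction
    when slot 1 is the fully coupled state and the last slot the quasi-gas
    state, matching the quadrature oracle's F(lambda_hi) - F(lambda_lo)."""
    return R_GAS * T * delta_f_total


def hydration_delta_g_from_samples(samples: SampleSet, subsample: int | str = 1,
                                   method: str = "mbar") -> float:
    """End-to-end F(slot 1) - F(slot N) in kcal/mol from one run."""
    if method == "bar":
        total = stratified_delta_f(neighbor_strata(samples, subsample=subsample))
    elif method == "mbar":
        mat = reduced_energy_matrix(samples, subsample=subsample)
        res = mbar_solve(mat)
        total = float(-(res.f_k[-1] - res.f_k[0]))  # ln(Z_last/Z_1)
    else:
        raise EstimatorError(f"unknown method {method!r}")
    return hydration_delta_g_from_f(total, T=samples.system.T0)


# ---------------------------------------------------------------------------
# PMF reconstruction
# ---------------------------------------------------------------------------

def mbar_pmf(matrix: ReducedEnergyMatrix, mbar: MBARResult, n_bins: int = 72,
             target_state: int = 0, T: float = 300.0):
    """Reweighted free-energy profile over phi at the target state.

    Returns (bin centers, profile kcal/mol) with empty bins as NaN, the
    populated minimum shifted to zero.
    """
    if matrix.phi is None:
        raise EstimatorError("matrix carries no phi record")
    if not mbar.converged:
        raise EstimatorError("MBAR result not converged")
    w = mbar.target_weights(matrix, state=target_state)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # np.histogram's weighted path goes through a cumulative sum, which wipes
    # out bins whose mass is ~1e-30 of the total (exactly the barrier-top bins
    # this profile exists to resolve); bincount sums each bin independently.
    bin_idx = np.clip(np.digitize(matrix.phi, edges) - 1, 0, n_bins - 1)
    mass = np.bincount(bin_idx, weights=w, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = np.full(n_bins, np.nan)
    pop = mass > 0
    if int(pop.sum()) <= 1:
        warnings.warn("degenerate PMF: all weight in one bin", RuntimeWarning,
                      stacklevel=2)
    profile[pop] = -R_GAS * T * np.log(mass[pop])
    profile -= np.nanmin(profile)
    return centers, profile


def pmf_barrier(centers: np.ndarray, profile: np.ndarray) -> float:
    """Barrier: populated maximum minus the Z-well (|phi| < pi/2) minimum."""
    z = np.abs(centers) < 0.5 * np.pi
    return float(np.nanmax(profile) - np.nanmin(profile[z]))


# ---------------------------------------------------------------------------
# mixture identity
# ---------------------------------------------------------------------------

def ratio_from_delta_g_ez(dg_ez: float, T: float = 300.0) -> float:
    """R_E/Z = exp(dg_ez / RT) under the RT ln(P_E/P_Z) convention."""
    if not np.isfinite(dg_ez):
        raise EstimatorError("dg_ez must be finite")
    return float(np.exp(dg_ez / (R_GAS * T)))


def mixture_delta_g(dg_E: float, dg_Z: float, r_ze: float, T: float = 300.0) -> float:
    """Mixture free energy combining per-isomer values with an E/Z ratio.

    Evaluates, term for term,

        dG = dG_E - RT ln[ 1/(1 + R_Z/E) + e^{-beta (dG_Z - dG_E)}/(1 + R_E/Z) ]

    with R_E/Z = 1/r_ze.  This reproduces the published worked examples when
    fed hydration-direction per-isomer values together with the solution
    (target-state) ratio.  See :func:`mixture_delta_g_exact` for the form
    that is an exact thermodynamic-cycle identity in that convention.
    """
    if not r_ze > 0:
        raise EstimatorError(f"r_ze must be positive, got {r_ze}")
    rt = R_GAS * T
    r_ez = 1.0 / r_ze
    bracket = 1.0 / (1.0 + r_ze) + np.exp(-(dg_Z - dg_E) / rt) / (1.0 + r_ez)
    return float(dg_E - rt * np.log(bracket))


def mixture_delta_g_exact(dg_E: float, dg_Z: float, r_ze: float, T: float = 300.0) -> float:
    """Exact mixture identity for hydration-direction dG with a solution ratio.

    Writing per-isomer transfer constants K_X = e^{+beta dG_X} (solution ->
    gas) and weighting them by the solution populations gives

        dG = dG_E + RT ln[ 1/(1 + R_Z/E) + e^{+beta (dG_Z - dG_E)}/(1 + R_E/Z) ]

    which is the sign-conjugate of :func:`mixture_delta_g`.  On an exactly
    consistent system this equals the end-to-end stratified estimate of the
    mixture, which is the property exercised by the self-consistency checks.
    """
    return -mixture_delta_g(-dg_E, -dg_Z, r_ze, T=T)
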