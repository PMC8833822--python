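"""Brute-force references for the analytic moment engine.

Two independent routes to the same stochastic process:

* ``ssa_ensemble`` — exact stochastic simulation (Gillespie) of the four
  effective reactions {OFF->ON at f, ON->OFF at h, birth at k while ON, death
  at rho*n}, run cell by cell.  Time-dependent rates are handled by running
  the standard constant-rate algorithm within each piecewise-constant segment
  of the dose-response rate functions, using a stricter segmentation tolerance
  than the analytic engine so that any disagreement cannot be blamed on the
  approximation.
* ``fsp_evolve`` — finite-state-projection integration of the master
  equation: the copy number is truncated at n_max, the resulting linear system
  is advanced exactly per segment by the action of the matrix exponential, and
  the probability mass leaking past the truncation is monitored and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csc_matrix, csr_matrix, identity, lil_matrix
from scipy.sparse.linalg import expm_multiply, spsolve

from .kinetics import GeneKinetics
from .simulate import TreatmentScenario, _union_rate_grid

__all__ = [
    "DistributionState",
    "EnsembleSummary",
    "ssa_ensemble",
    "fsp_evolve",
    "fsp_stationary",
]

ORACLE_ABS_ERR = 1e-6  # piecewise tolerance for oracle runs (stricter than default)


@dataclass(frozen=True)
class DistributionState:
    """Joint law at one time: alpha[n] = P(ON, n), beta[n] = P(OFF, n)."""

    alpha: np.ndarray
    beta: np.ndarray
    n_max: int
    leakage: float

    @property
    def marginal(self) -> np.ndarray:
        return self.alpha + self.beta

    def mean(self) -> float:
        n = np.arange(self.n_max + 1)
        return float(np.dot(n, self.marginal))

    def sd(self) -> float:
        n = np.arange(self.n_max + 1)
        p = self.marginal
        m1 = np.dot(n, p)
        return float(np.sqrt(max(np.dot(n * n, p) - m1 * m1, 0.0)))


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble mean/sd with standard errors at the probe times."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se_mean: np.ndarray
    se_sd: np.ndarray
    n_cells: int
    seed: int


@njit(cache=True)
def _ssa_cell(seed, n0, g0, seg_edges, seg_f, seg_k, seg_h, seg_rho,
              probe_times):  # pragma: no cover - compiled
    """Exact simulation of one cell; returns copy number at the probe times."""
    np.random.seed(seed)
    out = np.empty(probe_times.size, dtype=np.int64)
    n = n0
    gene_on = g0
    t = 0.0
    ip = 0
    for s in range(seg_edges.size - 1):
        t_end = seg_edges[s + 1]
        f = seg_f[s]
        k = seg_k[s]
        h = seg_h[s]
        rho = seg_rho[s]
        while t < t_end:
            a_switch = f if gene_on == 0 else h
            a_birth = k if gene_on == 1 else 0.0
            a_death = rho * n
            a_tot = a_switch + a_birth + a_death
            if a_tot <= 0.0:
                t = t_end
                break
            dt = -np.log(np.random.random()) / a_tot
            t_new = t + dt
            while ip < probe_times.size and probe_times[ip] < min(t_new, t_end):
                out[ip] = n
                ip += 1
            if t_new >= t_end:
                t = t_end
                break
            t = t_new
            u = np.random.random() * a_tot
            if u < a_switch:
                gene_on = 1 - gene_on
            elif u < a_switch + a_birth:
                n += 1
            else:
                n -= 1
    while ip < probe_times.size:
        out[ip] = n
        ip += 1
    return out


def _segment_rate_arrays(
    sc: TreatmentScenario, abs_err: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Union piecewise grid as flat per-segment rate arrays."""
    edges, rate_trajs = _union_rate_grid(sc, abs_err, continuity_mode=False)
    base = sc.baseline
    S = edges.size - 1
    arr = {
        "f": np.full(S, base.f),
        "k": np.full(S, base.k),
        "h": np.full(S, base.h),
        "rho": np.full(S, base.rho),
    }
    mids = 0.5 * (edges[:-1] + edges[1:])
    for target, rt in rate_trajs:
        arr[target] = np.array([rt.value_at(m) for m in mids])
    return edges, arr["f"], arr["k"], arr["h"], arr["rho"]


def _sample_stationary(kin: GeneKinetics, rng: np.random.Generator,
                       n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (copy number, gene state) pairs from the joint stationary law."""
    st = fsp_stationary(kin)
    p_joint = np.concatenate([st.alpha, st.beta])
    p_joint = np.clip(p_joint, 0.0, None)
    p_joint /= p_joint.sum()
    idx = rng.choice(p_joint.size, size=n_cells, p=p_joint)
    m = st.n_max + 1
    gene = (idx < m).astype(np.int64)  # first block is ON
    n = np.where(idx < m, idx, idx - m).astype(np.int64)
    return n, gene


def ssa_ensemble(
    sc: TreatmentScenario,
    n_cells: int,
    seed: int,
    probe_times: np.ndarray | None = None,
    abs_err: float = ORACLE_ABS_ERR,
) -> EnsembleSummary:
    """Ensemble of exact stochastic simulations of the scenario.

    Each cell starts from an independent draw of the pre-treatment joint
    stationary law and owns an independent random stream derived from
    (seed, cell index), so results are reproducible and order-independent.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if probe_times is None:
        probe_times = np.linspace(0.0, sc.horizon, 21)
    probe_times = np.asarray(probe_times, dtype=float)
    edges, f_a, k_a, h_a, rho_a = _segment_rate_arrays(sc, abs_err)
    rng = np.random.default_rng(seed)
    n0, g0 = _sample_stationary(sc.baseline, rng, n_cells)
    cell_seeds = np.random.SeedSequence(seed).generate_state(n_cells) % (2**31 - 1)
    counts = np.empty((n_cells, probe_times.size), dtype=np.int64)
    for c in range(n_cells):
        counts[c] = _ssa_cell(
            np.int64(cell_seeds[c]), np.int64(n0[c]), np.int64(g0[c]),
            edges, f_a, k_a, h_a, rho_a, probe_times,
        )
    x = counts.astype(float)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    sd = np.sqrt(var)
    se_mean = sd / np.sqrt(n_cells)
    # se of the sd via the delta method with the fourth central moment
    m4 = ((x - mean) ** 4).mean(axis=0)
    var_of_var = np.maximum(m4 - (n_cells - 3) / (n_cells - 1) * var**2, 0.0) / n_cells
    se_sd = np.sqrt(var_of_var) / np.maximum(2.0 * sd, 1e-12)
    return EnsembleSummary(
        times=probe_times, mean=mean, sd=sd, se_mean=se_mean, se_sd=se_sd,
        n_cells=n_cells, seed=seed,
    )


def _fsp_generator(kin: GeneKinetics, n_max: int) -> csr_matrix:
    """Truncated master-equation generator on states (ON block, OFF block)."""
    m = n_max + 1
    Q = lil_matrix((2 * m, 2 * m))
    k, rho, f, h = kin.k, kin.rho, kin.f, kin.h
    for n in range(m):
        on, off = n, m + n
        # synthesis (ON only); births out of n_max leak (FSP truncation)
        Q[on, on] -= k
        if n < n_max:
            Q[on + 1, on] += k
        # degradation
        if n > 0:
            Q[on - 1, on] += rho * n
            Q[off - 1, off] += rho * n
            Q[on, on] -= rho * n
            Q[off, off] -= rho * n
        # switching
        Q[off, on] += h
        Q[on, on] -= h
        Q[on, off] += f
        Q[off, off] -= f
    return csr_matrix(Q)


def fsp_stationary(kin: GeneKinetics, n_max: int | None = None) -> DistributionState:
    """Stationary joint law by direct solve of the truncated generator.

    Replaces one balance equation by the normalization constraint and solves
    the sparse linear system; leakage is the (tiny) stationary birth flux out
    of the truncation boundary.
    """
    if n_max is None:
        N = kin.k / kin.rho
        n_max = int(np.ceil(N + 10.0 * np.sqrt(max(N, 1.0)) + 50.0))
    Q = _fsp_generator(kin, n_max).tolil()
    m = n_max + 1
    Q[0, :] = 1.0
    rhs = np.zeros(2 * m)
    rhs[0] = 1.0
    p = spsolve(csc_matrix(Q), rhs)
    leakage = float(abs(1.0 - p.sum()))
    return DistributionState(alpha=p[:m], beta=p[m:], n_max=n_max, leakage=leakage)


def fsp_evolve(
    sc: TreatmentScenario,
    n_max: int,
    times: np.ndarray,
    init: DistributionState | None = None,
    abs_err: float = ORACLE_ABS_ERR,
    max_leakage: float = 1e-6,
) -> list[DistributionState]:
    """Master-equation trajectory of the scenario on a truncated state space.

    Rates follow the same piecewise-constant segmentation as the analytic
    engine; within each segment the (constant) truncated generator is applied
    through its exponential action.  Raises if the probability leaking past
    n_max exceeds ``max_leakage``.
    """
    times = np.asarray(times, dtype=float)
    edges, f_a, k_a, h_a, rho_a = _segment_rate_arrays(sc, abs_err)
    if init is None:
        init = fsp_stationary(sc.baseline, n_max)
    if init.n_max != n_max:
        raise ValueError("initial state truncation does not match n_max")
    m = n_max + 1
    p = np.concatenate([init.alpha, init.beta])
    if p[m - 1] + p[2 * m - 1] > 1e-9:
        raise ValueError(
            f"initial mass at the truncation bound n_max={n_max} is not negligible"
        )
    out: list[DistributionState] = []
    ip = 0
    t_seg = 0.0
    for s in range(edges.size - 1):
        a, b = edges[s], edges[s + 1]
        kin = GeneKinetics(k=k_a[s], rho=rho_a[s], f=f_a[s], h=h_a[s])
        Q = _fsp_generator(kin, n_max)
        # probe times inside this segment
        ts = []
        while ip < times.size and times[ip] < b:
            ts.append(times[ip])
            ip += 1
        for t in ts:
            pt = expm_multiply(Q * (t - a), p)
            leak = float(abs(1.0 - pt.sum()))
            if leak > max_leakage:
                raise RuntimeError(
                    f"FSP leakage {leak:.2e} exceeds {max_leakage:.0e} at "
                    f"t={t}; increase n_max beyond {n_max}"
                )
            out.append(DistributionState(alpha=pt[:m], beta=pt[m:],
                                         n_max=n_max, leakage=leak))
        p = expm_multiply(Q * (b - a), p)
        t_seg = b
    # probes at/after the horizon get the final state
    while ip < times.size:
        leak = float(abs(1.0 - p.sum()))
        out.append(DistributionState(alpha=p[:m], beta=p[m:],
                                     n_max=n_max, leakage=leak))
        ip += 1
    return out
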