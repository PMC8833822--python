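"""Treatment-response trajectories of the telegraph model.

A treatment scenario combines baseline gene kinetics with one or more drugs,
each carrying its own dose agenda.  The time-dependent rates are approximated
as piecewise-constant (``dosing.piecewise_rates``); within every segment of
the union grid all rates are constant, so the five-moment system is propagated
by its exact matrix-exponential solution.  The initial condition of each
segment is the final state of its predecessor, and the whole trajectory starts
from the pre-treatment stationary state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO

import numpy as np
from .dosing import Agenda, DrugSpec, RateTrajectory, piecewise_rates
from .kinetics import (
    GeneKinetics,
    MomentState,
    expm_moments,
    moment_system,
    steady_moment_state,
)

__all__ = [
    "TreatmentScenario",
    "Trajectory",
    "ResponseMetrics",
    "simulate",
    "response_metrics",
    "write_trajectory",
    "read_trajectory",
    "write_metrics",
]


@dataclass(frozen=True)
class TreatmentScenario:
    """Baseline kinetics plus drugs, agendas and readout conventions.

    threshold is the copy-number level the mean should exceed for the
    treatment to count as successful (80 in the default convention);
    target_mean is the post-treatment expression level aimed at (100);
    window (start, end, hours after the first dose) delimits the interval over
    which time-averaged response metrics are taken.
    """

    baseline: GeneKinetics
    drugs: tuple[tuple[DrugSpec, Agenda], ...] = ()
    horizon: float = 150.0
    output_dt: float = 0.05
    threshold: float = 80.0
    target_mean: float = 100.0
    window: tuple[float, float] = (60.0, 80.0)
    name: str = ""

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        targets = [d.target for d, _ in self.drugs]
        if len(set(targets)) != len(targets):
            raise ValueError("at most one drug per target rate")
        for drug, _ in self.drugs:
            base = getattr(self.baseline, drug.target)
            if not np.isclose(drug.r0, base, rtol=1e-9, atol=0.0):
                raise ValueError(
                    f"drug {drug.name}: r0={drug.r0} does not match baseline "
                    f"{drug.target}={base}"
                )

    def with_fractions(self, fractions: dict[str, float | Sequence[float]]
                       ) -> "TreatmentScenario":
        """Copy of the scenario with each named drug's dose fractions replaced."""
        new_drugs = []
        for drug, agenda in self.drugs:
            if drug.name in fractions:
                xis = fractions[drug.name]
                if np.isscalar(xis):
                    xis = [float(xis)] * len(agenda)
                agenda = Agenda(
                    tuple(
                        type(d)(d.tau, x) for d, x in zip(agenda.doses, xis)
                    )
                )
            new_drugs.append((drug, agenda))
        return TreatmentScenario(
            baseline=self.baseline, drugs=tuple(new_drugs), horizon=self.horizon,
            output_dt=self.output_dt, threshold=self.threshold,
            target_mean=self.target_mean, window=self.window, name=self.name,
        )

    def fingerprint(self) -> str:
        """Short stable hash of all scenario parameters."""
        payload = json.dumps(
            {
                "gene": [self.baseline.k, self.baseline.rho, self.baseline.f,
                         self.baseline.h],
                "drugs": [
                    [d.name, d.target, d.lam, d.r0, d.r1,
                     [[e.tau, e.xi] for e in a.doses]]
                    for d, a in self.drugs
                ],
                "sim": [self.horizon, self.output_dt, self.threshold,
                        self.target_mean, list(self.window)],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class Trajectory:
    """Mean and standard deviation of the copy number over time."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    moment_states: list[MomentState] = field(repr=False)
    abs_err: float = 1e-4

    def interp_mean(self, t: float) -> float:
        return float(np.interp(t, self.times, self.mean))


@dataclass(frozen=True)
class ResponseMetrics:
    """Summary readouts of a treatment-response trajectory.

    t_cross : first time the mean crosses the threshold upward (None if never);
    mean_max / t_max : maximum of the mean and when it occurs;
    avg_mean_minus_sd, avg_two_sd : unweighted time averages of <n>-sigma and
    2*sigma over the metrics window.
    """

    t_cross: Optional[float]
    mean_max: float
    t_max: float
    avg_mean_minus_sd: float
    avg_two_sd: float
    window: tuple[float, float]


def _union_rate_grid(
    sc: TreatmentScenario, abs_err: float, continuity_mode: bool
) -> tuple[np.ndarray, list[tuple[str, RateTrajectory]]]:
    """Union of all drugs' piecewise breakpoints; per-drug rate trajectories."""
    trajs: list[tuple[str, RateTrajectory]] = []
    edges = {0.0, sc.horizon}
    for drug, agenda in sc.drugs:
        rt = piecewise_rates(drug, agenda, sc.horizon, abs_err, continuity_mode)
        trajs.append((drug.target, rt))
        edges.update(rt.breakpoints.tolist())
    return np.array(sorted(edges)), trajs


def simulate(
    sc: TreatmentScenario,
    abs_err: float = 1e-4,
    init: Optional[MomentState] = None,
    continuity_mode: bool = False,
) -> Trajectory:
    """Moment trajectory of the scenario on the output grid.

    Rates are piecewise-constant with per-segment integrated error <= abs_err;
    moments chain exactly across segments, so mean and sd are continuous even
    though the rates jump.  The default initial condition is the pre-treatment
    stationary state of the baseline kinetics.
    """
    edges, rate_trajs = _union_rate_grid(sc, abs_err, continuity_mode)
    if init is None:
        init = steady_moment_state(sc.baseline)
    out_times = np.arange(0.0, sc.horizon + 0.5 * sc.output_dt, sc.output_dt)
    out_times = np.unique(np.concatenate([out_times, edges]))

    times: list[float] = []
    means: list[float] = []
    sds: list[float] = []
    states: list[MomentState] = []
    x = init.as_array()
    base = sc.baseline
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        rates = {"k": base.k, "rho": base.rho, "f": base.f, "h": base.h}
        for target, rt in rate_trajs:
            rates[target] = rt.value_at(mid)
        kin = GeneKinetics(**rates)
        M, bvec = moment_system(kin)
        xs = np.linalg.solve(M, -bvec)
        dx = (x - xs).astype(np.longdouble)
        # output times inside [a, b); segment end handled as next segment start
        sel = out_times[(out_times >= a) & (out_times < b)]
        for t in sel:
            xt = xs + np.asarray(expm_moments(M * (t - a)) @ dx, dtype=float)
            if not np.all(np.isfinite(xt)):
                raise ArithmeticError(
                    f"non-finite moments in segment [{a}, {b}] of scenario "
                    f"{sc.name or sc.fingerprint()}"
                )
            m1 = xt[1]
            var = max(xt[3] - m1 * m1, 0.0)
            times.append(float(t))
            means.append(float(m1))
            sds.append(float(np.sqrt(var)))
            xt[0] = min(max(xt[0], 0.0), 1.0)
            states.append(MomentState.from_array(xt))
        x = xs + np.asarray(expm_moments(M * (b - a)) @ dx, dtype=float)
    # final point at the horizon
    m1 = x[1]
    times.append(float(edges[-1]))
    means.append(float(m1))
    sds.append(float(np.sqrt(max(x[3] - m1 * m1, 0.0))))
    x[0] = min(max(x[0], 0.0), 1.0)
    states.append(MomentState.from_array(x))
    return Trajectory(
        times=np.array(times), mean=np.array(means), sd=np.array(sds),
        moment_states=states, abs_err=abs_err,
    )


def response_metrics(
    traj: Trajectory,
    threshold: float = 80.0,
    window: tuple[float, float] = (60.0, 80.0),
) -> ResponseMetrics:
    """Threshold crossing, maximum and windowed time averages of a trajectory.

    The crossing time is found by linear interpolation between grid points;
    time averages use the trapezoidal rule, x_bar = int x dt / (tf - ti).
    A mean that never reaches the threshold yields t_cross = None.
    """
    t, m, s = traj.times, traj.mean, traj.sd
    ti, tf = window
    if ti < t[0] or tf > t[-1] or tf <= ti:
        raise ValueError(f"window {window} not inside trajectory span "
                         f"({t[0]}, {t[-1]})")
    t_cross: Optional[float] = None
    above = m >= threshold
    if above[0]:
        t_cross = float(t[0])
    else:
        idx = np.nonzero(above[1:] & ~above[:-1])[0]
        if idx.size:
            i = idx[0]
            frac = (threshold - m[i]) / (m[i + 1] - m[i])
            t_cross = float(t[i] + frac * (t[i + 1] - t[i]))
    i_max = int(np.argmax(m))
    grid = np.linspace(ti, tf, 801)
    mw = np.interp(grid, t, m)
    sw = np.interp(grid, t, s)
    avg1 = float(np.trapezoid(mw - sw, grid) / (tf - ti))
    avg2 = float(np.trapezoid(2.0 * sw, grid) / (tf - ti))
    return ResponseMetrics(
        t_cross=t_cross,
        mean_max=float(m[i_max]),
        t_max=float(t[i_max]),
        avg_mean_minus_sd=avg1,
        avg_two_sd=avg2,
        window=window,
    )


def write_trajectory(traj: Trajectory, fh: TextIO, meta: str = "") -> None:
    """Tab-delimited trajectory table with a metadata header line."""
    fh.write(f"# genedose trajectory; times in h, copy numbers in molecules; "
             f"abs_err={traj.abs_err}{('; ' + meta) if meta else ''}\n")
    fh.write("time_h\tmean\tsd\tmean_minus_sd\tmean_plus_sd\n")
    for t, m, s in zip(traj.times, traj.mean, traj.sd):
        fh.write(f"{t:.17g}\t{m:.17g}\t{s:.17g}\t{m - s:.17g}\t{m + s:.17g}\n")


def read_trajectory(fh: TextIO) -> Trajectory:
    """Read back a table written by ``write_trajectory`` (moments not stored)."""
    rows = []
    abs_err = np.nan
    for line in fh:
        if line.startswith("#"):
            for tokenpart in line.split(";"):
                if "abs_err=" in tokenpart:
                    abs_err = float(tokenpart.split("abs_err=")[1].split(";")[0])
            continue
        if line.startswith("time_h"):
            continue
        rows.append([float(v) for v in line.split()])
    arr = np.array(rows)
    return Trajectory(times=arr[:, 0], mean=arr[:, 1], sd=arr[:, 2],
                      moment_states=[], abs_err=abs_err)


def write_metrics(metrics: ResponseMetrics, sc: TreatmentScenario,
                  fh: TextIO, abs_err: float = 1e-4) -> None:
    """JSON metrics record with scenario fingerprint and approximation metadata."""
    rec = {
        "scenario": sc.name or "",
        "fingerprint": sc.fingerprint(),
        "t_cross_h": metrics.t_cross,
        "mean_max": metrics.mean_max,
        "t_max_h": metrics.t_max,
        "avg_mean_minus_sd": metrics.avg_mean_minus_sd,
        "avg_two_sd": metrics.avg_two_sd,
        "window_h": list(metrics.window),
        "piecewise_abs_err": abs_err,
        "segment_rule": "midpoint",
    }
    json.dump(rec, fh, indent=2)
    fh.write("\n")
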