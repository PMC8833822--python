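"""Time-dependent kinetic rates under multi-dose treatment.

Each drug targets one kinetic rate of the telegraph model.  A dose applied at
time tau_j instantaneously moves the targeted rate toward its maximum-dose
value r1, scaled by the dose fraction xi in (0, 1]; between doses the drug
effect decays exponentially at rate lam, so the rate relaxes back toward its
baseline r0.  Remainders of earlier doses superpose: the post-dose rate is

    r_s(tau_j) = r1 * sum_{i<=j} xi_i * exp(-lam * (tau_j - tau_i))

and for tau_j <= t < tau_{j+1}

    r(t) = r0 + (r_s(tau_j) - r0) * exp(-lam * (t - tau_j)).

For analytic propagation of the moment dynamics the exponentially relaxing
rate is approximated as piecewise constant, with the integrated absolute
deviation on every segment held below a requested error bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "DrugSpec",
    "DoseEvent",
    "Agenda",
    "RateTrajectory",
    "rate_value",
    "post_dose_rate",
    "piecewise_rates",
]

TargetRate = Literal["f", "k", "h", "rho"]


@dataclass(frozen=True)
class DrugSpec:
    """Pharmacodynamic description of one drug.

    name : identifier; target : which telegraph rate it acts on (f, k, h, rho);
    lam : exponential decay rate of the drug effect (1/h); r0 : baseline value
    of the targeted rate; r1 : value of the targeted rate at maximum tolerated
    dose (r1 > r0 enhances, r1 < r0 suppresses).
    """

    name: str
    target: TargetRate
    lam: float
    r0: float
    r1: float

    def __post_init__(self) -> None:
        if self.target not in ("f", "k", "h", "rho"):
            raise ValueError(f"unknown target rate {self.target!r}")
        if self.lam <= 0:
            raise ValueError(f"drug {self.name}: decay rate lam must be > 0")
        if self.r0 < 0 or (self.r0 == 0 and self.target != "f"):
            raise ValueError(f"drug {self.name}: baseline r0 must be positive")
        if self.r1 < 0:
            raise ValueError(f"drug {self.name}: max-dose rate r1 must be >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """One dose: application time tau (h) and fraction xi of the maximum dose."""

    tau: float
    xi: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"dose time tau must be >= 0, got {self.tau}")
        if not 0.0 < self.xi <= 1.0:
            raise ValueError(f"dose fraction xi must lie in (0, 1], got {self.xi}")


@dataclass(frozen=True)
class Agenda:
    """A drug's dose schedule; dose times strictly increasing."""

    doses: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        taus = [d.tau for d in self.doses]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError(f"dose times must be strictly increasing, got {taus}")

    @staticmethod
    def regular(n_doses: int, interval: float, xis: float | Sequence[float] = 1.0,
                start: float = 0.0) -> "Agenda":
        """Agenda of n_doses doses spaced by ``interval`` hours from ``start``."""
        if np.isscalar(xis):
            xis = [float(xis)] * n_doses
        xis = list(xis)
        if len(xis) != n_doses:
            raise ValueError(f"need {n_doses} fractions, got {len(xis)}")
        return Agenda(tuple(DoseEvent(start + i * interval, x) for i, x in enumerate(xis)))

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class RateTrajectory:
    """Piecewise-constant approximation of a time-dependent rate.

    ``breakpoints`` (length S+1) delimit S segments with constant ``values``;
    ``exact`` evaluates the un-approximated rate; ``abs_err`` is the per-segment
    bound on the integrated absolute deviation that the construction enforced;
    ``segment_rule`` records how the constant was chosen.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    exact: Callable[[float], float] = field(repr=False)
    abs_err: float
    segment_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if self.values.size != self.breakpoints.size - 1:
            raise ValueError("need exactly one value per segment")

    def value_at(self, t: float) -> float:
        """Approximated rate at time t (right-continuous at breakpoints)."""
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        i = min(max(i, 0), self.values.size - 1)
        return float(self.values[i])

    def to_table(self) -> np.ndarray:
        """Two-column (segment start time, rate) array."""
        return np.column_stack([self.breakpoints[:-1], self.values])


def post_dose_rate(drug: DrugSpec, agenda: Agenda, j: int,
                   continuity_mode: bool = False) -> float:
    """Targeted-rate value immediately after the j-th dose (0-based).

    Default is the superposition form r1 * sum_i xi_i exp(-lam (tau_j-tau_i)).
    With ``continuity_mode`` the new dose instead adds (r1-r0)*xi_j on top of
    the limit from the left, which makes the trajectory jump exactly by the
    dose increment (the printed superposition differs from this by
    r0-proportional terms).
    """
    doses = agenda.doses
    tau_j = doses[j].tau
    if not continuity_mode:
        return drug.r1 * sum(
            d.xi * np.exp(-drug.lam * (tau_j - d.tau)) for d in doses[: j + 1]
        )
    if j == 0:
        return drug.r0 + (drug.r1 - drug.r0) * doses[0].xi
    prev = post_dose_rate(drug, agenda, j - 1, continuity_mode=True)
    left = drug.r0 + (prev - drug.r0) * np.exp(-drug.lam * (tau_j - doses[j - 1].tau))
    return left + (drug.r1 - drug.r0) * doses[j].xi


def rate_value(drug: DrugSpec, agenda: Agenda, t: float,
               continuity_mode: bool = False) -> float:
    """Exact targeted-rate value at time t >= 0."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    taus = [d.tau for d in agenda.doses]
    j = int(np.searchsorted(taus, t, side="right")) - 1
    if j < 0:
        return drug.r0
    rs = post_dose_rate(drug, agenda, j, continuity_mode)
    return drug.r0 + (rs - drug.r0) * np.exp(-drug.lam * (t - taus[j]))


def _segment_error(c: float, lam: float, t0: float, t1: float) -> float:
    """Integrated |c e^{-lam t} - c e^{-lam tm}| over [t0, t1], tm midpoint.

    Times are measured from the most recent dose.  The integrand changes sign
    exactly once, at the midpoint, so the integral splits into two exact
    pieces of the exponential antiderivative.
    """
    tm = 0.5 * (t0 + t1)
    e0, em, e1 = np.exp(-lam * t0), np.exp(-lam * tm), np.exp(-lam * t1)
    left = (e0 - em) / lam - (tm - t0) * em
    right = (t1 - tm) * em + (e1 - em) / lam
    return abs(c) * (left + right)


def piecewise_rates(
    drug: DrugSpec,
    agenda: Agenda,
    horizon: float,
    abs_err: float = 1e-4,
    continuity_mode: bool = False,
    max_segments: int = 2_000_000,
) -> RateTrajectory:
    """Piecewise-constant approximation of the exact rate on [0, horizon].

    Segments never straddle a dose time.  Within each inter-dose interval the
    grid is refined by recursive bisection until the integrated absolute
    deviation of every segment from the exact exponential is <= abs_err; each
    segment's constant is the exact rate at the segment midpoint.  Halving
    abs_err can only refine the grid further, never coarsen it.
    """
    if abs_err <= 0:
        raise ValueError("abs_err must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    taus = [d.tau for d in agenda.doses if d.tau < horizon]
    edges_out: list[float] = []
    values: list[float] = []

    def exact(t: float) -> float:
        return rate_value(drug, agenda, t, continuity_mode)

    # interval boundaries: 0, dose times, horizon
    bounds = sorted({0.0, horizon, *taus})
    n_total = 0
    for a, b in zip(bounds, bounds[1:]):
        # amplitude of the exponential on this interval (constant before dose 1)
        j = int(np.searchsorted(taus, a, side="right")) - 1
        if j < 0:
            edges_out.append(a)
            values.append(drug.r0)
            n_total += 1
            continue
        rs = post_dose_rate(drug, agenda, j, continuity_mode)
        c = rs - drug.r0
        lam = drug.lam
        tau_j = taus[j]
        stack = [(a, b)]
        segs: list[tuple[float, float]] = []
        while stack:
            t0, t1 = stack.pop()
            if _segment_error(c, lam, t0 - tau_j, t1 - tau_j) <= abs_err:
                segs.append((t0, t1))
            else:
                tm = 0.5 * (t0 + t1)
                n_total += 1
                if n_total > max_segments:
                    raise RuntimeError(
                        f"abs_err={abs_err} requires more than the segment cap "
                        f"max_segments={max_segments}"
                    )
                stack.append((tm, t1))
                stack.append((t0, tm))
        for t0, t1 in sorted(segs):
            edges_out.append(t0)
            values.append(exact(0.5 * (t0 + t1)))
    edges_out.append(horizon)
    return RateTrajectory(
        breakpoints=np.array(edges_out),
        values=np.array(values),
        exact=exact,
        abs_err=abs_err,
        segment_rule="midpoint",
    )
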