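"""Packaged treatment scenarios for the five pre-treatment regimes.

Scenario names follow the figure-panel convention of the source study of the
RKIP system: columns 1/2/3 are treatments targeting the OFF->ON switching
rate f (DETANONOate-like, effect decay 0.05/h), the synthesis rate k
(5-AzaC-like, decay 0.25/h), or both; rows A-E are pre-treatment regimes with
switching speed eps0 = (0.1, 1, 2, 10, 10-burst).  Panels A-E are single full
doses at t=0; panels F-J are the multi-dose designs (5 f-doses every 10 h,
10 k-doses every 4 h, or the mixed fractional agendas of the combined
design).

The degradation rate convention is rho = 1/6 per hour (the value consistent
with the printed eps ladder); ``rho_convention="printed"`` selects 0.17.
"""

from __future__ import annotations

from typing import Sequence

from .dosing import Agenda, DrugSpec
from .kinetics import GeneKinetics
from .simulate import TreatmentScenario

__all__ = ["FIXTURE_NAMES", "fixture_scenario", "rho_value"]

LAMBDA_F = 0.05   # decay of the f-targeting drug effect, 1/h
LAMBDA_K = 0.25   # decay of the k-targeting drug effect, 1/h

_ROWS = "ABCDE"

# column 1: f-targeting drug; (k, f0, f1, h) per row A-E
_FIG3 = {
    "A": (18.5, 0.0015, 0.14, 0.015),
    "B": (18.5, 0.015, 1.37, 0.15),
    "C": (18.5, 0.03, 2.73, 0.3),
    "D": (18.5, 0.15, 13.65, 1.52),
    "E": (166.7, 0.017, 0.18, 1.65),
}
# column 2: k-targeting drug; (k0, k1, f, h) per row
_FIG4 = {
    "A": (3.3, 33.0, 0.008, 0.008),
    "B": (3.3, 33.0, 0.08, 0.08),
    "C": (3.3, 33.0, 0.17, 0.17),
    "D": (3.3, 33.0, 0.83, 0.83),
    "E": (166.7, 1667.0, 0.017, 1.65),
}
# column 3: both drugs; (k0, k1, f0, f1, h) per row
_FIG5 = {
    "A": (18.5, 33.0, 0.0015, 0.015, 0.015),
    "B": (18.5, 33.0, 0.015, 0.15, 0.15),
    "C": (18.5, 33.0, 0.03, 0.3, 0.3),
    "D": (18.5, 33.0, 0.15, 1.5, 1.5),
    "E": (167.0, 333.0, 0.017, 0.087, 1.65),
}
# combined-design multi-dose fractional agendas (panels F3-J3):
# (n_f_doses, xi_a sequence, n_k_doses, xi_b sequence)
_TABLE1 = {
    "F": ([0.9] * 3 + [0.8] * 4 + [0.5], [0.9] * 5 + [0.8] * 10 + [0.7] * 5),
    "G": ([0.8] * 3 + [0.7] + [0.5] * 2, [0.8] * 5 + [0.75] * 10),
    "H": ([0.8] * 3 + [0.7] + [0.5] * 2, [0.8] * 5 + [0.75] * 10),
    "I": ([0.7] * 4 + [0.6] + [0.5], [0.7] * 15),
    "J": ([0.7] * 3 + [0.65] + [0.6] * 2, [0.7] * 5 + [0.65] * 5 + [0.6] * 5),
}

FIXTURE_NAMES: tuple[str, ...] = tuple(
    f"fig{fig}_{panel}{col}"
    for fig, col in ((3, 1), (4, 2), (5, 3))
    for panel in "ABCDEFGHIJ"
)


def rho_value(rho_convention: str = "one-sixth") -> float:
    """Degradation rate for the chosen convention: 1/6 (default) or 0.17 per h."""
    if rho_convention == "one-sixth":
        return 1.0 / 6.0
    if rho_convention == "printed":
        return 0.17
    raise ValueError(f"unknown rho convention {rho_convention!r}")


def _f_drug(f0: float, f1: float) -> DrugSpec:
    return DrugSpec(name="detanonoate", target="f", lam=LAMBDA_F, r0=f0, r1=f1)


def _k_drug(k0: float, k1: float) -> DrugSpec:
    return DrugSpec(name="azacytidine", target="k", lam=LAMBDA_K, r0=k0, r1=k1)


def fixture_scenario(name: str, rho_convention: str = "one-sixth",
                     horizon: float | None = None) -> TreatmentScenario:
    """Build the named packaged scenario (e.g. ``fig3_A1``, ``fig5_H3``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    rho = rho_value(rho_convention)
    fig, panel_col = name.split("_")
    panel, col = panel_col[0], panel_col[1]
    row = panel if panel in _ROWS else _ROWS["FGHIJ".index(panel)]
    multi = panel not in _ROWS

    if fig == "fig3":
        k, f0, f1, h = _FIG3[row]
        gene = GeneKinetics(k=k, rho=rho, f=f0, h=h)
        agenda = Agenda.regular(5, 10.0) if multi else Agenda.regular(1, 1.0)
        drugs = ((_f_drug(f0, f1), agenda),)
        default_horizon = 150.0
    elif fig == "fig4":
        k0, k1, f, h = _FIG4[row]
        gene = GeneKinetics(k=k0, rho=rho, f=f, h=h)
        agenda = Agenda.regular(10, 4.0) if multi else Agenda.regular(1, 1.0)
        drugs = ((_k_drug(k0, k1), agenda),)
        default_horizon = 120.0
    else:
        k0, k1, f0, f1, h = _FIG5[row]
        gene = GeneKinetics(k=k0, rho=rho, f=f0, h=h)
        if multi:
            xa, xb = _TABLE1[panel]
            drugs = (
                (_f_drug(f0, f1), Agenda.regular(len(xa), 10.0, xa)),
                (_k_drug(k0, k1), Agenda.regular(len(xb), 4.0, xb)),
            )
            default_horizon = 150.0
        else:
            drugs = (
                (_f_drug(f0, f1), Agenda.regular(1, 1.0)),
                (_k_drug(k0, k1), Agenda.regular(1, 1.0)),
            )
            default_horizon = 250.0
    return TreatmentScenario(
        baseline=gene,
        drugs=drugs,
        horizon=default_horizon if horizon is None else horizon,
        name=name,
    )
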