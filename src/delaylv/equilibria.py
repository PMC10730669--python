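"""Closed-form equilibria, survival condition, nullclines and outcome labels.

At equilibrium every chain stage equals the adult density and the window
mean is ``f_i = tau_i N_i / Delta_i``, so the adult equation reduces to a
condition on ``(N1, N2)`` alone.  Taking logs, the growth nullcline of
species ``i`` is the straight line::

    a_i tau_i N_i + (Delta_i / Delta_j) b_j tau_j N_j = -A_i

The ``Delta_i / Delta_j`` factor on the cross term arises because the
competitor's window mean ``f_j`` (taken over its own maturation window
``Delta_j``) enters species ``i``'s mortality integral over the window
``Delta_i``.  It is 1 whenever the two truncation shifts coincide — the
symmetric settings in which the model's closed forms are usually quoted —
but must be kept for asymmetric kernels or the analytic equilibria stop
matching the ODE system.

Outcomes are labelled by the standard invasibility logic of competition
theory: with both species viable in isolation (``A_i < 0``), species ``i``
can invade the competitor's single-species equilibrium iff its log growth
rate there is positive.  Mutual invasibility under weak interspecific
competition (``a1 a2 > b1 b2``) gives stable coexistence; mutual
non-invasibility under strong competition gives bistability (the interior
point is a saddle); one-sided invasibility gives competitive exclusion.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
import json

import numpy as np

from .chain_model import DerivedParams, SpeciesParams, TwoSpeciesModel, derive
from .errors import DegenerateRegimeError, ExistenceError, ParameterError

__all__ = [
    "LABELS",
    "NullclineLine",
    "EquilibriumReport",
    "survives",
    "survival_ratio_threshold",
    "boundary_equilibrium",
    "coexistence_equilibrium",
    "nullclines",
    "classify",
    "discrete_limit_params",
    "outcome_grid",
]

#: Outcome labels, in the encoding used by the region maps.
LABELS = (
    "both_extinct",
    "sp1_only",
    "sp2_only",
    "coexistence_stable",
    "bistable",
    "degenerate",
)
_CODE = {name: i for i, name in enumerate(LABELS)}

#: Tolerance on strict inequalities: values this close to a frontier are
#: labelled degenerate rather than silently assigned to a side.
TOL = 1e-9


@dataclass(frozen=True)
class NullclineLine:
    """The line ``coef_self * N_i + coef_other * N_j = constant`` on which
    the growth rate of species ``i`` vanishes.

    ``coef_self = a_i tau_i``, ``coef_other = (Delta_i/Delta_j) b_j tau_j``,
    ``constant = -A_i``.
    """

    coef_self: float
    coef_other: float
    constant: float

    def residual(self, N_self: float, N_other: float) -> float:
        return self.coef_self * N_self + self.coef_other * N_other - self.constant

    def solve_other(self, N_self) -> np.ndarray:
        """``N_j`` on the line for given ``N_i`` (requires ``coef_other != 0``)."""
        return (self.constant - self.coef_self * np.asarray(N_self)) / self.coef_other


@dataclass
class EquilibriumReport:
    """The four equilibrium candidates with existence/stability flags."""

    trivial_stable: bool
    boundary1: float | None
    boundary1_stable: bool | None
    boundary2: float | None
    boundary2_stable: bool | None
    coexistence: tuple[float, float] | None
    coexistence_exists: bool
    coexistence_stable: bool | None
    regime: str  # weak | strong | degenerate
    label: str

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def survives(species: SpeciesParams) -> bool:
    """Survival in isolation: reproduction beats the combined mortality drain.

    ``ln(r) - ln(m) + p [ln(beta) - ln(beta+mu)] > 0``, i.e. ``A < 0``.
    """
    return derive(species).A < 0


def survival_ratio_threshold(r: float, m: float, mu: float, p: int) -> float:
    """Critical mean-delay ratio ``p / beta`` at the survival boundary.

    Solves ``A(beta) = 0`` at fixed integer shape, which has the closed form
    ``beta* = mu / ((r/m)**(1/p) - 1)``; a species with ``p/beta`` above the
    returned value fails the survival condition.  With ``mu = 0`` the
    deficit is delay-independent and the threshold is infinite.
    """
    if not r > m:
        raise ParameterError(f"requires r > m, got r={r}, m={m}")
    if mu < 0:
        raise ParameterError(f"mu must be non-negative, got {mu}")
    if mu == 0:
        return math.inf
    beta_crit = mu / ((r / m) ** (1.0 / p) - 1.0)
    return p / beta_crit


def boundary_equilibrium(species: SpeciesParams) -> float:
    """Single-species equilibrium density ``-A / (a * tau)``.

    Exists only when the survival condition holds (``A < 0``).
    """
    d = derive(species)
    if d.A >= 0:
        raise ExistenceError(
            f"boundary equilibrium does not exist: survival condition fails (A={d.A:.6g} >= 0)"
        )
    return -d.A / (species.a * d.tau)


def _geometry(model: TwoSpeciesModel):
    sp1, sp2 = model.species1, model.species2
    d1, d2 = derive(sp1), derive(sp2)
    rho = sp1.kernel.delta / sp2.kernel.delta
    det = sp1.a * sp2.a - sp1.b * sp2.b
    # g_i > 0  <=>  species i can invade the competitor's boundary equilibrium
    g1 = rho * sp2.b * d2.A - sp2.a * d1.A
    g2 = sp1.b * d1.A / rho - sp1.a * d2.A
    return sp1, sp2, d1, d2, rho, det, g1, g2


def nullclines(model: TwoSpeciesModel) -> tuple[NullclineLine, NullclineLine]:
    """Log-linearised growth nullclines of the two species in the (N1, N2) plane."""
    sp1, sp2, d1, d2, rho, _, _, _ = _geometry(model)
    line1 = NullclineLine(sp1.a * d1.tau, rho * sp2.b * d2.tau, -d1.A)
    line2 = NullclineLine(sp2.a * d2.tau, sp1.b * d1.tau / rho, -d2.A)
    return line1, line2


def coexistence_equilibrium(model: TwoSpeciesModel) -> tuple[float, float]:
    """Intersection of the two nullclines (may lie outside the positive quadrant).

    Solves the 2x2 linear system; raises :class:`DegenerateRegimeError` when
    ``a1 a2 = b1 b2`` within tolerance (parallel nullclines).
    """
    sp1, sp2, d1, d2, rho, det, g1, g2 = _geometry(model)
    if abs(det) < 1e-12:
        raise DegenerateRegimeError(
            f"a1*a2 - b1*b2 = {det:.3g}: nullclines are parallel, no isolated interior point"
        )
    N1 = g1 / (det * d1.tau)
    N2 = g2 / (det * d2.tau)
    return N1, N2


def _labels_from_arrays(A1, A2, g1, g2, det, tol=TOL):
    """Vectorised outcome labelling shared by :func:`classify` and the region scans.

    All inputs broadcast together; ``det`` is ``a1*a2 - b1*b2``.  Returns an
    integer array of codes into :data:`LABELS`.
    """
    A1, A2, g1, g2 = np.broadcast_arrays(
        np.asarray(A1, float), np.asarray(A2, float), np.asarray(g1, float), np.asarray(g2, float)
    )
    det = np.broadcast_to(np.asarray(det, float), A1.shape)

    surv1 = A1 < -tol
    surv2 = A2 < -tol
    near_A = (np.abs(A1) <= tol) | (np.abs(A2) <= tol)
    both = surv1 & surv2
    near_g = both & ((np.abs(g1) <= tol) | (np.abs(g2) <= tol) | (np.abs(det) <= tol))
    weak = det > tol
    strong = det < -tol

    conditions = [
        near_A,
        ~surv1 & ~surv2,
        surv1 & ~surv2,
        surv2 & ~surv1,
        near_g,
        both & (g1 > tol) & (g2 < -tol),
        both & (g1 < -tol) & (g2 > tol),
        both & weak & (g1 > tol) & (g2 > tol),
        both & strong & (g1 < -tol) & (g2 < -tol),
    ]
    choices = [
        _CODE["degenerate"],
        _CODE["both_extinct"],
        _CODE["sp1_only"],
        _CODE["sp2_only"],
        _CODE["degenerate"],
        _CODE["sp1_only"],
        _CODE["sp2_only"],
        _CODE["coexistence_stable"],
        _CODE["bistable"],
    ]
    return np.select(conditions, choices, default=_CODE["degenerate"])


def outcome_grid(A1, A2, g1, g2, det, tol=TOL):
    """Public alias of the shared vectorised labelling rule."""
    return _labels_from_arrays(A1, A2, g1, g2, det, tol=tol)


def classify(model: TwoSpeciesModel) -> EquilibriumReport:
    """Full outcome classification of the model.

    Procedure: (1) test the survival condition per species — a species that
    fails it is extinct independent of competition; (2) with both viable,
    locate the nullcline intersection and decide its existence/stability
    from the competition regime and mutual invasibility; (3) without an
    interior point, resolve competitive exclusion by invasibility of the
    boundary equilibria.  Frontier cases (any strict inequality within
    tolerance) are labelled ``degenerate``.
    """
    sp1, sp2, d1, d2, rho, det, g1, g2 = _geometry(model)
    code = int(_labels_from_arrays(d1.A, d2.A, g1, g2, det))
    label = LABELS[code]

    regime = "degenerate" if abs(det) <= TOL else ("weak" if det > 0 else "strong")

    b1_eq = -d1.A / (sp1.a * d1.tau) if d1.A < 0 else None
    b2_eq = -d2.A / (sp2.a * d2.tau) if d2.A < 0 else None
    # boundary i is locally stable iff it exists and the competitor cannot invade
    b1_stable = (g2 < -TOL) if b1_eq is not None else None
    b2_stable = (g1 < -TOL) if b2_eq is not None else None

    coex = None
    coex_exists = False
    coex_stable = None
    if abs(det) > TOL:
        coex = (g1 / (det * d1.tau), g2 / (det * d2.tau))
        coex_exists = coex[0] > TOL and coex[1] > TOL and d1.A < -TOL and d2.A < -TOL
        if coex_exists:
            coex_stable = regime == "weak"

    return EquilibriumReport(
        trivial_stable=d1.A > TOL and d2.A > TOL,
        boundary1=b1_eq,
        boundary1_stable=b1_stable,
        boundary2=b2_eq,
        boundary2_stable=b2_stable,
        coexistence=coex,
        coexistence_exists=coex_exists,
        coexistence_stable=coex_stable,
        regime=regime,
        label=label,
    )


def discrete_limit_params(species: SpeciesParams) -> DerivedParams:
    """Derived quantities in the discrete-delay limit ``p -> inf`` at fixed ``T = p/beta``.

    The kernel tends to a Dirac mass at ``T``: ``alpha -> 1``, ``tau -> T``
    and the log fitness deficit tends to ``A = ln(m/r) + mu*T`` (the limit
    of ``p ln((beta+mu)/beta)`` with ``p/beta`` held constant is ``mu*T``).
    """
    T = species.kernel.p / species.kernel.beta
    A = math.log(species.m / species.r) + species.mu * T
    return DerivedParams(alpha=1.0, tau=T, A=A)
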