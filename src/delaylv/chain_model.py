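"""Parameter containers, derived quantities and the linear-chain ODE system.

The distributed-delay competition model is represented, exactly for a
truncated-Erlang kernel, by a cascade of first-order stages (the linear
chain trick).  Per species ``i`` the state consists of the adult density
``N_i``, a chain ``x_{i,1..p_i}`` carrying the delayed birth cohort with
immature mortality, the mean density ``f_i`` of adults over the maturation
window, and a second chain ``y_{i,1..p_i}`` that delays ``N_i`` (without
mortality) to drive ``f_i``.  The packed vector has length
``2 * (p1 + p2 + 2)`` with the fixed order::

    [N1, x1_1..x1_p1, f1, y1_1..y1_p1, N2, x2_1..x2_p2, f2, y2_1..y2_p2]

The right-hand side implements, per species ``i`` with competitor ``j``::

    dN_i/dt   = r_i (beta_i/(beta_i+mu_i))**p_i * x_{i,p_i}
                * exp(-Delta_i [a_i f_i + b_j f_j]) - m_i N_i
    dx_{i,1}  = (mu_i+beta_i) (N_i - x_{i,1}) / alpha_i
    dx_{i,k}  = (mu_i+beta_i) (x_{i,k-1} - x_{i,k}) / alpha_i
    df_i      = (N_i - y_{i,p_i}) / Delta_i
    dy_{i,1}  = beta_i (N_i - y_{i,1}) / alpha_i
    dy_{i,k}  = beta_i (y_{i,k-1} - y_{i,k}) / alpha_i

Cross-coupling convention: the equation for species ``i`` uses the ``b`` of
species ``j`` (the competitor's effect *on* ``i`` is stored on the species
exerting it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .errors import DomainError, ParameterError, StructureError
from .kernels import KernelSpec

__all__ = [
    "SpeciesParams",
    "DerivedParams",
    "TwoSpeciesModel",
    "derive",
    "rhs",
    "equilibrium_state",
    "initial_state",
    "state_size",
    "column_names",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Rates and competition coefficients of one species.

    ``r``: offspring per adult per unit time; ``m``: adult mortality;
    ``mu``: immature mortality; ``a``: intraspecific competition
    coefficient; ``b``: interspecific effect exerted BY this species ON the
    other (normalized densities, so both are dimensionless); ``kernel``:
    the maturation-delay kernel.  Requires ``r > m``.
    """

    r: float
    m: float
    mu: float
    a: float
    b: float
    kernel: KernelSpec

    def __post_init__(self) -> None:
        for name in ("r", "m", "mu", "a"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.b < 0:
            raise ParameterError(f"b must be non-negative, got {self.b}")
        if not self.r > self.m:
            raise ParameterError(
                f"reproduction must exceed adult mortality (r > m), got r={self.r}, m={self.m}"
            )


@dataclass(frozen=True)
class DerivedParams:
    """Quantities that drive every equilibrium formula.

    ``alpha``: Erlang mass below the truncation shift; ``tau``: effective
    delay weight ``p * alpha / beta`` (scales competition exposure during
    maturation); ``A``: log fitness deficit
    ``ln(m) - ln(r) + p [ln(beta+mu) - ln(beta)]`` — the species survives
    in isolation iff ``A < 0``.
    """

    alpha: float
    tau: float
    A: float


def derive(params: SpeciesParams) -> DerivedParams:
    """Compute the truncation constant, delay weight and log fitness deficit."""
    k = params.kernel
    a = kernels.alpha(k)
    tau = k.p * a / k.beta
    A = (
        math.log(params.m)
        - math.log(params.r)
        + k.p * (math.log(k.beta + params.mu) - math.log(k.beta))
    )
    return DerivedParams(alpha=a, tau=tau, A=A)


class _SpeciesBlock:
    """Precomputed per-species constants and state-vector slices."""

    __slots__ = (
        "p", "offset", "iN", "sx", "i_f", "sy",
        "m", "a", "b", "delta", "inv_delta", "R", "cx", "cy",
    )

    def __init__(self, sp: SpeciesParams, offset: int):
        k = sp.kernel
        d = derive(sp)
        self.p = k.p
        self.offset = offset
        self.iN = offset
        self.sx = slice(offset + 1, offset + 1 + k.p)
        self.i_f = offset + 1 + k.p
        self.sy = slice(offset + 2 + k.p, offset + 2 + 2 * k.p)
        self.m = sp.m
        self.a = sp.a
        self.b = sp.b
        self.delta = k.delta
        self.inv_delta = 1.0 / k.delta
        self.R = sp.r * (k.beta / (k.beta + sp.mu)) ** k.p
        self.cx = (sp.mu + k.beta) / d.alpha
        self.cy = k.beta / d.alpha


@dataclass
class TwoSpeciesModel:
    """The full two-species model: parameters plus precomputed chain constants."""

    species1: SpeciesParams
    species2: SpeciesParams
    _blocks: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        p1 = self.species1.kernel.p
        b1 = _SpeciesBlock(self.species1, 0)
        b2 = _SpeciesBlock(self.species2, 2 * p1 + 2)
        self._blocks = (b1, b2)

    @property
    def size(self) -> int:
        p1 = self.species1.kernel.p
        p2 = self.species2.kernel.p
        return 2 * (p1 + p2 + 2)

    @property
    def derived(self) -> tuple[DerivedParams, DerivedParams]:
        return derive(self.species1), derive(self.species2)

    def swapped(self) -> "TwoSpeciesModel":
        """The same model with species labels 1 and 2 exchanged."""
        return TwoSpeciesModel(self.species2, self.species1)


def state_size(model: TwoSpeciesModel) -> int:
    return model.size


def column_names(model: TwoSpeciesModel) -> list[str]:
    """State-vector component names in packing order (used in CSV headers)."""
    names: list[str] = []
    for i, sp in enumerate((model.species1, model.species2), start=1):
        p = sp.kernel.p
        names.append(f"N{i}")
        names.extend(f"x{i}_{k}" for k in range(1, p + 1))
        names.append(f"f{i}")
        names.extend(f"y{i}_{k}" for k in range(1, p + 1))
    return names


def rhs(t: float, state: np.ndarray, model: TwoSpeciesModel) -> np.ndarray:
    """Right-hand side of the chain ODE system at time ``t``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.size,):
        raise StructureError(
            f"state has shape {state.shape}, expected ({model.size},) for this model"
        )
    blk1, blk2 = model._blocks
    out = np.empty_like(state)
    f1 = state[blk1.i_f]
    f2 = state[blk2.i_f]
    for blk, f_self, f_other in ((blk1, f1, f2), (blk2, f2, f1)):
        # the competitor's b appears in this species' equation
        other = blk2 if blk is blk1 else blk1
        N = state[blk.iN]
        x = state[blk.sx]
        y = state[blk.sy]
        E = math.exp(-blk.delta * (blk.a * f_self + other.b * f_other))
        out[blk.iN] = blk.R * x[-1] * E - blk.m * N
        dx = out[blk.sx]
        dx[0] = blk.cx * (N - x[0])
        if blk.p > 1:
            dx[1:] = blk.cx * (x[:-1] - x[1:])
        out[blk.i_f] = (N - y[-1]) * blk.inv_delta
        dy = out[blk.sy]
        dy[0] = blk.cy * (N - y[0])
        if blk.p > 1:
            dy[1:] = blk.cy * (y[:-1] - y[1:])
    return out


def equilibrium_state(model: TwoSpeciesModel, N1bar: float, N2bar: float) -> np.ndarray:
    """Packed state at the analytic equilibrium ``(N1bar, N2bar)``.

    All chain stages equal the adult density and the window mean is
    ``f_i = tau_i * N_i / Delta_i``.
    """
    if N1bar < 0 or N2bar < 0:
        raise DomainError("equilibrium densities must be non-negative")
    state = np.zeros(model.size)
    for blk, sp, Nbar in (
        (model._blocks[0], model.species1, N1bar),
        (model._blocks[1], model.species2, N2bar),
    ):
        d = derive(sp)
        state[blk.iN] = Nbar
        state[blk.sx] = Nbar
        state[blk.i_f] = d.tau * Nbar / sp.kernel.delta
        state[blk.sy] = Nbar
    return state


def initial_state(
    model: TwoSpeciesModel, N1: float, N2: float, history: str = "zero"
) -> np.ndarray:
    """Initial condition with adults present and a chosen maturation history.

    ``history="zero"``: chains, window means and delayed stages all start at
    zero (a colonisation scenario: no immatures in the pipeline).
    ``history="equilibrium"``: the pipeline starts consistent with constant
    past densities ``(N1, N2)``.
    """
    if history == "zero":
        if N1 < 0 or N2 < 0:
            raise DomainError("initial densities must be non-negative")
        state = np.zeros(model.size)
        state[model._blocks[0].iN] = N1
        state[model._blocks[1].iN] = N2
        return state
    if history == "equilibrium":
        return equilibrium_state(model, N1, N2)
    raise DomainError(f"unknown history convention {history!r}")
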