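"""Local stability: chain-system Jacobian and transcendental characteristic functions.

The primary instrument is the Jacobian of the finite ODE system — the
linear chain makes that spectrum authoritative for the implemented model.
The transcendental characteristic functions quoted for the trivial and
boundary equilibria of the underlying delay system are provided for
cross-verification: their rightmost-root signs are compared with the
Jacobian in the test suite, not used as a primary code path.

The chain system conserves one quantity per species,
``C_i = f_i - (alpha_i / (beta_i Delta_i)) * sum_k y_{i,k}``
(the window mean minus its own driving chain's running integral): its time
derivative cancels identically.  Initial conditions select the invariant
manifold — both the zero-history and the equilibrium-history conventions
give ``C_i = 0``, which is what pins ``f_i = tau_i N_i / Delta_i`` at
equilibrium.  Consequently the Jacobian at *every* equilibrium carries two
structurally-neutral zero eigenvalues (motion across manifolds, not along
the dynamics).  The stability decision excludes exactly those two modes;
all remaining eigenvalues must satisfy ``Re(lambda) < -1e-9``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .chain_model import TwoSpeciesModel, derive, rhs
from .equilibria import boundary_equilibrium
from .errors import DomainError, PoleError

__all__ = [
    "StabilityResult",
    "jacobian",
    "stability_from_jacobian",
    "characteristic_det_trivial",
    "characteristic_det_boundary",
    "rightmost_root",
]

#: An equilibrium is declared stable when every non-neutral eigenvalue has
#: real part below this margin.
STABLE_MARGIN = -1e-9


@dataclass
class StabilityResult:
    eigenvalues: np.ndarray
    max_real: float
    stable: bool
    method: str  # "jacobian" | "characteristic"
    n_neutral: int = 0
    equilibrium_residual: float = 0.0
    at_equilibrium: bool = True

    def to_json(self, **kwargs) -> str:
        payload = {
            "eigenvalues": [[z.real, z.imag] for z in np.atleast_1d(self.eigenvalues)],
            "max_real": self.max_real,
            "stable": self.stable,
            "method": self.method,
            "n_neutral": self.n_neutral,
            "equilibrium_residual": self.equilibrium_residual,
            "at_equilibrium": self.at_equilibrium,
        }
        return json.dumps(payload, **kwargs)


def jacobian(model: TwoSpeciesModel, at: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the chain system at the state ``at``."""
    at = np.asarray(at, dtype=float)
    n = model.size
    if at.shape != (n,):
        raise DomainError(f"state has shape {at.shape}, expected ({n},)")
    blk1, blk2 = model._blocks
    J = np.zeros((n, n))
    f1 = at[blk1.i_f]
    f2 = at[blk2.i_f]
    for blk, f_self, f_other in ((blk1, f1, f2), (blk2, f2, f1)):
        other = blk2 if blk is blk1 else blk1
        x_last = at[blk.sx][-1]
        E = math.exp(-blk.delta * (blk.a * f_self + other.b * f_other))
        # adult equation
        J[blk.iN, blk.iN] = -blk.m
        J[blk.iN, blk.sx.stop - 1] = blk.R * E
        J[blk.iN, blk.i_f] += -blk.R * x_last * E * blk.delta * blk.a
        J[blk.iN, other.i_f] += -blk.R * x_last * E * blk.delta * other.b
        # x chain
        J[blk.sx.start, blk.iN] = blk.cx
        J[blk.sx.start, blk.sx.start] = -blk.cx
        for k in range(1, blk.p):
            J[blk.sx.start + k, blk.sx.start + k - 1] = blk.cx
            J[blk.sx.start + k, blk.sx.start + k] = -blk.cx
        # window mean
        J[blk.i_f, blk.iN] = blk.inv_delta
        J[blk.i_f, blk.sy.stop - 1] = -blk.inv_delta
        # y chain
        J[blk.sy.start, blk.iN] = blk.cy
        J[blk.sy.start, blk.sy.start] = -blk.cy
        for k in range(1, blk.p):
            J[blk.sy.start + k, blk.sy.start + k - 1] = blk.cy
            J[blk.sy.start + k, blk.sy.start + k] = -blk.cy
    return J


def stability_from_jacobian(model: TwoSpeciesModel, at: np.ndarray) -> StabilityResult:
    """Spectral stability of an equilibrium state via the chain Jacobian.

    A non-equilibrium input (``||rhs||_inf >= 1e-8``) sets a warning flag on
    the result rather than raising.
    """
    residual = float(np.max(np.abs(rhs(0.0, at, model))))
    J = jacobian(model, at)
    eig = np.linalg.eigvals(J)
    # two conserved window-mean modes (one per species) sit at exactly zero;
    # drop them — but only if they are numerically zero, so a genuinely
    # marginal third eigenvalue is never masked
    order = np.argsort(np.abs(eig))
    n_neutral = int(np.sum(np.abs(eig[order[:2]]) < 1e-7))
    kept = eig[order[n_neutral:]] if n_neutral else eig
    max_real = float(np.max(kept.real)) if kept.size else 0.0
    return StabilityResult(
        eigenvalues=eig,
        max_real=max_real,
        stable=max_real < STABLE_MARGIN,
        method="jacobian",
        n_neutral=n_neutral,
        equilibrium_residual=residual,
        at_equilibrium=residual < 1e-8,
    )


def _check_poles(lam: complex, model: TwoSpeciesModel, tol: float = 1e-12) -> None:
    for sp in (model.species1, model.species2):
        k = sp.kernel
        for pole in (-k.beta, -(k.beta + sp.mu)):
            if abs(lam - pole) < tol:
                raise PoleError(f"lambda = {lam} coincides with excluded pole {pole}")


def characteristic_det_trivial(lam: complex, model: TwoSpeciesModel) -> complex:
    """Characteristic function of the delay system at the extinction equilibrium.

    ``prod_i [lambda + m_i - r_i (beta_i/(beta_i+lambda+mu_i))**p_i]``.
    Roots with positive real part signal instability of (0, 0); the
    rightmost root crosses zero exactly on the survival boundary ``A_i = 0``
    (in the untruncated limit).
    """
    lam = complex(lam)
    _check_poles(lam, model)
    out = 1.0 + 0.0j
    for sp in (model.species1, model.species2):
        k = sp.kernel
        h = (k.beta / (k.beta + lam + sp.mu)) ** k.p
        out *= lam + sp.m - sp.r * h
    return out


def characteristic_det_boundary(lam: complex, model: TwoSpeciesModel, which_species: int) -> complex:
    """Characteristic function at the boundary equilibrium of ``which_species``.

    Product ``M_1(lam) * M_2(lam)`` where ``M_1`` governs the resident
    species at its single-species equilibrium and ``M_2`` the invading
    competitor.  With the resident ``i`` at density ``Nbar``::

        M_1 = lam**2 + m_i lam - r_i exp(-a_i tau_i Nbar)
              * (lam h_i(lam) - a_i Nbar [1 - g_i(lam)])
        M_2 = lam + m_j - r_j exp(-b_i tau_i Nbar Delta_j/Delta_i) h_j(lam)

    with ``g(lam) = (beta/(beta+lam))**p`` and
    ``h(lam) = (beta/(beta+lam+mu))**p``.  The factor
    ``exp(-a_i tau_i Nbar)`` is the equilibrium competition attenuation
    (``r_i`` times it, times ``h_i(0)``, equals ``m_i``); ``M_1`` carries a
    structural root at ``lam = 0`` from the linearisation of the window
    mean, which root finders must exclude.
    """
    lam = complex(lam)
    _check_poles(lam, model)
    if which_species not in (1, 2):
        raise DomainError("which_species must be 1 or 2")
    sp_i = model.species1 if which_species == 1 else model.species2
    sp_j = model.species2 if which_species == 1 else model.species1
    d_i = derive(sp_i)
    Nbar = boundary_equilibrium(sp_i)
    ki, kj = sp_i.kernel, sp_j.kernel

    g_i = (ki.beta / (ki.beta + lam)) ** ki.p
    h_i = (ki.beta / (ki.beta + lam + sp_i.mu)) ** ki.p
    h_j = (kj.beta / (kj.beta + lam + sp_j.mu)) ** kj.p

    M1 = lam * lam + sp_i.m * lam - sp_i.r * math.exp(-sp_i.a * d_i.tau * Nbar) * (
        lam * h_i - sp_i.a * Nbar * (1.0 - g_i)
    )
    M2 = lam + sp_j.m - sp_j.r * math.exp(
        -sp_i.b * d_i.tau * Nbar * kj.delta / ki.delta
    ) * h_j
    return M1 * M2


def rightmost_root(
    f,
    re_range: tuple[float, float] = (-2.0, 2.0),
    im_range: tuple[float, float] = (0.0, 4.0),
    n: int = 41,
    exclude_origin: bool = True,
    newton_tol: float = 1e-10,
) -> complex | None:
    """Rightmost root of a holomorphic function on a rectangle.

    Scans a grid over ``re_range x im_range`` (upper half plane suffices for
    real-coefficient functions: roots come in conjugate pairs), polishes
    local minima of ``|f|`` (plus a coarse subgrid of extra seeds) by
    Newton's method with a numerical derivative, deduplicates, and returns
    the converged root of largest real part.  ``exclude_origin`` divides out
    the structural root at 0 carried by the boundary characteristic function
    before searching.  Degenerate multiple roots are out of scope.
    """
    if exclude_origin:
        raw = f
        f = lambda lam: raw(lam) / lam if lam != 0 else (raw(1e-12) / 1e-12)
    xs = np.linspace(*re_range, n)
    ys = np.linspace(*im_range, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = X + 1j * Y
    absf = np.empty(Z.shape)
    for idx in np.ndindex(Z.shape):
        try:
            absf[idx] = abs(f(Z[idx]))
        except (PoleError, ZeroDivisionError):
            absf[idx] = np.inf

    def is_local_min(i, j):
        v = absf[i, j]
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < n and absf[ii, jj] < v:
                    return False
        return True

    seeds = [Z[i, j] for i in range(n) for j in range(n) if is_local_min(i, j)]
    seeds += [Z[i, j] for i in range(0, n, 4) for j in range(0, n, 4)]
    roots: list[complex] = []
    h = 1e-7
    for z in seeds:
        lam = z
        ok = False
        for _ in range(60):
            try:
                fv = f(lam)
                dfv = (f(lam + h) - f(lam - h)) / (2 * h)
            except (PoleError, ZeroDivisionError):
                break
            if dfv == 0:
                break
            step = fv / dfv
            lam = lam - step
            if abs(step) < newton_tol:
                ok = True
                break
        if not ok or abs(f(lam)) > 1e-6:
            continue
        if exclude_origin and abs(lam) < 1e-8:
            continue
        # keep roots inside (a slightly expanded) search box
        if not (re_range[0] - 1 <= lam.real <= re_range[1] + 1):
            continue
        if all(abs(lam - r) > 1e-6 for r in roots):
            roots.append(lam)
    if not roots:
        return None
    return max(roots, key=lambda r: r.real)
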