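"""Outcome maps over the plane of mean maturation delays (p1/beta1, p2/beta2).

Each grid cell fixes the delay ratio ``p_i / beta_i`` of both species,
derives ``beta_i`` from the (fixed, integer) shapes, places the truncation
shift at a chosen percentile of each kernel, and classifies the outcome
analytically — no ODE integration, so a 200 x 200 scan runs in well under a
second.  A companion map evaluates the same cells in the discrete-delay
limit (shape -> infinity at fixed delay ratio), whose frontiers are the
white overlay curves of the corresponding phase diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import equilibria
from .chain_model import SpeciesParams
from .equilibria import LABELS
from .errors import DomainError
from .kernels import percentile_shift

__all__ = ["RegionMap", "scan", "region_areas", "write_region_csv", "write_region_image"]

_RATE_KEYS = ("r", "m", "mu", "a", "b")


def _rates(params) -> dict:
    """Accept a SpeciesParams (kernel ignored) or a mapping with keys r, m, mu, a, b."""
    if isinstance(params, SpeciesParams):
        return {k: getattr(params, k) for k in _RATE_KEYS}
    out = {k: float(params[k]) for k in _RATE_KEYS}
    return out


@dataclass
class RegionMap:
    """Grid of outcome labels over the two delay-ratio axes.

    ``labels[i, j]`` is the integer-coded outcome at
    ``(axis1[i], axis2[j])``; ``limit_labels`` the discrete-delay-limit
    outcome at the same cell.  Codes index :data:`delaylv.equilibria.LABELS`.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    labels: np.ndarray
    limit_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def label_names(self) -> tuple[str, ...]:
        return LABELS


def _species_axis(rates: dict, p: int, ratios: np.ndarray, percentile: float):
    """Per-axis derived quantities for one species: beta, delta, tau, A.

    With the shift at the q-th percentile the truncation constant is q by
    construction, so ``tau = q * ratio`` exactly.
    """
    beta = p / ratios
    delta = np.array([percentile_shift(p, b, percentile) for b in beta])
    tau = percentile * ratios
    A = math.log(rates["m"] / rates["r"]) + p * np.log((beta + rates["mu"]) / beta)
    return beta, delta, tau, A


def _classify_grid(rates1, rates2, A1, delta1, A2, delta2):
    """Vectorised outcome codes for all axis combinations (axis1 x axis2)."""
    a1, b1 = rates1["a"], rates1["b"]
    a2, b2 = rates2["a"], rates2["b"]
    det = a1 * a2 - b1 * b2
    rho = delta1[:, None] / delta2[None, :]
    A1g = A1[:, None]
    A2g = A2[None, :]
    g1 = rho * b2 * A2g - a2 * A1g
    g2 = b1 * A1g / rho - a1 * A2g
    return equilibria.outcome_grid(A1g, A2g, g1, g2, det)


def scan(
    fixed_params1,
    fixed_params2,
    p1: int = 1,
    p2: int = 1,
    ratio_range: tuple[float, float] = (0.1, 8.0),
    n_grid: int = 200,
    percentile: float = 0.99,
) -> RegionMap:
    """Classify outcomes over a grid of mean-delay ratios.

    ``fixed_params*`` hold the rates ``r, m, mu, a, b`` of each species
    (a mapping, or a :class:`SpeciesParams` whose kernel is ignored);
    ``p1, p2`` are the kernel shapes held fixed over the scan.
    """
    if not (ratio_range[0] > 0 and ratio_range[1] > ratio_range[0]):
        raise DomainError(f"ratio_range must be positive and increasing, got {ratio_range}")
    if n_grid < 2:
        raise DomainError(f"n_grid must be >= 2, got {n_grid}")
    r1 = _rates(fixed_params1)
    r2 = _rates(fixed_params2)
    ratios1 = np.linspace(*ratio_range, n_grid)
    ratios2 = np.linspace(*ratio_range, n_grid)

    _, delta1, _, A1 = _species_axis(r1, p1, ratios1, percentile)
    _, delta2, _, A2 = _species_axis(r2, p2, ratios2, percentile)
    labels = _classify_grid(r1, r2, A1, delta1, A2, delta2)

    # discrete-delay limit: alpha -> 1, tau -> ratio, delta -> ratio,
    # A -> ln(m/r) + mu * ratio
    A1_lim = math.log(r1["m"] / r1["r"]) + r1["mu"] * ratios1
    A2_lim = math.log(r2["m"] / r2["r"]) + r2["mu"] * ratios2
    limit_labels = _classify_grid(r1, r2, A1_lim, ratios1, A2_lim, ratios2)

    meta = {
        "species1": r1,
        "species2": r2,
        "p1": p1,
        "p2": p2,
        "ratio_range": tuple(ratio_range),
        "n_grid": n_grid,
        "percentile": percentile,
    }
    return RegionMap(axis1=ratios1, axis2=ratios2, labels=labels,
                     limit_labels=limit_labels, meta=meta)


def region_areas(region_map: RegionMap, which: str = "labels") -> dict[str, float]:
    """Fraction of grid cells carrying each outcome label (fractions sum to 1)."""
    mat = getattr(region_map, which)
    total = mat.size
    return {name: float(np.sum(mat == code)) / total for code, name in enumerate(LABELS)}


def write_region_csv(region_map: RegionMap, path) -> None:
    """Long-format CSV: ratio1, ratio2, label, limit_label."""
    i, j = np.meshgrid(
        np.arange(len(region_map.axis1)), np.arange(len(region_map.axis2)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "ratio1": region_map.axis1[i.ravel()],
            "ratio2": region_map.axis2[j.ravel()],
            "label": [LABELS[c] for c in region_map.labels.ravel()],
            "limit_label": [LABELS[c] for c in region_map.limit_labels.ravel()],
        }
    )
    df.to_csv(path, index=False)


def write_region_image(region_map: RegionMap, path, overlay_limit: bool = True) -> None:
    """Raster of the outcome map, oriented with ratio1 on x and ratio2 on y.

    Optionally overlays the discrete-delay-limit frontiers as white contours
    (requires matplotlib).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    # black, blue (sp1), red (sp2), brown (coexistence), tan (bistable), grey
    cmap = ListedColormap(["#000000", "#2166ac", "#b2182b", "#8c510a", "#dfc27d", "#999999"])
    fig, ax = plt.subplots(figsize=(5, 4.5))
    extent = (
        region_map.axis1[0], region_map.axis1[-1],
        region_map.axis2[0], region_map.axis2[-1],
    )
    ax.imshow(
        region_map.labels.T, origin="lower", extent=extent, aspect="auto",
        cmap=cmap, vmin=-0.5, vmax=5.5, interpolation="nearest",
    )
    if overlay_limit:
        X, Y = np.meshgrid(region_map.axis1, region_map.axis2, indexing="ij")
        ax.contour(X, Y, region_map.limit_labels, colors="white", linewidths=0.8,
                   levels=np.arange(0.5, 5.5))
    ax.set_xlabel("p1 / beta1")
    ax.set_ylabel("p2 / beta2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
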