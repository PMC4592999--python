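"""Genetic map-function arithmetic and the marker + pseudomarker evaluation grid.

Map functions convert between recombination fraction ``r`` (per meiosis,
between two loci) and genetic distance in centimorgans.  The Carter–Falconer
map function, which assumes strong positive crossover interference as observed
in the mouse, is the package default; Haldane (no interference) and Kosambi
are provided for comparison and simulation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_io import GeneticMap

MAP_FUNCTIONS = ("carter_falconer", "haldane", "kosambi")


def carter_falconer_cM(r: float) -> float:
    """Carter–Falconer map distance (cM) for recombination fraction ``r``.

    d = 100 * (1/4) * [ (1/2) * ln((1+2r)/(1-2r)) + arctan(2r) ]

    Defined for ``0 <= r < 0.5``; strictly increasing, 0 at 0, and divergent
    as ``r -> 0.5``.
    """
    r = float(r)
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 100.0 * 0.25 * (0.5 * np.log1p(4 * r / (1 - 2 * r)) + np.arctan(2 * r))


def haldane_cM(r: float) -> float:
    """Haldane map distance (cM): d = -50 * ln(1 - 2r)."""
    r = float(r)
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * np.log1p(-2 * r)


def kosambi_cM(r: float) -> float:
    """Kosambi map distance (cM): d = 25 * ln((1+2r)/(1-2r))."""
    r = float(r)
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


_FORWARD = {
    "carter_falconer": carter_falconer_cM,
    "haldane": haldane_cM,
    "kosambi": kosambi_cM,
}


def map_cM(r: float, map_function: str = "carter_falconer") -> float:
    """Forward map function dispatch: recombination fraction -> cM."""
    try:
        return _FORWARD[map_function](r)
    except KeyError:
        raise ValueError(f"unknown map function {map_function!r}") from None


def inverse_map_r(d: float, map_function: str = "carter_falconer") -> float:
    """Recombination fraction for a map distance of ``d`` cM.

    Haldane and Kosambi invert in closed form; Carter–Falconer has no closed
    inverse and is solved by bracketed root finding to 1e-12.
    """
    d = float(d)
    if d < 0:
        raise ValueError(f"map distance must be non-negative, got {d}")
    if d == 0:
        return 0.0
    if map_function == "haldane":
        return 0.5 * -np.expm1(-2 * d / 100.0)
    if map_function == "kosambi":
        return 0.5 * np.tanh(2 * d / 100.0)
    if map_function != "carter_falconer":
        raise ValueError(f"unknown map function {map_function!r}")
    hi = 0.5 - 1e-15
    if carter_falconer_cM(hi) <= d:  # numerically unreachable distance
        return hi
    return brentq(lambda r: carter_falconer_cM(r) - d, 0.0, hi, xtol=1e-12)


@dataclass
class PositionGrid:
    """Ordered marker + pseudomarker positions per chromosome.

    ``kinds`` holds ``"marker"`` / ``"pseudomarker"`` per position and
    ``marker_index`` the index into the map's marker list (or -1 for
    pseudomarkers).
    """

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    kinds: dict[str, np.ndarray]
    marker_index: dict[str, np.ndarray]
    max_spacing: float

    def n_positions(self, chromosome: str) -> int:
        return len(self.positions[chromosome])

    def marker_mask(self, chromosome: str) -> np.ndarray:
        return self.kinds[chromosome] == "marker"


def build_grid(gmap: GeneticMap, max_spacing_cM: float = 0.5) -> PositionGrid:
    """Insert evenly spaced pseudomarkers so no grid gap exceeds ``max_spacing_cM``.

    Between adjacent markers separated by gap ``g``, ``ceil(g / max_spacing) - 1``
    pseudomarkers are placed at even offsets; markers themselves are kept
    exactly.  Coincident markers (gap 0) stay as distinct grid positions in
    map order.
    """
    if max_spacing_cM <= 0:
        raise ValueError("max_spacing_cM must be positive")
    positions: dict[str, np.ndarray] = {}
    kinds: dict[str, np.ndarray] = {}
    marker_index: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosome_names():
        midx = gmap.chromosome_index(chrom)
        mpos = gmap.positions[midx]
        pos: list[float] = []
        kind: list[str] = []
        src: list[int] = []
        for k, (mi, p) in enumerate(zip(midx, mpos)):
            pos.append(float(p))
            kind.append("marker")
            src.append(int(mi))
            if k + 1 < len(mpos):
                gap = float(mpos[k + 1] - p)
                if gap > 0:
                    n_pseudo = int(np.ceil(gap / max_spacing_cM)) - 1
                    for j in range(1, n_pseudo + 1):
                        pos.append(float(p + gap * j / (n_pseudo + 1)))
                        kind.append("pseudomarker")
                        src.append(-1)
        positions[chrom] = np.array(pos)
        kinds[chrom] = np.array(kind, dtype=object)
        marker_index[chrom] = np.array(src, dtype=int)
    return PositionGrid(
        chromosomes=gmap.chromosome_names(),
        positions=positions,
        kinds=kinds,
        marker_index=marker_index,
        max_spacing=float(max_spacing_cM),
    )


def nearest_position(grid: PositionGrid, chromosome: str, position_cM: float) -> int:
    """Index of the grid position on ``chromosome`` nearest to ``position_cM``.

    Ties at exact midpoints break toward the lower (proximal) index, so the
    result is deterministic and independent of grid construction order.
    """
    if chromosome not in grid.positions:
        raise KeyError(f"chromosome {chromosome!r} not in grid")
    d = np.abs(grid.positions[chromosome] - float(position_cM))
    return int(np.argmin(d))  # argmin returns the first (lower) index on ties
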