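"""Rectangular tank geometries for the three flow scenarios.

All scenarios live on a uniform MAC grid: ``nx x ny`` nodes spanning the
tank, cells in between.  The three tags correspond to the paradigmatic tank
flows the simulator supports:

``cavity``
    10 m x 10 m lid-driven cavity, upper wall translating in +x.
``channel``
    40 m x 5 m channel, Poiseuille inflow at x = +20 m toward -x.
``double_gyre``
    10 m x 5 m cavity whose left and right walls translate in +y,
    producing two counter-rotating gyres split at x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCENARIOS = ("cavity", "channel", "double_gyre")

#: default grid spacing shared by all scenarios [m]
DEFAULT_SPACING = 0.125


@dataclass(frozen=True)
class TankGeometry:
    """Rectangular tank with a uniform node lattice.

    Parameters
    ----------
    x_min, x_max, y_min, y_max : float
        Tank extent in metres.
    nx, ny : int
        Number of grid *nodes* along x and y (cells are ``nx-1 x ny-1``).
    scenario : str
        One of :data:`SCENARIOS`.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int
    scenario: str = "cavity"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("need at least 3 nodes per direction")
        if not np.isclose(self.dx, self.dy, rtol=1e-10):
            raise ValueError(f"grid spacing must be uniform (dx={self.dx}, dy={self.dy})")

    # -- spacings -----------------------------------------------------
    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.nx - 1)

    @property
    def dy(self) -> float:
        return (self.y_max - self.y_min) / (self.ny - 1)

    @property
    def lx(self) -> float:
        return self.x_max - self.x_min

    @property
    def ly(self) -> float:
        return self.y_max - self.y_min

    # -- coordinate arrays -------------------------------------------
    @property
    def x_nodes(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.nx)

    @property
    def y_nodes(self) -> np.ndarray:
        return self.y_min + self.dy * np.arange(self.ny)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + self.dx * (0.5 + np.arange(self.nx - 1))

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + self.dy * (0.5 + np.arange(self.ny - 1))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (np.asarray(x) >= self.x_min)
            & (np.asarray(x) <= self.x_max)
            & (np.asarray(y) >= self.y_min)
            & (np.asarray(y) <= self.y_max)
        )

    @classmethod
    def for_scenario(cls, scenario: str, spacing: float = DEFAULT_SPACING) -> "TankGeometry":
        """Default tank for a scenario at a common grid spacing.

        Channel: 40 m x 5 m on 321 x 41 nodes.  Cavity: 10 m x 10 m.
        Double gyre: 10 m x 5 m.  All at 0.125 m spacing by default.
        """
        if scenario == "cavity":
            lx, ly = 10.0, 10.0
            x0, y0 = 0.0, 0.0
        elif scenario == "channel":
            lx, ly = 40.0, 5.0
            x0, y0 = -20.0, 0.0
        elif scenario == "double_gyre":
            lx, ly = 10.0, 5.0
            x0, y0 = -5.0, 0.0
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        nx = int(round(lx / spacing)) + 1
        ny = int(round(ly / spacing)) + 1
        return cls(x0, x0 + lx, y0, y0 + ly, nx, ny, scenario)
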