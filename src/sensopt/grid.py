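"""Sensor-grid geometry for a greenhouse monitoring array.

The default layout mirrors a strawberry greenhouse instrumented with 56
2-in-1 temperature/humidity nodes arranged in 8 lettered columns (A-H) and 7
numbered rows, spaced 3 m horizontally and 1 m vertically.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field


@dataclass(frozen=True)
class SensorGrid:
    """Rectangular layout of sensor nodes with physical coordinates.

    Parameters
    ----------
    columns : tuple of str
        Ordered column labels (default ``("A", ..., "H")``).
    rows : tuple of int
        Ordered row indices (default ``(1, ..., 7)``).
    horizontal_spacing : float
        Distance between adjacent columns, metres (default 3).
    vertical_spacing : float
        Distance between adjacent rows, metres (default 1).

    Node identifiers are formed as column label + row index, e.g. ``"A1"``.
    """

    columns: tuple[str, ...] = tuple(string.ascii_uppercase[:8])
    rows: tuple[int, ...] = tuple(range(1, 8))
    horizontal_spacing: float = 3.0
    vertical_spacing: float = 1.0

    def __post_init__(self) -> None:
        if not self.columns or not self.rows:
            raise ValueError("grid needs at least one column and one row")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column labels")
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate row indices")
        if self.horizontal_spacing <= 0 or self.vertical_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def nodes(self) -> list[str]:
        """Node ids in grid order: A1, A2, ..., A7, B1, ... H7."""
        return [f"{c}{r}" for c in self.columns for r in self.rows]

    @property
    def n_nodes(self) -> int:
        return len(self.columns) * len(self.rows)

    def coordinates(self) -> dict[str, tuple[float, float]]:
        """Physical (x, y) position of every node in metres."""
        coords = {}
        for ci, c in enumerate(self.columns):
            for ri, r in enumerate(self.rows):
                coords[f"{c}{r}"] = (
                    ci * self.horizontal_spacing,
                    ri * self.vertical_spacing,
                )
        return coords

    def __contains__(self, node_id: str) -> bool:
        return node_id in set(self.nodes)
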