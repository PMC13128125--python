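"""Planar observation windows and marked point patterns.

Coordinates are in micrometres throughout: the natural scale of the
microscopy fields the spatial statistics operate on (windows of roughly
185-255 µm, bacterial cells of ~1 µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Window:
    """Rectangular observation window [xmin, xmax] x [ymin, ymax] in µm."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("window must satisfy xmax > xmin and ymax > ymin")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def short_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge (µm)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return np.minimum.reduce(
            [x - self.xmin, self.xmax - x, y - self.ymin, self.ymax - y]
        )

    @classmethod
    def square(cls, side: float) -> "Window":
        return cls(0.0, float(side), 0.0, float(side))


@dataclass
class PointPattern:
    """A planar point pattern with optional species marks and site metadata.

    ``points`` is an (n, 2) float array of (x, y) in µm, all inside
    ``window``. ``marks`` is an optional length-n array of species labels.
    ``meta`` carries free-form site information (e.g., image id, tip/base,
    center/epithelium).
    """

    window: Window
    points: np.ndarray
    marks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float).reshape(-1, 2)
        self.points = pts
        if not np.all(self.window.contains(pts[:, 0], pts[:, 1])):
            raise ValueError("all points must lie inside the window")
        if self.marks is not None:
            marks = np.asarray(self.marks)
            if len(marks) != len(pts):
                raise ValueError("marks length must equal number of points")
            self.marks = marks

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def intensity(self) -> float:
        """Naive constant intensity n / |W| (points per µm²)."""
        return self.n / self.window.area

    def subset(self, mask: np.ndarray) -> "PointPattern":
        mask = np.asarray(mask, bool)
        return PointPattern(
            window=self.window,
            points=self.points[mask],
            marks=None if self.marks is None else self.marks[mask],
            meta=dict(self.meta),
        )


def write_pattern(pattern: PointPattern, path: str | Path) -> None:
    """Write a pattern as delimited text with '#'-prefixed window header."""
    path = Path(path)
    df = pd.DataFrame({"x_um": pattern.x, "y_um": pattern.y})
    df["species"] = pattern.marks if pattern.marks is not None else ""
    df["image_id"] = pattern.meta.get("image_id", "")
    df["site"] = pattern.meta.get("site", "")
    w = pattern.window
    header = (
        f"# window xmin={w.xmin!r} xmax={w.xmax!r} ymin={w.ymin!r} ymax={w.ymax!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_pattern(path: str | Path) -> PointPattern:
    """Read a pattern written by :func:`write_pattern`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# window"):
            raise ValueError("missing '# window' header line")
        kv = dict(tok.split("=") for tok in first.split()[2:])
        window = Window(**{k: float(v) for k, v in kv.items()})
        df = pd.read_csv(fh)
    marks = None
    if "species" in df and df["species"].notna().any():
        marks = df["species"].to_numpy()
    meta = {}
    for col in ("image_id", "site"):
        if col in df and df[col].notna().any():
            vals = df[col].dropna().unique()
            if len(vals) == 1:
                meta[col] = vals[0]
    return PointPattern(
        window=window,
        points=np.column_stack([df["x_um"].to_numpy(), df["y_um"].to_numpy()]),
        marks=marks,
        meta=meta,
    )
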