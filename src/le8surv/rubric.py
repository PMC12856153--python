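"""Versioned scoring rubric for the eight cardiovascular-health components.

The band thresholds are shipped as a plain-text CSV
(``data/le8_rubric_v1.csv``) so they are auditable and swappable: each row
is either a half-open numeric band ``[lower, upper) -> points`` on a named
input variable, a categorical rule, a treatment-modifier deduction, or a
diet quartile->points mapping.  Points follow the published AHA Life's
Essential 8 scoring tables; physical activity is expressed in MET-min/week
(AHA minutes-of-moderate-activity cut-points multiplied by 4 MET, matching
IPAQ-derived activity volumes).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RUBRIC_RESOURCE = "le8_rubric_v1.csv"


@dataclass(frozen=True)
class BandTable:
    """Piecewise-constant lookup: points for x in [lower_i, upper_i)."""

    lower: np.ndarray
    upper: np.ndarray
    points: np.ndarray

    def lookup(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, np.nan)
        for lo, hi, pt in zip(self.lower, self.upper, self.points):
            out = np.where((x >= lo) & (x < hi), pt, out)
        return out


@dataclass(frozen=True)
class Rubric:
    """Parsed scoring rubric: band tables keyed by (component, variable),
    categorical points, deductions, and diet quartile points."""

    bands: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    deductions: dict = field(default_factory=dict)
    diet_quartile_points: tuple = (0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0)
    version: str = DEFAULT_RUBRIC_RESOURCE


def load_rubric(source: str | None = None) -> Rubric:
    """Load a rubric CSV; ``source=None`` loads the packaged default."""
    if source is None:
        ref = importlib.resources.files("le8surv").joinpath(
            "data", DEFAULT_RUBRIC_RESOURCE
        )
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
        version = DEFAULT_RUBRIC_RESOURCE
    else:
        df = pd.read_csv(source)
        version = str(source)

    bands: dict = {}
    categories: dict = {}
    deductions: dict = {}
    diet_points = [0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0]
    for (comp, key), grp in df[df["kind"] == "band"].groupby(["component", "key"]):
        bands[(comp, key)] = BandTable(
            lower=grp["lower"].astype(float).to_numpy(),
            upper=grp["upper"].astype(float).to_numpy(),
            points=grp["points"].astype(float).to_numpy(),
        )
    for _, row in df[df["kind"] == "category"].iterrows():
        categories[(row["component"], row["key"])] = float(row["points"])
    for _, row in df[df["kind"] == "deduction"].iterrows():
        deductions[row["component"]] = float(row["points"])
    qp = df[df["kind"] == "quartile_points"].sort_values("key")
    if len(qp):
        diet_points = [float(p) for p in qp["points"]]
    return Rubric(
        bands=bands,
        categories=categories,
        deductions=deductions,
        diet_quartile_points=tuple(diet_points),
        version=version,
    )


_default_rubric: Rubric | None = None


def default_rubric() -> Rubric:
    global _default_rubric
    if _default_rubric is None:
        _default_rubric = load_rubric(None)
    return _default_rubric
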