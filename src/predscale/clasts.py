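"""Thin-section clast morphometrics: roundness, sphericity, size, summaries.

Shape metrics follow the classical 2-D grain conventions: Wadell roundness
R = mean(r_i / r_max) over measured corner radii of curvature (r_max the
radius of the maximal inscribed circle), Krumbein-Sloss sphericity
psi = D_min / D_max, and clast size S = (D_min + D_max) / 2.  Inputs are
measured radii/dimensions in mm (CSV); corner detection from images is out
of scope.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClastRecord",
    "wadell_roundness",
    "sphericity",
    "clast_size",
    "AssemblageSummary",
    "summarize",
    "read_clast_csv",
    "write_clast_csv",
]

CLAST_CLASSES = ("lithic", "mineral")


@dataclasses.dataclass(frozen=True)
class ClastRecord:
    """One measured fragment; lengths in mm, class 'lithic' or 'mineral'."""

    id: str
    clast_class: str
    corner_radii: tuple[float, ...]
    r_max: float
    d_min: float
    d_max: float
    colour: str = ""
    composition: str = ""

    def __post_init__(self):
        if self.clast_class not in CLAST_CLASSES:
            raise ValueError(f"class must be one of {CLAST_CLASSES}, got {self.clast_class!r}")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        for r in self.corner_radii:
            if r <= 0:
                raise ValueError("corner radii must be positive")
            if r > self.r_max + 1e-12:
                raise ValueError(f"corner radius {r} exceeds inscribed radius {self.r_max}")
        if not 0 < self.d_min <= self.d_max:
            raise ValueError(f"need 0 < d_min <= d_max, got ({self.d_min}, {self.d_max})")


def wadell_roundness(record: ClastRecord) -> float:
    """Mean corner-to-inscribed radius ratio, in (0, 1]."""
    if not record.corner_radii:
        raise ValueError(f"clast {record.id}: no corner radii measured")
    r = np.asarray(record.corner_radii)
    return float(np.mean(r / record.r_max))


def sphericity(record: ClastRecord) -> float:
    """Krumbein-Sloss sphericity d_min/d_max, in (0, 1]."""
    return record.d_min / record.d_max


def clast_size(record: ClastRecord) -> float:
    """Average cross-sectional dimension (d_min + d_max)/2, mm."""
    return 0.5 * (record.d_min + record.d_max)


@dataclasses.dataclass
class AssemblageSummary:
    n_by_class: dict[str, int]
    size_mean: dict[str, float]
    size_min: dict[str, float]
    size_max: dict[str, float]
    roundness_mean: dict[str, float]
    sphericity_mean: dict[str, float]
    composition_pct: dict[str, dict[str, float]]  # per class
    colour_pct: dict[str, dict[str, float]]  # per class
    matrix_framework_ratio: tuple[float, float] | None  # normalized to sum 100

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.matrix_framework_ratio is not None:
            d["matrix_framework_ratio"] = list(self.matrix_framework_ratio)
        return d


def _pct(labels: Sequence[str]) -> dict[str, float]:
    labels = [l.strip().lower() for l in labels if l and l.strip()]
    if not labels:
        return {}
    counts = Counter(labels)
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in sorted(counts.items())}


def summarize(
    records: Sequence[ClastRecord],
    matrix_area: float | None = None,
    framework_area: float | None = None,
) -> AssemblageSummary:
    """Per-class counts, size/shape statistics and composition percentages.

    Colour and composition labels are grouped case-insensitively.  The
    matrix:framework ratio is computed from supplied mapped areas and
    normalised to sum to 100.
    """
    if not records:
        raise ValueError("no clast records")
    ratio = None
    if matrix_area is not None or framework_area is not None:
        ma = float(matrix_area or 0.0)
        fa = float(framework_area or 0.0)
        if ma < 0 or fa < 0:
            raise ValueError("areas must be nonnegative")
        if ma + fa == 0:
            raise ValueError("matrix and framework areas are both zero")
        ratio = (100.0 * ma / (ma + fa), 100.0 * fa / (ma + fa))

    n_by, smean, smin, smax, rmean, psimean, comp, col = {}, {}, {}, {}, {}, {}, {}, {}
    for cls in CLAST_CLASSES:
        sub = [r for r in records if r.clast_class == cls]
        n_by[cls] = len(sub)
        if not sub:
            continue
        sizes = np.array([clast_size(r) for r in sub])
        smean[cls] = float(sizes.mean())
        smin[cls] = float(sizes.min())
        smax[cls] = float(sizes.max())
        with_corners = [r for r in sub if r.corner_radii]
        if with_corners:
            rmean[cls] = float(np.mean([wadell_roundness(r) for r in with_corners]))
        psimean[cls] = float(np.mean([sphericity(r) for r in sub]))
        comp[cls] = _pct([r.composition for r in sub])
        col[cls] = _pct([r.colour for r in sub])
    return AssemblageSummary(
        n_by_class=n_by, size_mean=smean, size_min=smin, size_max=smax,
        roundness_mean=rmean, sphericity_mean=psimean,
        composition_pct=comp, colour_pct=col, matrix_framework_ratio=ratio,
    )


# -- CSV plumbing: corner radii ';'-separated in one column ------------------


def read_clast_csv(path_or_buf) -> list[ClastRecord]:
    df = pd.read_csv(path_or_buf, dtype={"corner_radii": str}, keep_default_na=False,
                     float_precision="round_trip")
    records = []
    for row in df.to_dict("records"):
        raw = row.get("corner_radii", "")
        radii = tuple(float(t) for t in str(raw).split(";") if t.strip()) if raw else ()
        records.append(
            ClastRecord(
                id=str(row["id"]),
                clast_class=str(row.get("class", row.get("clast_class", ""))),
                corner_radii=radii,
                r_max=float(row["r_max"]),
                d_min=float(row["d_min"]),
                d_max=float(row["d_max"]),
                colour=str(row.get("colour", "")),
                composition=str(row.get("composition", "")),
            )
        )
    return records


def write_clast_csv(records: Sequence[ClastRecord], path_or_buf=None) -> str | None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "class": [r.clast_class for r in records],
            "corner_radii": [";".join(repr(v) for v in r.corner_radii) for r in records],
            # repr round-trips floats exactly; pandas' default float format does not
            "r_max": [repr(r.r_max) for r in records],
            "d_min": [repr(r.d_min) for r in records],
            "d_max": [repr(r.d_max) for r in records],
            "colour": [r.colour for r in records],
            "composition": [r.composition for r in records],
        }
    )
    return df.to_csv(path_or_buf, index=False)
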