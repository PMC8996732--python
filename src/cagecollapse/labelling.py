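"""Shape-persistence labelling from precomputed geometry descriptors.

A [4+6] tetrahedral cage should expose four windows around one internal
cavity.  Labels are assigned from descriptors (window count, window
diameters, cavity diameter) computed upstream on optimised 3D structures:

* wrong window count            -> "collapsed"
* alpha < 0.035 and cavity > 1 A -> "not collapsed"
* otherwise                     -> "undetermined"

``alpha`` is a window-asymmetry score.  Its default here is the
coefficient of variation (population standard deviation / mean) of the
window diameters — a reconstruction chosen for its scale invariance, not
an asserted literature formula — and any user-supplied asymmetry function
may replace it.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryDescriptors",
    "compute_alpha",
    "assign_label",
    "label_dataset",
    "LabelSummary",
]

AlphaFunction = Callable[[Sequence[float]], float]


@dataclass(frozen=True)
class GeometryDescriptors:
    """Window/cavity geometry of one cage, in Angstrom."""

    n_windows: int
    window_diameters: tuple[float, ...]
    cavity_diameter: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.n_windows < 0:
            raise ValueError("window count must be >= 0")
        if any(d < 0 for d in self.window_diameters):
            raise ValueError("window diameters must be >= 0")
        if self.window_diameters and len(self.window_diameters) != self.n_windows:
            raise ValueError(
                f"{len(self.window_diameters)} diameters for "
                f"{self.n_windows} windows"
            )
        if self.cavity_diameter is not None and self.cavity_diameter < 0:
            raise ValueError("cavity diameter must be >= 0")


def compute_alpha(
    window_diameters: Sequence[float],
    alpha_function: AlphaFunction | None = None,
) -> float:
    """Window-asymmetry score; default: coefficient of variation.

    Uses the population standard deviation (the four windows of a
    tetrahedral cage are the complete set, not a sample).  Scale
    invariant: doubling all diameters leaves alpha unchanged.
    """
    if alpha_function is not None:
        return float(alpha_function(window_diameters))
    d = np.asarray(window_diameters, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 window diameters")
    if np.any(d <= 0):
        raise ValueError("window diameters must be > 0")
    mean = d.mean()
    if mean == 0:
        raise ValueError("zero mean window diameter")
    return float(d.std(ddof=0) / mean)


def assign_label(
    d: GeometryDescriptors,
    expected_windows: int = 4,
    alpha_threshold: float = 0.035,
    cavity_min: float = 1.0,
    alpha_function: AlphaFunction | None = None,
) -> str:
    """Label one cage from its geometry.

    Strict inequalities at both thresholds: alpha exactly at the
    threshold, or a cavity of exactly ``cavity_min``, is "undetermined".
    """
    if d.n_windows != expected_windows:
        return "collapsed"
    alpha = d.alpha
    if alpha is None:
        alpha = compute_alpha(d.window_diameters, alpha_function)
    if d.cavity_diameter is None:
        raise ValueError(
            "cavity diameter required when the window count matches"
        )
    if alpha < alpha_threshold and d.cavity_diameter > cavity_min:
        return "not collapsed"
    return "undetermined"


@dataclass
class LabelSummary:
    """Class counts and percentages over a labelled descriptor table."""

    counts: dict[str, int] = field(default_factory=dict)
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}


def label_dataset(
    descriptors: pd.DataFrame,
    expected_windows: int = 4,
    alpha_threshold: float = 0.035,
    cavity_min: float = 1.0,
    alpha_function: AlphaFunction | None = None,
) -> tuple[pd.DataFrame, LabelSummary]:
    """Apply the labelling rule row-wise to a descriptor table.

    Expects columns ``cage_id``, ``n_windows``, ``window_diameters``
    (semicolon-separated Angstrom values) and ``cavity_diameter``.
    Malformed rows are reported with their row number in the summary and
    skipped; processing continues.
    """
    required = {"cage_id", "n_windows", "window_diameters", "cavity_diameter"}
    missing = required - set(descriptors.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    summary = LabelSummary(
        counts={"collapsed": 0, "not collapsed": 0, "undetermined": 0}
    )
    out_rows = []
    for row_no, row in enumerate(descriptors.itertuples(index=False)):
        try:
            raw = str(row.window_diameters).strip()
            diameters = tuple(
                float(x) for x in raw.split(";") if x.strip()
            ) if raw else ()
            cavity = row.cavity_diameter
            cavity = None if pd.isna(cavity) else float(cavity)
            desc = GeometryDescriptors(
                n_windows=int(row.n_windows),
                window_diameters=diameters,
                cavity_diameter=cavity,
            )
            label = assign_label(
                desc,
                expected_windows=expected_windows,
                alpha_threshold=alpha_threshold,
                cavity_min=cavity_min,
                alpha_function=alpha_function,
            )
        except (ValueError, TypeError) as exc:
            summary.errors.append((row_no, str(exc)))
            continue
        summary.counts[label] += 1
        out_rows.append({"cage_id": row.cage_id, "label": label})
    return pd.DataFrame(out_rows, columns=["cage_id", "label"]), summary
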