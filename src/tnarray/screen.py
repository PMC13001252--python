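"""Crystal-violet microplate screen: normalization, fold hits, t-tests.

Biofilm signal per well is crystal-violet absorbance (OD540) normalized by
culture density (OD660).  A mutant is called a hit when its replicate-mean
normalized signal departs from the plate mean by at least a fold factor
(default 1.5x) in either direction; candidate hits are then compared to a
control by a two-sided unpaired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenPlate",
    "normalize_plate",
    "call_fold_hits",
    "ttest_vs_control",
    "read_plate_csv",
]

_ROWS = list("ABCDEFGH")
_COLS = list(range(1, 13))


@dataclass
class ScreenPlate:
    """One plate read in one replicate: OD540 and OD660 grids plus controls.

    ``od540`` and ``od660`` are DataFrames with row labels (A-H) as index
    and column numbers as columns.  ``control_wells`` holds (row, col)
    labels of designated control wells.
    """

    plate_id: str
    replicate_id: str
    od540: pd.DataFrame
    od660: pd.DataFrame
    control_wells: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.od540.index.equals(self.od660.index) or not self.od540.columns.equals(
            self.od660.columns
        ):
            raise ValueError("OD540 and OD660 grids must share shape and labels")
        if (self.od540.to_numpy() < 0).any() or (self.od660.to_numpy() < 0).any():
            raise ValueError("OD values must be non-negative")


def normalize_plate(plate: ScreenPlate) -> pd.DataFrame:
    """Per-well OD540/OD660 ratio; wells with OD660 <= 0 are masked (NaN)."""
    od660 = plate.od660.to_numpy(dtype=float)
    od540 = plate.od540.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(od660 > 0, od540 / np.where(od660 > 0, od660, 1.0), np.nan)
    return pd.DataFrame(ratio, index=plate.od540.index, columns=plate.od540.columns)


def call_fold_hits(
    plates: Sequence[ScreenPlate],
    fold: float = 1.5,
    include_controls_in_mean: bool = False,
) -> pd.DataFrame:
    """Call fold-change hits across replicates of one plate layout.

    For each well, the normalized signal is averaged across replicates (m);
    the plate mean mu is the mean over unmasked wells per replicate
    (excluding designated controls unless ``include_controls_in_mean``),
    averaged across replicates.  Direction: ``increased`` if m >= fold*mu,
    ``decreased`` if m <= mu/fold, else ``none``.  Masked-everywhere wells
    are dropped.
    """
    if not plates:
        raise ValueError("at least one replicate plate is required")
    if not fold > 1:
        raise ValueError("fold must be > 1")
    plate_ids = {p.plate_id for p in plates}
    if len(plate_ids) != 1:
        raise ValueError("call_fold_hits expects replicates of a single plate")
    norm = [normalize_plate(p) for p in plates]
    controls = plates[0].control_wells
    mus = []
    for p, nm in zip(plates, norm):
        vals = nm.stack(future_stack=True)
        if not include_controls_in_mean and controls:
            vals = vals.drop(labels=list(controls), errors="ignore")
        mus.append(float(vals.mean()))
    mu = float(np.mean(mus))

    stacked = pd.concat([nm.stack(future_stack=True) for nm in norm], axis=1)
    m = stacked.mean(axis=1, skipna=True)
    rows = []
    for (row, col), value in m.items():
        if np.isnan(value):
            continue
        if value >= fold * mu:
            direction = "increased"
        elif value <= mu / fold:
            direction = "decreased"
        else:
            direction = "none"
        rows.append(
            {
                "well_row": row,
                "well_col": col,
                "mean_signal": float(value),
                "plate_mean": mu,
                "fold_change": float(value / mu) if mu > 0 else np.nan,
                "direction": direction,
                "is_control": (row, col) in controls,
            }
        )
    return pd.DataFrame(rows)


def ttest_vs_control(
    mutant_values: Sequence[float],
    control_values: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided unpaired t-test of mutant vs control replicate values.

    Classic pooled-variance form by default; ``welch=True`` drops the
    equal-variance assumption.  Returns (t, p).
    """
    a = np.asarray(mutant_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read an 8 x 12 OD grid CSV (rows A-H, columns 1-12)."""
    df = pd.read_csv(path, index_col=0)
    df.index = [str(i).strip().upper() for i in df.index]
    df.columns = [int(c) for c in df.columns]
    return df
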