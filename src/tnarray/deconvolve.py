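"""Pool-count deconvolution: thresholding, SNR filtering and triangulation.

Each insertion site has a read count in every pool.  Splitting those counts
by axis gives four profiles; on each axis the true coordinate should carry
far more reads than any other.  A coordinate is accepted automatically when
its top count clears an absolute threshold (default 50 reads) *and* the
signal-to-noise ratio -- top count divided by the second-highest count on
that axis -- clears a ratio threshold (default 9).  Sites resolved on all
four axes get status ``auto``.

Sites failing on some axis keep per-axis candidate sets.  Because no two
mutants share a well, wells claimed by confidently placed sites can be
eliminated from other sites' candidate well sets; whenever elimination
leaves exactly one candidate well the site is placed with status
``triangulated``.  The elimination loop runs to a fixpoint.

Statuses: ``auto``, ``triangulated``, ``ambiguous`` (several candidate wells
persist, or two auto sites collided on one well), ``multilocated`` (the
profile shows two strong peaks on two or more axes -- a duplicate clone
picked into several wells), ``unresolved`` (no candidate well survives).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AXES, PoolingDesign, WellAddress
from .mapping import PoolCountMatrix

__all__ = [
    "AUTO",
    "TRIANGULATED",
    "AMBIGUOUS",
    "MULTILOCATED",
    "UNRESOLVED",
    "DeconvolutionConfig",
    "AxisProfile",
    "AxisResolution",
    "Assignment",
    "axis_profiles",
    "resolve_axis",
    "assign_first_pass",
    "triangulate",
    "deconvolve",
    "brute_force_oracle",
    "assignments_frame",
]

AUTO = "auto"
TRIANGULATED = "triangulated"
AMBIGUOUS = "ambiguous"
MULTILOCATED = "multilocated"
UNRESOLVED = "unresolved"

_ASSIGNED = (AUTO, TRIANGULATED)


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Thresholds of the deconvolution.

    primary_threshold: minimum top read count per axis (absolute filter).
    snr_threshold: minimum top/second ratio per axis (SNR filter).
    candidate_floor: minimum count for a coordinate to stay a triangulation
        candidate on an unresolved axis.
    max_rounds: cap on triangulation sweeps.
    """

    primary_threshold: int = 50
    snr_threshold: float = 9.0
    candidate_floor: int = 10
    max_rounds: int = 100

    def __post_init__(self) -> None:
        if self.primary_threshold < 1:
            raise ValueError("primary_threshold must be >= 1")
        if not self.snr_threshold > 1:
            raise ValueError("snr_threshold must be > 1")
        if self.candidate_floor > self.primary_threshold:
            raise ValueError("candidate_floor must be <= primary_threshold")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class AxisProfile:
    """Counts of one site on one axis, with top/second/SNR summaries."""

    axis: str
    counts: tuple[int, ...]  # index 0 is coordinate 1

    @property
    def top_coord(self) -> int:
        return int(np.argmax(self.counts)) + 1

    @property
    def top(self) -> int:
        return int(max(self.counts))

    @property
    def second(self) -> int:
        if len(self.counts) == 1:
            return 0
        arr = sorted(self.counts, reverse=True)
        return int(arr[1])

    @property
    def snr(self) -> float:
        if self.top == 0:
            return 0.0
        if self.second == 0:
            return math.inf
        return self.top / self.second


@dataclass(frozen=True)
class AxisResolution:
    """Outcome of thresholding one axis: a coordinate, or a candidate set."""

    axis: str
    resolved: bool
    coord: int | None
    candidates: frozenset[int]
    snr: float


@dataclass
class Assignment:
    """Resolved (or not) location of one insertion site."""

    site_id: str
    status: str
    well: WellAddress | None = None
    candidates: dict[str, frozenset[int]] = field(default_factory=dict)
    snr: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0
    note: str = ""


def axis_profiles(
    row: pd.Series | np.ndarray, design: PoolingDesign
) -> dict[str, AxisProfile]:
    """Partition one count row (design pool order) into four axis profiles."""
    values = np.asarray(row.to_numpy() if isinstance(row, pd.Series) else row)
    if len(values) != design.n_pools:
        raise ValueError(
            f"row length {len(values)} != design pool count {design.n_pools}"
        )
    profiles: dict[str, AxisProfile] = {}
    offset = 0
    for axis in AXES:
        size = design.axis_size(axis)
        profiles[axis] = AxisProfile(axis, tuple(int(v) for v in values[offset:offset + size]))
        offset += size
    return profiles


def resolve_axis(profile: AxisProfile, config: DeconvolutionConfig) -> AxisResolution:
    """Apply primary (absolute count) and secondary (SNR) thresholds to one axis.

    Resolved iff ``top >= primary_threshold`` and ``snr >= snr_threshold``
    (SNR is +inf when the runner-up count is zero; an exact tie gives SNR 1,
    hence unresolved).  Otherwise the candidate set keeps every coordinate
    with count >= max(candidate_floor, top / snr_threshold).
    """
    top, second, snr = profile.top, profile.second, profile.snr
    if top >= config.primary_threshold and snr >= config.snr_threshold and top > second:
        return AxisResolution(
            profile.axis, True, profile.top_coord, frozenset({profile.top_coord}), snr
        )
    floor = max(config.candidate_floor, top / config.snr_threshold)
    candidates = frozenset(
        i + 1 for i, c in enumerate(profile.counts) if c >= floor
    )
    return AxisResolution(profile.axis, False, None, candidates, snr)


def _site_order(matrix: PoolCountMatrix) -> list[str]:
    """Deterministic processing order: descending total reads, ties by site_id."""
    totals = matrix.counts.sum(axis=1)
    return sorted(matrix.counts.index, key=lambda s: (-int(totals[s]), s))


def _is_multilocated(
    profiles: dict[str, AxisProfile], config: DeconvolutionConfig
) -> bool:
    """Two or more axes each showing >= 2 coordinates above the primary threshold."""
    strong_axes = sum(
        1
        for p in profiles.values()
        if sum(c >= config.primary_threshold for c in p.counts) >= 2
    )
    return strong_axes >= 2


def assign_first_pass(
    matrix: PoolCountMatrix,
    design: PoolingDesign,
    config: DeconvolutionConfig | None = None,
) -> dict[str, Assignment]:
    """Threshold every site; returns assignments keyed by site_id.

    Sites resolved on all four axes become ``auto``; sites with two strong
    peaks on >= 2 axes become ``multilocated``; the rest stay ``unresolved``
    with per-axis candidate sets.  Two auto sites claiming one well are both
    demoted to ``ambiguous``.
    """
    config = config or DeconvolutionConfig()
    matrix.validate_against(design)
    assignments: dict[str, Assignment] = {}
    totals = matrix.counts.sum(axis=1)
    for site_id in matrix.counts.index:
        profiles = axis_profiles(matrix.counts.loc[site_id], design)
        res = {axis: resolve_axis(profiles[axis], config) for axis in AXES}
        a = Assignment(
            site_id=site_id,
            status=UNRESOLVED,
            candidates={axis: res[axis].candidates for axis in AXES},
            snr={axis: res[axis].snr for axis in AXES},
            total_reads=int(totals[site_id]),
        )
        if all(res[axis].resolved for axis in AXES):
            a.status = AUTO
            a.well = design.well_from_coords(
                res["WELL_COL"].coord,
                res["WELL_ROW"].coord,
                res["PLATE_COL"].coord,
                res["PLATE_ROW"].coord,
            )
        elif _is_multilocated(profiles, config):
            a.status = MULTILOCATED
            a.note = "two strong peaks on >=2 axes; likely duplicate clone"
        assignments[site_id] = a

    # demote conflicting auto assignments (shared well) to ambiguous
    by_well: dict[WellAddress, list[Assignment]] = {}
    for a in assignments.values():
        if a.status == AUTO:
            by_well.setdefault(a.well, []).append(a)
    for well, claimants in by_well.items():
        if len(claimants) > 1:
            for a in claimants:
                a.status = AMBIGUOUS
                a.well = None
                a.note = f"auto conflict on well {well}"
    return assignments


def _candidate_wells(
    a: Assignment, design: PoolingDesign, occupied: set[WellAddress]
) -> list[WellAddress]:
    """Cartesian product of per-axis candidate sets, minus occupied wells."""
    sets = [sorted(a.candidates[axis]) for axis in AXES]
    if any(not s for s in sets):
        return []
    wells = []
    for wc, wr, pc, pr in itertools.product(*sets):
        if not design.plate_occupied(pr, pc):
            continue
        w = WellAddress(pr, pc, wr, wc)
        if w not in occupied:
            wells.append(w)
    return wells


def triangulate(
    assignments: dict[str, Assignment],
    design: PoolingDesign,
    config: DeconvolutionConfig | None = None,
    matrix: PoolCountMatrix | None = None,
) -> dict[str, Assignment]:
    """Iteratively place unresolved sites by eliminating occupied wells.

    Each sweep visits unresolved sites in descending total-read order (ties
    by site_id); a site whose candidate wells minus occupied wells reduce to
    exactly one is placed (status ``triangulated``) and its well immediately
    blocks later sites.  Sweeps repeat until nothing changes or
    ``max_rounds`` is hit.  Finally, sites with several surviving candidate
    wells become ``ambiguous``, sites with none stay ``unresolved``.
    """
    config = config or DeconvolutionConfig()
    occupied = {a.well for a in assignments.values() if a.status in _ASSIGNED}
    order = sorted(
        (a for a in assignments.values() if a.status == UNRESOLVED),
        key=lambda a: (-a.total_reads, a.site_id),
    )
    changed = True
    rounds = 0
    while changed and rounds < config.max_rounds:
        changed = False
        rounds += 1
        for a in order:
            if a.status != UNRESOLVED:
                continue
            wells = _candidate_wells(a, design, occupied)
            if len(wells) == 1:
                a.status = TRIANGULATED
                a.well = wells[0]
                occupied.add(wells[0])
                changed = True
    if changed:
        warnings.warn(
            f"triangulation stopped after {config.max_rounds} rounds with pending changes",
            RuntimeWarning,
            stacklevel=2,
        )
    for a in assignments.values():
        if a.status == UNRESOLVED:
            n = len(_candidate_wells(a, design, occupied))
            if n >= 2:
                a.status = AMBIGUOUS
                a.note = f"{n} candidate wells persist"
    return assignments


def deconvolve(
    matrix: PoolCountMatrix,
    design: PoolingDesign,
    config: DeconvolutionConfig | None = None,
) -> dict[str, Assignment]:
    """Full pipeline: first-pass thresholding followed by triangulation."""
    config = config or DeconvolutionConfig()
    assignments = assign_first_pass(matrix, design, config)
    return triangulate(assignments, design, config)


# ---------------------------------------------------------------------------
# independent oracle

_ORACLE_MAX_GRID = 4


def brute_force_oracle(
    matrix: PoolCountMatrix,
    design: PoolingDesign,
    config: DeconvolutionConfig | None = None,
) -> dict[str, Assignment]:
    """Reference deconvolution by exhaustive well enumeration (small designs).

    A well is consistent for a site iff each of its four coordinates lies in
    that axis's candidate set (a resolved axis contributes a singleton).  The
    unique-elimination fixpoint is applied by re-enumerating every well each
    sweep.  Intended as an independent cross-check of
    :func:`deconvolve`; refuses plate grids larger than 4 x 4.
    """
    config = config or DeconvolutionConfig()
    if design.grid_rows > _ORACLE_MAX_GRID or design.grid_cols > _ORACLE_MAX_GRID:
        raise ValueError(
            f"oracle restricted to grids <= {_ORACLE_MAX_GRID}x{_ORACLE_MAX_GRID}"
        )
    matrix.validate_against(design)
    all_wells = list(design.iter_wells())
    totals = matrix.counts.sum(axis=1)

    def coords_of(well: WellAddress) -> dict[str, int]:
        return {
            "WELL_COL": well.well_col,
            "WELL_ROW": well.well_row,
            "PLATE_COL": well.plate_col,
            "PLATE_ROW": well.plate_row,
        }

    assignments: dict[str, Assignment] = {}
    for site_id in matrix.counts.index:
        profiles = axis_profiles(matrix.counts.loc[site_id], design)
        res = {axis: resolve_axis(profiles[axis], config) for axis in AXES}
        a = Assignment(
            site_id=site_id,
            status=UNRESOLVED,
            candidates={axis: res[axis].candidates for axis in AXES},
            snr={axis: res[axis].snr for axis in AXES},
            total_reads=int(totals[site_id]),
        )
        if all(r.resolved for r in res.values()):
            consistent = [
                w
                for w in all_wells
                if all(coords_of(w)[ax] in res[ax].candidates for ax in AXES)
            ]
            assert len(consistent) == 1
            a.status = AUTO
            a.well = consistent[0]
        elif _is_multilocated(profiles, config):
            a.status = MULTILOCATED
        assignments[site_id] = a

    by_well: dict[WellAddress, list[Assignment]] = {}
    for a in assignments.values():
        if a.status == AUTO:
            by_well.setdefault(a.well, []).append(a)
    for claimants in by_well.values():
        if len(claimants) > 1:
            for a in claimants:
                a.status = AMBIGUOUS
                a.well = None

    occupied = {a.well for a in assignments.values() if a.status in _ASSIGNED}
    order = sorted(
        (a for a in assignments.values() if a.status == UNRESOLVED),
        key=lambda a: (-a.total_reads, a.site_id),
    )

    def consistent_wells(a: Assignment) -> list[WellAddress]:
        return [
            w
            for w in all_wells
            if w not in occupied
            and all(coords_of(w)[ax] in a.candidates[ax] for ax in AXES)
        ]

    for _ in range(config.max_rounds):
        changed = False
        for a in order:
            if a.status != UNRESOLVED:
                continue
            wells = consistent_wells(a)
            if len(wells) == 1:
                a.status = TRIANGULATED
                a.well = wells[0]
                occupied.add(wells[0])
                changed = True
        if not changed:
            break
    for a in assignments.values():
        if a.status == UNRESOLVED and len(consistent_wells(a)) >= 2:
            a.status = AMBIGUOUS
    return assignments


def assignments_frame(
    assignments: dict[str, Assignment], matrix: PoolCountMatrix | None = None
) -> pd.DataFrame:
    """Tabulate assignments (site_id, position, strand, status, well, SNRs)."""
    rows = []
    for site_id in sorted(assignments):
        a = assignments[site_id]
        row = {
            "site_id": site_id,
            "status": a.status,
            "plate_row": a.well.plate_row if a.well else pd.NA,
            "plate_col": a.well.plate_col if a.well else pd.NA,
            "well_row": a.well.well_row_label if a.well else pd.NA,
            "well_col": a.well.well_col if a.well else pd.NA,
            "total_reads": a.total_reads,
            "note": a.note,
        }
        for axis in AXES:
            row[f"snr_{axis.lower()}"] = a.snr.get(axis, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("site_id")
        if matrix is not None:
            df = matrix.sites.join(df, how="right")
    return df
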