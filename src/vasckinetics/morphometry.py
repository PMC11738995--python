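"""Vessel-compartment classification, population counts and expansion stats.

Cells are counted via their nuclei; a cell is "inside" the venous
endothelium when its centroid falls within the segmented vessel surface (or
within a configurable distance tolerance of it, mirroring shortest-distance
filtering between detected spots and a segmented surface). Marker-defined
populations are tallied per compartment, and stage-to-stage expansion is
summarized as mean ± s.d. over replicate embryos with fold changes computed
as ratios of means.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import EmptyMaskError, SchemaError, UnknownMarkerError
from .io import FLAG_COLUMNS, LabelMask

__all__ = [
    "PopulationCounts",
    "TimecourseSummary",
    "classify_compartment",
    "count_population",
    "fold_change",
    "compare_groups",
]

P_FLOOR = 1e-300  # cap for degenerate zero-variance p-values


@dataclass(frozen=True)
class PopulationCounts:
    """Tallies of a marker-defined population split by vessel compartment."""

    query: str
    n_inside: int
    n_outside: int
    n_unassigned: int
    stage_label: str = ""

    @property
    def n_total(self) -> int:
        return self.n_inside + self.n_outside + self.n_unassigned

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "stage_label": self.stage_label,
            "n_inside": self.n_inside,
            "n_outside": self.n_outside,
            "n_unassigned": self.n_unassigned,
            "n_total": self.n_total,
        }


@dataclass
class TimecourseSummary:
    """Per-stage replicate means ± s.d. and a fold change between two stages."""

    stages: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    n_replicates: dict[str, int]
    earlier: str
    later: str
    fold_change: float
    fold_change_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "means": self.means,
            "sds": self.sds,
            "n_replicates": self.n_replicates,
            "fold_change": {
                "from": self.earlier,
                "to": self.later,
                "value": self.fold_change,
                "sd": self.fold_change_sd,
            },
        }


def classify_compartment(
    cells: pd.DataFrame,
    vessel: LabelMask | np.ndarray,
    spacing=None,
    tolerance_um: float = 0.0,
) -> pd.DataFrame:
    """Label each cell inside/outside the vessel by centroid position.

    A cell is "inside" when its centroid's voxel lies in the vessel mask, or
    within ``tolerance_um`` of the nearest vessel voxel (anisotropic
    Euclidean distance transform in physical µm). Centroids outside the
    volume bounds become "unassigned". Returns a copy of the table with the
    ``compartment`` column filled.
    """
    if isinstance(vessel, LabelMask):
        if spacing is not None and tuple(float(s) for s in spacing) != vessel.spacing:
            raise SchemaError(
                f"spacing {tuple(spacing)} disagrees with the mask's {vessel.spacing}"
            )
        arr, sp = vessel.array.astype(bool), np.asarray(vessel.spacing)
    else:
        if spacing is None:
            raise SchemaError("spacing (z,y,x µm) is required with a bare array")
        arr, sp = np.asarray(vessel).astype(bool), np.asarray(spacing, dtype=float)
    if not arr.any():
        raise EmptyMaskError()
    if tolerance_um < 0:
        raise SchemaError("tolerance_um must be >= 0")

    for col in ("x_um", "y_um", "z_um"):
        if col not in cells.columns:
            raise SchemaError(f"cell table lacks coordinate column '{col}'")

    # centroid -> nearest voxel index; coordinates are µm, voxel centers at index*spacing
    coords_um = cells[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    idx = np.rint(coords_um / sp).astype(int)
    in_bounds = np.all((idx >= 0) & (idx < np.array(arr.shape)), axis=1)

    inside = np.zeros(len(cells), dtype=bool)
    ib = idx[in_bounds]
    hit = arr[ib[:, 0], ib[:, 1], ib[:, 2]]
    if tolerance_um > 0:
        dist_out = ndi.distance_transform_edt(~arr, sampling=sp)
        hit = hit | (dist_out[ib[:, 0], ib[:, 1], ib[:, 2]] <= tolerance_um)
    inside[in_bounds] = hit

    out = cells.copy()
    comp = np.full(len(cells), "unassigned", dtype=object)
    comp[in_bounds & inside] = "inside"
    comp[in_bounds & ~inside] = "outside"
    out["compartment"] = comp
    return out


_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def count_population(
    cells: pd.DataFrame,
    query: str = "",
    stage_label: str = "",
) -> PopulationCounts:
    """Tally cells matching a marker predicate, split by compartment.

    ``query`` is a boolean expression over the marker flag columns, e.g.
    ``"erg & prox1"`` or ``"prox1 & ~lineage"``; empty selects every cell.
    Unknown names raise an error listing the valid flags.
    """
    available = [c for c in FLAG_COLUMNS if c in cells.columns]
    if query.strip():
        names = set(_IDENT.findall(query)) - {"and", "or", "not"}
        unknown = names - set(available)
        if unknown:
            raise UnknownMarkerError(
                f"unknown marker flag(s) {sorted(unknown)}; valid flags: {available}"
            )
        sel = cells.eval(query) if len(cells) else pd.Series([], dtype=bool)
        sub = cells[sel.astype(bool)] if len(cells) else cells
    else:
        sub = cells
    comp = sub["compartment"] if "compartment" in sub.columns else pd.Series([], dtype=str)
    vc = comp.value_counts()
    return PopulationCounts(
        query=query,
        n_inside=int(vc.get("inside", 0)),
        n_outside=int(vc.get("outside", 0)),
        n_unassigned=int(vc.get("unassigned", 0)),
        stage_label=stage_label,
    )


def fold_change(
    replicates: dict[str, "list[float] | np.ndarray"],
    earlier: str,
    later: str,
) -> TimecourseSummary:
    """Expansion between two stages as the ratio of replicate means.

    ``replicates`` maps stage labels (e.g. "E9.5") to per-embryo counts.
    The fold change is later-mean / earlier-mean (ratio of means, not mean
    of per-embryo ratios); its s.d. is propagated to first order from the
    replicate s.d. of both stages.
    """
    for stage in (earlier, later):
        if stage not in replicates:
            raise SchemaError(f"stage {stage!r} missing from replicates")
    means = {s: float(np.mean(v)) for s, v in replicates.items()}
    sds = {s: float(np.std(v, ddof=1)) if len(np.atleast_1d(v)) > 1 else 0.0
           for s, v in replicates.items()}
    if means[earlier] <= 0:
        raise SchemaError(f"earlier-stage mean must be positive, got {means[earlier]}")
    ratio = means[later] / means[earlier]
    rel = [sds[s] / means[s] for s in (earlier, later) if means[s] > 0]
    sd = ratio * math.sqrt(sum(r * r for r in rel))
    return TimecourseSummary(
        stages=list(replicates),
        means=means,
        sds=sds,
        n_replicates={s: len(np.atleast_1d(v)) for s, v in replicates.items()},
        earlier=earlier,
        later=later,
        fold_change=ratio,
        fold_change_sd=sd,
    )


def compare_groups(groups: dict[str, "list[float] | np.ndarray"], test: str = "t") -> dict:
    """Unpaired two-tailed Student's t-test or one-way ANOVA across groups.

    Returns a report row with the statistic, degrees of freedom and p-value.
    Degenerate zero-within-variance comparisons are resolved explicitly:
    equal means give t = 0, p = 1; different means give p capped at a tiny
    floor rather than NaN.
    """
    vals = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in vals.items():
        if v.size < 2:
            raise SchemaError(f"group {k!r} needs >= 2 replicates, has {v.size}")
    if test == "t":
        if len(vals) != 2:
            raise SchemaError("t-test requires exactly 2 groups")
        a, b = vals.values()
        dof = a.size + b.size - 2
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = math.inf, P_FLOOR
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            stat, p = float(res.statistic), max(float(res.pvalue), P_FLOOR)
        return {"test": "t", "statistic": stat, "df": dof, "p_value": p}
    if test == "anova":
        if len(vals) < 2:
            raise SchemaError("ANOVA requires >= 2 groups")
        res = stats.f_oneway(*vals.values())
        k, n = len(vals), sum(v.size for v in vals.values())
        p = float(res.pvalue)
        if math.isnan(p):  # all-zero within variance
            p = 1.0 if len({v.mean() for v in vals.values()}) == 1 else P_FLOOR
        return {
            "test": "anova",
            "statistic": float(res.statistic),
            "df": (k - 1, n - k),
            "p_value": max(p, P_FLOOR),
        }
    raise SchemaError(f"unknown test {test!r}; use 't' or 'anova'")
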