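"""Synthetic labeling experiments and 3D vessel scenes with known ground truth.

Two generators make every downstream stage testable by parameter recovery:

* :func:`simulate_pulse_labeling` draws an asynchronous cycling population
  with known total cycle length, S-phase length and growth fraction, and
  flags each cell EdU/BrdU/KI67 under a configurable analogue-availability
  schedule — the in-silico analogue of a dual-pulse injection experiment.
* :func:`generate_vessel_scene` voxelizes nuclei and Golgi spheres around a
  tubular vessel, with Golgi offset directions drawn from a von Mises
  distribution, standing in for segmented confocal/light-sheet stacks.

Both record per-cell ground truth so estimators can be checked against the
generating parameters rather than against other code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cellcycle import PulseCounts
from .errors import PlacementError, SchemaError
from .io import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "CycleSimParams",
    "PulseSchedule",
    "SceneParams",
    "GroundTruth",
    "KAPPA_CAP",
    "simulate_pulse_labeling",
    "sample_polarity_angles",
    "generate_vessel_scene",
]

#: concentrations at or above this are treated as a point mass at mu
KAPPA_CAP = 1e6


@dataclass(frozen=True)
class CycleSimParams:
    """Ground-truth kinetics of the simulated population.

    ``s_phase_start`` positions the S window inside the cycle (hours from
    cycle start); under the steady-state uniform-phase assumption the
    estimators are independent of it, so it defaults to centering S.
    """

    t_cycle: float
    t_s: float
    growth_fraction: float
    n_cells: int
    s_phase_start: float | None = None
    ki67_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.t_cycle <= 0:
            raise SchemaError(f"t_cycle must be > 0 h, got {self.t_cycle}")
        if not (0 < self.t_s < self.t_cycle):
            raise SchemaError(
                f"t_s must satisfy 0 < t_s < t_cycle, got t_s={self.t_s}, t_cycle={self.t_cycle}"
            )
        if not (0.0 <= self.growth_fraction <= 1.0):
            raise SchemaError(f"growth_fraction must be in [0,1], got {self.growth_fraction}")
        if self.n_cells <= 0:
            raise SchemaError("n_cells must be a positive count")
        if self.s_phase_start is None:
            object.__setattr__(self, "s_phase_start", (self.t_cycle - self.t_s) / 2.0)
        if not (0.0 <= self.s_phase_start <= self.t_cycle - self.t_s):
            raise SchemaError(
                f"s_phase_start must lie in [0, t_cycle - t_s], got {self.s_phase_start}"
            )
        if not (0.0 <= self.ki67_flip_prob <= 1.0):
            raise SchemaError("ki67_flip_prob must be a probability")


@dataclass(frozen=True)
class PulseSchedule:
    """Analogue availability windows (hours from first injection).

    The first analogue (EdU) is treated as continuously available over its
    window because it is re-injected to maintain bioavailability; the second
    (BrdU) is available from its injection until harvest. ``t_i`` is the
    injection interval the estimator divides by; the default schedule is
    EdU [0, 6] h, BrdU [6, 8] h, T_i = 6 h.
    """

    edu_window: tuple[float, float] = (0.0, 6.0)
    brdu_window: tuple[float, float] = (6.0, 8.0)
    t_i: float = 6.0

    def __post_init__(self):
        for name, (a, b) in (("edu_window", self.edu_window), ("brdu_window", self.brdu_window)):
            if not b > a:
                raise SchemaError(f"{name} must be non-degenerate [start, end), got [{a}, {b})")
        if not self.edu_window[0] < self.brdu_window[0]:
            raise SchemaError("EdU availability must start before BrdU")
        if self.t_i <= 0:
            raise SchemaError(f"t_i must be > 0 h, got {self.t_i}")

    @property
    def horizon(self) -> float:
        """Total experiment span in hours (first injection to harvest)."""
        return self.brdu_window[1] - self.edu_window[0]


@dataclass(frozen=True)
class SceneParams:
    """Geometry of a synthetic vessel scene.

    A straight tube of ``vessel_radius`` µm runs along the x axis through the
    volume center; ``n_inside`` nuclei are placed inside it and ``n_outside``
    beyond it. Each nucleus gets a Golgi sphere whose centroid is displaced
    ``golgi_offset`` µm in the x–y plane along a compass direction drawn from
    von Mises(``mu_deg``, ``kappa``); 0° points toward +y ("dorsal"), 90°
    toward +x ("lateral"). ``min_separation`` keeps nucleus centroids far
    enough apart that nucleus–Golgi pairing is unambiguous.
    """

    volume_shape: tuple[int, int, int] = (40, 192, 192)          # (z,y,x) voxels
    voxel_spacing: tuple[float, float, float] = (2.0, 0.5, 0.5)  # µm
    vessel_radius: float = 20.0
    n_inside: int = 10
    n_outside: int = 10
    golgi_offset: float = 6.0
    mu_deg: float = 0.0
    kappa: float = 2.0
    nucleus_radius: float = 3.0
    golgi_radius: float = 1.5
    min_separation: float = 16.0
    seed: int = 0
    max_attempts: int = 20000

    def __post_init__(self):
        if self.kappa < 0:
            raise SchemaError(f"kappa must be >= 0, got {self.kappa}")
        if min(self.nucleus_radius, self.golgi_radius, self.vessel_radius) <= 0:
            raise SchemaError("all radii must be positive µm")
        if self.golgi_offset <= 0:
            raise SchemaError("golgi_offset must be positive µm")
        if min(self.n_inside, self.n_outside) < 0:
            raise SchemaError("object counts must be non-negative")
        extent = [s * v for s, v in zip(self.volume_shape, self.voxel_spacing)]
        reach = self.nucleus_radius + self.golgi_offset + self.golgi_radius
        if any(e <= 2 * reach for e in extent[1:]) or extent[0] <= 2 * self.nucleus_radius:
            raise SchemaError("volume too small for the requested object sizes")
        if 2 * self.vessel_radius >= min(extent[0], extent[1]):
            raise SchemaError("vessel tube does not fit inside the volume")


@dataclass
class GroundTruth:
    """Per-cell generating truth plus the echoed parameters."""

    cells: pd.DataFrame
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pulse-labeling simulation
# ---------------------------------------------------------------------------

def _window_overlaps_s(phase, t_cycle, t_s, s_start, window):
    """True where a cell's (recurring) S interval intersects [a, b).

    ``phase`` is hours since cycle start at t=0; the cell is in S at time t
    iff (phase + t) mod t_cycle falls in [s_start, s_start + t_s). The cell
    is labeled iff it is in S when the window opens, or it enters S before
    the window closes — which handles exit-and-re-enter wrapping exactly.
    """
    a, b = window
    pos_at_open = np.mod(phase + a - s_start, t_cycle)
    next_entry = np.mod(s_start - phase - a, t_cycle)
    return (pos_at_open < t_s) | (next_entry < (b - a))


def simulate_pulse_labeling(
    params: CycleSimParams, schedule: PulseSchedule | None = None
) -> tuple[pd.DataFrame, PulseCounts, GroundTruth]:
    """Simulate a dual-pulse labeling experiment on an asynchronous population.

    Cycling cells (an exact ``growth_fraction`` share of the population, KI67+)
    are assigned a uniform phase in [0, t_cycle); a cell is flagged positive
    for an analogue iff its S window, wrapping modulo the cycle, overlaps the
    analogue's availability window. Non-cycling cells never incorporate and
    are KI67−. Returns the per-cell table, the pooled counts, and ground truth.
    """
    schedule = schedule or PulseSchedule()
    if params.t_cycle - params.t_s < schedule.horizon:
        logger.warning(
            "re-entry regime: t_cycle - t_s = %.2f h is shorter than the %.2f h "
            "schedule horizon; cells can exit and re-enter S, biasing L_cells low "
            "and the estimates high",
            params.t_cycle - params.t_s,
            schedule.horizon,
            extra={"stage": "simulate_pulse_labeling", "regime": "re-entry"},
        )
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    n_cycling = int(round(params.growth_fraction * n))
    cycling = np.zeros(n, dtype=bool)
    cycling[rng.permutation(n)[:n_cycling]] = True

    phase = np.full(n, np.nan)
    phase[cycling] = rng.uniform(0.0, params.t_cycle, size=n_cycling)

    edu = np.zeros(n, dtype=bool)
    brdu = np.zeros(n, dtype=bool)
    if n_cycling:
        ph = phase[cycling]
        edu[cycling] = _window_overlaps_s(
            ph, params.t_cycle, params.t_s, params.s_phase_start, schedule.edu_window
        )
        brdu[cycling] = _window_overlaps_s(
            ph, params.t_cycle, params.t_s, params.s_phase_start, schedule.brdu_window
        )

    ki67 = cycling.copy()
    if params.ki67_flip_prob > 0:
        flips = rng.random(n) < params.ki67_flip_prob
        ki67 ^= flips

    pos = rng.uniform(0.0, 100.0, size=(n, 3))  # cosmetic scatter, µm
    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "edu": edu,
            "brdu": brdu,
            "ki67": ki67,
            "compartment": "unassigned",
        }
    )
    counts = PulseCounts.from_cell_table(table, t_i=schedule.t_i)
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"cell_id": table["cell_id"], "cycling": cycling, "phase_hours": phase}
        ),
        params={**asdict(params), **asdict(schedule)},
    )
    return table, counts, truth


# ---------------------------------------------------------------------------
# angular sampling and vessel scenes
# ---------------------------------------------------------------------------

def sample_polarity_angles(mu_deg: float, kappa: float, n: int, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` compass angles (degrees in [0, 360)) from von Mises(mu, kappa).

    kappa = 0 reduces to uniform sampling; kappa >= ``KAPPA_CAP`` collapses to
    a point mass at ``mu_deg``.
    """
    if kappa < 0:
        raise SchemaError(f"kappa must be >= 0, got {kappa}")
    if n < 0:
        raise SchemaError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if kappa >= KAPPA_CAP:
        return np.full(n, mu_deg % 360.0)
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=n)) % 360.0


def _rasterize_sphere(array: np.ndarray, center_um: np.ndarray, radius: float,
                      spacing: np.ndarray, label: int) -> None:
    """Set ``label`` on voxels whose centers lie within ``radius`` µm of center.

    Voxel centers sit at index·spacing; anisotropy is respected by the
    physical distance test. Writes into ``array`` in place.
    """
    lo = np.maximum(np.ceil((center_um - radius) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((center_um + radius) / spacing).astype(int), np.array(array.shape) - 1)
    if np.any(lo > hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center_um)))
    sub = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    region = array[sub]
    region[d2 <= radius**2] = label


def generate_vessel_scene(
    params: SceneParams,
) -> tuple[LabelMask, LabelMask, LabelMask, GroundTruth]:
    """Build (nuclei, golgi, vessel) masks plus ground truth for one scene.

    Nucleus centroids are rejection-sampled — inside the tube with a one-voxel
    safety margin from the wall, or outside it — keeping every centroid at
    least ``min_separation`` µm from the others and every sphere (including
    the offset Golgi) inside the volume. Placement failure after
    ``max_attempts`` draws raises an error naming the violated constraint.
    """
    rng = np.random.default_rng(params.seed)
    spacing = np.array(params.voxel_spacing, dtype=float)          # (z,y,x)
    shape = tuple(params.volume_shape)
    extent = spacing * np.array(shape)                             # physical µm
    margin_vox = float(spacing.max())

    # vessel: tube along x, centered in the (z, y) cross-section
    zc, yc = extent[0] / 2.0, extent[1] / 2.0
    zz = np.arange(shape[0])[:, None] * spacing[0]
    yy = np.arange(shape[1])[None, :] * spacing[1]
    cross = (zz - zc) ** 2 + (yy - yc) ** 2 <= params.vessel_radius**2
    vessel = np.broadcast_to(cross[:, :, None], shape).copy()

    reach = params.nucleus_radius + params.golgi_offset + params.golgi_radius
    z_lo, z_hi = params.nucleus_radius, extent[0] - params.nucleus_radius

    centers: list[np.ndarray] = []  # (z, y, x) µm
    compartments: list[str] = []

    def try_place(inside: bool) -> np.ndarray:
        for _ in range(params.max_attempts):
            if inside:
                # uniform in the tube cross-section disc, shrunk by a margin
                r_eff = params.vessel_radius - margin_vox - 1e-9
                rad = r_eff * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                z, y = zc + rad * np.cos(ang), yc + rad * np.sin(ang)
                if not (z_lo <= z <= z_hi and reach <= y <= extent[1] - reach):
                    continue
                x = rng.uniform(reach, extent[2] - reach)
            else:
                z = rng.uniform(z_lo, z_hi)
                y = rng.uniform(reach, extent[1] - reach)
                x = rng.uniform(reach, extent[2] - reach)
                if (z - zc) ** 2 + (y - yc) ** 2 < (params.vessel_radius + margin_vox) ** 2:
                    continue
            c = np.array([z, y, x])
            if all(np.linalg.norm(c - p) >= params.min_separation for p in centers):
                return c
        raise PlacementError(
            f"could not place an {'inside' if inside else 'outside'} nucleus after "
            f"{params.max_attempts} attempts; constraints: min_separation="
            f"{params.min_separation} µm, vessel_radius={params.vessel_radius} µm, "
            f"volume extent={tuple(np.round(extent, 1))} µm"
        )

    for _ in range(params.n_inside):
        centers.append(try_place(inside=True))
        compartments.append("inside")
    for _ in range(params.n_outside):
        centers.append(try_place(inside=False))
        compartments.append("outside")

    n = len(centers)
    angles = sample_polarity_angles(
        params.mu_deg, params.kappa, n, seed=int(rng.integers(0, 2**31 - 1))
    )
    # compass convention: 0° -> +y (dorsal), 90° -> +x (lateral)
    rad = np.radians(angles)
    offsets = np.stack(
        [np.zeros(n), np.cos(rad) * params.golgi_offset, np.sin(rad) * params.golgi_offset],
        axis=1,
    )  # (z, y, x)

    nuclei_arr = np.zeros(shape, dtype=np.uint16)
    golgi_arr = np.zeros(shape, dtype=np.uint16)
    rows = []
    for i, (c, comp, ang, off) in enumerate(zip(centers, compartments, angles, offsets), start=1):
        g = c + off
        _rasterize_sphere(nuclei_arr, c, params.nucleus_radius, spacing, i)
        _rasterize_sphere(golgi_arr, g, params.golgi_radius, spacing, i)
        rows.append(
            {
                "cell_id": i,
                "x_um": c[2], "y_um": c[1], "z_um": c[0],
                "golgi_x_um": g[2], "golgi_y_um": g[1], "golgi_z_um": g[0],
                "compartment": comp,
                "angle_deg": float(ang),
            }
        )

    sp = tuple(params.voxel_spacing)
    truth = GroundTruth(cells=pd.DataFrame(rows), params=asdict(params))
    return (
        LabelMask(nuclei_arr, sp),
        LabelMask(golgi_arr, sp),
        LabelMask(vessel.astype(np.uint8), sp),
        truth,
    )
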