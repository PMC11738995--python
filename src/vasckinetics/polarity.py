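"""Nucleus–Golgi polarity: pairing, angle computation, circular summary.

The Golgi apparatus sits ahead of the nucleus in a migrating cell, so the
nucleus→Golgi centroid vector is a proxy for migration direction. The
pipeline mirrors the standard image-analysis workflow on segmented surfaces:

1. extract per-object geometry (centroid, boundary voxels) from label masks;
2. pair each nucleus with its Golgi by closest border–border distance (3D,
   physical µm), excluding pairs farther apart than 5 µm;
3. project the centroid vector to the x–y plane and measure its angle
   against a dorsal reference axis, θ = arccos(A·B), signed to the compass
   convention 0° dorsal, 90° lateral, 180° ventral, 270° medial;
4. summarize the angles as a rose histogram with circular mean, resultant
   length R and a Rayleigh uniformity test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .errors import DegeneratePairError, SchemaError
from .io import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectGeometry",
    "NucleusGolgiPair",
    "AngularDistribution",
    "PairingResult",
    "extract_geometry",
    "pair_nuclei_golgi",
    "compute_polarity_angle",
    "assign_angles",
    "summarize_angles",
    "polarity_pipeline",
    "rose_plot",
]

DEFAULT_MAX_DIST_UM = 5.0
DEFAULT_REFERENCE_AXIS = (0.0, 1.0)  # image +y is dorsal


@dataclass
class ObjectGeometry:
    """Centroid and boundary of one labeled object, in physical µm (x,y,z)."""

    label_id: int
    centroid: np.ndarray          # (3,) µm, (x, y, z)
    boundary: np.ndarray          # (k, 3) µm, voxel centers with a background 6-neighbor

    def __post_init__(self):
        if len(self.boundary) == 0:
            raise SchemaError(f"object {self.label_id} has an empty boundary")


@dataclass
class NucleusGolgiPair:
    """One nucleus matched to one Golgi, with its polarity vector."""

    nucleus_id: int
    golgi_id: int
    border_distance: float                 # µm, 3D boundary-to-boundary
    nucleus_centroid: np.ndarray           # (3,) µm
    golgi_centroid: np.ndarray             # (3,) µm
    included: bool = True
    exclusion_reason: str | None = None
    vector_xy: np.ndarray | None = None    # unit vector A in the x-y plane
    angle_deg: float | None = None


@dataclass
class PairingResult:
    """Pairs plus the ids that could not be matched."""

    pairs: list[NucleusGolgiPair]
    unmatched_nuclei: list[int] = field(default_factory=list)
    unmatched_golgi: list[int] = field(default_factory=list)

    @property
    def included(self) -> list[NucleusGolgiPair]:
        return [p for p in self.pairs if p.included]


@dataclass
class AngularDistribution:
    """Rose-histogram counts plus circular summary statistics."""

    bin_edges: np.ndarray        # degrees, len n_bins + 1
    counts: np.ndarray
    n_included: int
    n_excluded: int
    mean_deg: float              # circular mean direction
    resultant_length: float      # R in [0, 1]
    rayleigh_p: float

    def to_dict(self) -> dict:
        return {
            "bin_edges_deg": [float(x) for x in self.bin_edges],
            "counts": [int(c) for c in self.counts],
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "circular_mean_deg": self.mean_deg,
            "resultant_length": self.resultant_length,
            "rayleigh_p": self.rayleigh_p,
        }


# ---------------------------------------------------------------------------
# geometry extraction
# ---------------------------------------------------------------------------

def extract_geometry(mask: LabelMask) -> list[ObjectGeometry]:
    """Per-label centroids and boundary voxels from a label mask.

    Centroids are the unweighted mean of member voxel centers in µm;
    a boundary voxel has at least one 6-neighbor that is background (0) or
    lies outside the volume. An empty mask yields an empty list.
    """
    arr = mask.array
    spacing = np.asarray(mask.spacing)  # (z, y, x)
    labels = mask.labels
    if labels.size == 0:
        return []

    fg = arr != 0
    padded = np.pad(fg, 1, constant_values=False)
    near_bg = np.zeros_like(fg)
    for ax in range(3):
        for shift in (1, -1):
            sl = [slice(1, -1)] * 3
            sl[ax] = slice(2, None) if shift == 1 else slice(None, -2)
            near_bg |= ~padded[tuple(sl)]
    boundary_mask = fg & near_bg

    out = []
    for lab in labels:
        member = np.argwhere(arr == lab)
        centroid_zyx = member.mean(axis=0) * spacing
        b = np.argwhere((arr == lab) & boundary_mask) * spacing
        out.append(
            ObjectGeometry(
                label_id=int(lab),
                centroid=centroid_zyx[::-1].copy(),   # -> (x, y, z)
                boundary=b[:, ::-1].copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _border_distance_matrix(nuclei: list[ObjectGeometry], golgi: list[ObjectGeometry]) -> np.ndarray:
    """Minimum boundary-to-boundary Euclidean distance (µm) per pair."""
    d = np.empty((len(nuclei), len(golgi)))
    trees = [cKDTree(g.boundary) for g in golgi]
    for i, nuc in enumerate(nuclei):
        for j, tree in enumerate(trees):
            d[i, j] = tree.query(nuc.boundary, k=1)[0].min()
    return d


def pair_nuclei_golgi(
    nuclei: list[ObjectGeometry],
    golgi: list[ObjectGeometry],
    max_dist: float = DEFAULT_MAX_DIST_UM,
    method: str = "greedy",
) -> PairingResult:
    """One-to-one nucleus–Golgi pairing by closest border–border distance.

    ``method='greedy'`` (default) assigns candidate pairs in ascending
    distance order, each object claiming at most one partner;
    ``method='optimal'`` minimizes the total distance with the Hungarian
    algorithm instead. Pairs farther than ``max_dist`` µm are kept but
    flagged excluded; leftover objects are reported unmatched.
    """
    if method not in ("greedy", "optimal"):
        raise SchemaError(f"unknown pairing method {method!r}")
    if not golgi:
        logger.warning(
            "no Golgi objects: all %d nuclei unmatched", len(nuclei),
            extra={"stage": "pair_nuclei_golgi"},
        )
        return PairingResult(pairs=[], unmatched_nuclei=[n.label_id for n in nuclei])
    if not nuclei:
        return PairingResult(pairs=[], unmatched_golgi=[g.label_id for g in golgi])

    d = _border_distance_matrix(nuclei, golgi)
    matches: list[tuple[int, int]] = []
    if method == "greedy":
        taken_n: set[int] = set()
        taken_g: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"), d.shape))[0]
        for i, j in order:
            if i not in taken_n and j not in taken_g:
                matches.append((int(i), int(j)))
                taken_n.add(int(i))
                taken_g.add(int(j))
    else:
        rows, cols = linear_sum_assignment(d)
        matches = list(zip(rows.tolist(), cols.tolist()))

    pairs = []
    for i, j in sorted(matches):
        dist = float(d[i, j])
        pairs.append(
            NucleusGolgiPair(
                nucleus_id=nuclei[i].label_id,
                golgi_id=golgi[j].label_id,
                border_distance=dist,
                nucleus_centroid=nuclei[i].centroid,
                golgi_centroid=golgi[j].centroid,
                included=dist <= max_dist,
                exclusion_reason=None if dist <= max_dist else "border_distance",
            )
        )
    matched_n = {i for i, _ in matches}
    matched_g = {j for _, j in matches}
    return PairingResult(
        pairs=pairs,
        unmatched_nuclei=[n.label_id for k, n in enumerate(nuclei) if k not in matched_n],
        unmatched_golgi=[g.label_id for k, g in enumerate(golgi) if k not in matched_g],
    )


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def compute_polarity_angle(
    pair: NucleusGolgiPair,
    reference_axis=DEFAULT_REFERENCE_AXIS,
    lateral_side: str = "right",
) -> float:
    """Compass angle of the nucleus→Golgi vector against the body axis.

    A is the normalized x–y projection of (Golgi − nucleus); θ = arccos(A·B)
    in [0°, 180°] is then signed by the orientation of A relative to the
    reference B: with ``lateral_side='right'`` the +90° (lateral) direction
    is the one B reaches by a clockwise turn in a right-handed x–y frame
    (B = +y dorsal puts lateral at +x); ``'left'`` mirrors the convention
    for the opposite body side. Returns degrees in [0, 360).
    """
    if lateral_side not in ("right", "left"):
        raise SchemaError(f"lateral_side must be 'right' or 'left', got {lateral_side!r}")
    b = np.asarray(reference_axis, dtype=float)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise SchemaError("reference axis must be a nonzero x-y vector")
    b = b / nb
    v = (pair.golgi_centroid[:2] - pair.nucleus_centroid[:2]).astype(float)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise DegeneratePairError(
            f"nucleus {pair.nucleus_id} / golgi {pair.golgi_id}: centroids coincide in x-y"
        )
    a = v / nv
    theta = float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))
    cross = b[0] * a[1] - b[1] * a[0]
    if lateral_side == "left":
        cross = -cross
    angle = theta if cross <= 0 else 360.0 - theta
    pair.vector_xy = a
    pair.angle_deg = angle % 360.0
    return pair.angle_deg


def assign_angles(
    result: PairingResult,
    reference_axis=DEFAULT_REFERENCE_AXIS,
    lateral_side: str = "right",
) -> np.ndarray:
    """Angles for all included pairs; degenerate pairs become excluded."""
    angles = []
    for pair in result.pairs:
        if not pair.included:
            continue
        try:
            angles.append(compute_polarity_angle(pair, reference_axis, lateral_side))
        except DegeneratePairError:
            pair.included = False
            pair.exclusion_reason = DegeneratePairError.code
    return np.asarray(angles)


# ---------------------------------------------------------------------------
# circular summary
# ---------------------------------------------------------------------------

def _rayleigh_p_approx(n: int, r: float) -> float:
    """Small-sample-corrected Rayleigh p-value, p = e^-Z (1 + (2Z - Z^2)/(4n))."""
    z = n * r * r
    p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return float(np.clip(p, 0.0, 1.0))


def _rayleigh_p_montecarlo(n: int, r: float, n_sim: int = 9999, seed: int = 0) -> float:
    """Monte-Carlo Rayleigh p: share of uniform samples with R >= observed."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=(n_sim, n))
    r_sim = np.abs(np.exp(1j * theta).mean(axis=1))
    return float((1 + np.sum(r_sim >= r)) / (n_sim + 1))


def summarize_angles(
    angles,
    n_bins: int = 24,
    n_excluded: int = 0,
    uniformity: str = "approx",
    seed: int = 0,
) -> AngularDistribution:
    """Rose-histogram bins plus circular mean, resultant length and Rayleigh p.

    The resultant length R = |Σ e^{iθ}| / n measures concentration (R = 1:
    all angles identical; R = 0: perfectly balanced). ``uniformity`` selects
    the documented analytic Rayleigh approximation (default) or a Monte-Carlo
    permutation-style null, recommended for n < 100.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise SchemaError("cannot summarize an empty set of angles")
    if n_bins < 1:
        raise SchemaError("n_bins must be >= 1")
    angles = np.mod(angles, 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    z = np.exp(1j * np.radians(angles)).mean()
    r = float(np.abs(z))
    mean_deg = float(np.degrees(np.angle(z)) % 360.0)
    n = angles.size
    if uniformity == "approx":
        p = _rayleigh_p_approx(n, r)
    elif uniformity == "monte_carlo":
        p = _rayleigh_p_montecarlo(n, r, seed=seed)
    else:
        raise SchemaError(f"unknown uniformity test {uniformity!r}")
    return AngularDistribution(
        bin_edges=edges,
        counts=counts,
        n_included=int(n),
        n_excluded=int(n_excluded),
        mean_deg=mean_deg,
        resultant_length=r,
        rayleigh_p=p,
    )


def polarity_pipeline(
    nuclei_mask: LabelMask,
    golgi_mask: LabelMask,
    max_dist: float = DEFAULT_MAX_DIST_UM,
    reference_axis=DEFAULT_REFERENCE_AXIS,
    lateral_side: str = "right",
    n_bins: int = 24,
) -> tuple[PairingResult, AngularDistribution]:
    """Full pipeline from two label masks to an angular distribution."""
    nuclei = extract_geometry(nuclei_mask)
    golgi = extract_geometry(golgi_mask)
    result = pair_nuclei_golgi(nuclei, golgi, max_dist=max_dist)
    angles = assign_angles(result, reference_axis, lateral_side)
    n_excluded = sum(1 for p in result.pairs if not p.included)
    logger.info(
        "polarity: %d included, %d excluded, %d unmatched nuclei, %d unmatched golgi",
        len(angles), n_excluded, len(result.unmatched_nuclei), len(result.unmatched_golgi),
        extra={"stage": "polarity_pipeline"},
    )
    dist = summarize_angles(angles, n_bins=n_bins, n_excluded=n_excluded)
    return result, dist


def rose_plot(dist: AngularDistribution, path) -> None:
    """Save the angular distribution as an SVG rose diagram (0° at top,
    clockwise), matching the compass convention of the angles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    centers = np.radians((dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2.0)
    width = np.radians(np.diff(dist.bin_edges))
    ax.bar(centers, dist.counts, width=width, bottom=0.0, edgecolor="black", alpha=0.7)
    ax.set_title(
        f"n={dist.n_included}, mean={dist.mean_deg:.1f}°, R={dist.resultant_length:.2f}, "
        f"Rayleigh p={dist.rayleigh_p:.3g}"
    )
    fig.savefig(path, format="svg")
    plt.close(fig)
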