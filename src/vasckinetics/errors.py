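"""Typed exceptions with stable error codes.

Division-by-zero and degenerate-input conditions raise these errors rather
than propagating NaN, so that pipeline stages fail loudly and callers can
branch on ``code``.
"""

from __future__ import annotations


class VascKineticsError(Exception):
    """Base class for all package errors."""

    code: str = "error"

    def __init__(self, message: str | None = None):
        super().__init__(message or self.__doc__)


class EmptyPopulationError(VascKineticsError):
    """Empty population: no scored nuclei (P_cells = 0)."""

    code = "empty_population"


class NoDoublePositiveError(VascKineticsError):
    """No double-positive cells: S_cells = 0, the S-phase ratio is undefined."""

    code = "no_double_positive"


class NoLeavingCellsError(VascKineticsError):
    """No EdU-only cells: T_i too short or population saturated (L_cells = 0)."""

    code = "no_edu_only"


class ZeroGrowthFractionError(VascKineticsError):
    """Growth fraction is zero: no cycling cells, cycle length undefined."""

    code = "zero_growth_fraction"


class BootstrapFailureError(VascKineticsError):
    """Too many failed bootstrap replicates; a larger sample is needed."""

    code = "bootstrap_failure"


class EmptyMaskError(VascKineticsError):
    """Vessel or label mask contains no foreground voxels."""

    code = "empty_mask"


class SpacingError(VascKineticsError):
    """Voxel spacing missing, non-positive, or inconsistent with the mask."""

    code = "bad_spacing"


class PlacementError(VascKineticsError):
    """Scene generation could not satisfy a placement constraint."""

    code = "placement_failure"


class SchemaError(VascKineticsError):
    """Input table/config does not match the documented schema."""

    code = "schema_error"


class UnknownMarkerError(VascKineticsError):
    """Marker query references a flag that is not a known column."""

    code = "unknown_marker"


class DegeneratePairError(VascKineticsError):
    """Nucleus and Golgi centroids coincide in the x-y projection."""

    code = "degenerate_xy"
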