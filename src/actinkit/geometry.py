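"""Helical-symmetry arithmetic for actin filaments and segmenting geometry.

F-actin's genetic (short-pitch) helix is left-handed, so its per-subunit
rotation is reported negative: a twist of n subunits per turn corresponds to
a rotation of −360/n degrees between symmetry neighbours.  Bare F-actin sits
near 2.16 subunits/turn (−166.67°); a twist change to 2.14 subunits/turn
corresponds to −168.22°, −168° to the nearest degree.

The segmenting arithmetic covers the overlapping-box scheme used when
averaging helical segments: a box of B pixels advanced by a stride of
B − overlap pixels lets each asymmetric unit appear in B/(B − overlap)
different views.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HelicalSymmetry",
    "SegmentScheme",
    "rotation_from_twist",
    "twist_from_rotation",
    "views_per_unit",
    "subunits_per_box",
    "F_ACTIN_RISE_NM",
]

F_ACTIN_RISE_NM = 2.75  # canonical axial rise per subunit


def rotation_from_twist(twist: float) -> float:
    """Signed per-subunit rotation (degrees) from subunits per turn.

    Negative by the left-handed genetic-helix convention; requires twist > 1
    so the rotation magnitude stays below 360°.
    """
    twist = float(twist)
    if not twist > 1:
        raise ValueError(f"twist must exceed 1 subunit per turn, got {twist}")
    return -360.0 / twist


def twist_from_rotation(rotation: float) -> float:
    """Subunits per turn from a signed per-subunit rotation (degrees)."""
    rotation = float(rotation)
    if rotation == 0 or abs(rotation) >= 360.0:
        raise ValueError(f"rotation must satisfy 0 < |rotation| < 360, got {rotation}")
    return -360.0 / rotation if rotation < 0 else 360.0 / rotation


@dataclass(frozen=True)
class HelicalSymmetry:
    """Filament symmetry: twist (subunits/turn), rotation (deg, signed), rise (nm)."""

    twist: float
    rise: float = F_ACTIN_RISE_NM

    def __post_init__(self):
        if not self.twist > 1:
            raise ValueError("twist must exceed 1")
        if not self.rise > 0:
            raise ValueError("rise must be positive")

    @property
    def rotation(self) -> float:
        return rotation_from_twist(self.twist)

    @classmethod
    def from_rotation(cls, rotation: float, rise: float = F_ACTIN_RISE_NM) -> "HelicalSymmetry":
        return cls(twist=twist_from_rotation(rotation), rise=rise)


@dataclass(frozen=True)
class SegmentScheme:
    """Overlapping-box segmenting geometry: box and overlap in pixels."""

    box: int
    overlap: int
    pixel_size: float  # nm/pixel

    def __post_init__(self):
        if not 0 <= self.overlap < self.box:
            raise ValueError("need 0 <= overlap < box")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")

    @property
    def stride(self) -> int:
        return self.box - self.overlap


def views_per_unit(scheme: SegmentScheme) -> tuple[float, bool]:
    """Number of overlapping views each asymmetric unit contributes to.

    Returns (box/stride, exact) where exact is False when the stride does
    not divide the box evenly (the count is then fractional).
    """
    q, r = divmod(scheme.box, scheme.stride)
    if r == 0:
        return float(q), True
    return scheme.box / scheme.stride, False


def subunits_per_box(scheme: SegmentScheme, symmetry: HelicalSymmetry) -> float:
    """Fractional count of asymmetric units spanned by one box."""
    return scheme.box * scheme.pixel_size / symmetry.rise


def symmetry_report(twist: float, rise: float = F_ACTIN_RISE_NM,
                    scheme: SegmentScheme | None = None) -> dict:
    """JSON-ready summary of a filament symmetry (and optional box scheme)."""
    sym = HelicalSymmetry(twist=twist, rise=rise)
    rot = sym.rotation
    out = {
        "twist_subunits_per_turn": sym.twist,
        "rotation_deg": rot,
        "rotation_deg_2dp": round(rot, 2),
        "rotation_deg_nearest": round(rot),
        "rise_nm": sym.rise,
    }
    if scheme is not None:
        views, exact = views_per_unit(scheme)
        out["views_per_unit"] = views
        out["views_exact"] = exact
        out["subunits_per_box"] = subunits_per_box(scheme, sym)
    return out
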