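"""Helical-wheel projection and amphipathicity metrics for short helices.

An ideal α-helix advances 100° per residue when projected along its axis, so
an 18-residue helix covers exactly five turns and residue 19 falls back onto
residue 1.  Amphipathic actin-binding helices (WH2-type) cluster their
hydrophobic residues on one face of this wheel; the hydrophobic moment µH —
the vector sum of per-residue hydrophobicities at the wheel angles —
quantifies that asymmetry, and the largest contiguous hydrophobic arc
locates the face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HelixPeptide",
    "WheelLayout",
    "EISENBERG",
    "KYTE_DOOLITTLE",
    "wheel_layout",
    "classify_residue",
    "hydrophobic_moment",
    "hydrophobic_face",
]

# Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

try:  # Kyte-Doolittle from biopython when present, else the published table
    from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
except ImportError:  # pragma: no cover
    KYTE_DOOLITTLE = {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    }

_NEGATIVE = set("DE")
_POSITIVE = set("KRH")

# glyph vocabulary for plot-data export: hydrophilic circles, hydrophobic
# diamonds, acidic triangles, basic pentagons
GLYPHS = {
    "hydrophilic": "circle",
    "hydrophobic": "diamond",
    "negative": "triangle",
    "positive": "pentagon",
}


@dataclass(frozen=True)
class HelixPeptide:
    """A named peptide given as a one-letter residue string."""

    identifier: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - set(EISENBERG)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        if not seq:
            raise ValueError("peptide sequence must be non-empty")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WheelResidue:
    index: int          # 1-based position in the peptide
    residue: str
    angle: float        # degrees mod 360, counterclockwise from residue 1
    klass: str          # hydrophobic | hydrophilic | negative | positive
    hydrophobicity: float
    glyph: str


@dataclass(frozen=True)
class WheelLayout:
    peptide: HelixPeptide
    step: float
    residues: tuple[WheelResidue, ...]

    def angles(self) -> np.ndarray:
        return np.array([r.angle for r in self.residues])

    def to_records(self) -> list[dict]:
        return [
            {
                "index": r.index,
                "residue": r.residue,
                "angle_deg": r.angle,
                "class": r.klass,
                "hydrophobicity": r.hydrophobicity,
                "glyph": r.glyph,
            }
            for r in self.residues
        ]


def classify_residue(aa: str, scale: dict | None = None) -> str:
    """Four-way residue class: D/E negative, K/R/H positive, rest by scale sign."""
    aa = aa.upper()
    scale = EISENBERG if scale is None else scale
    if aa not in scale:
        raise ValueError(f"unknown residue letter {aa!r}")
    if aa in _NEGATIVE:
        return "negative"
    if aa in _POSITIVE:
        return "positive"
    return "hydrophobic" if scale[aa] > 0 else "hydrophilic"


def wheel_layout(peptide: HelixPeptide, step: float = 100.0,
                 scale: dict | None = None) -> WheelLayout:
    """Project a peptide onto the helical wheel (angle origin at residue 1)."""
    scale = EISENBERG if scale is None else scale
    residues = []
    for i, aa in enumerate(peptide.sequence, start=1):
        klass = classify_residue(aa, scale)
        residues.append(
            WheelResidue(
                index=i,
                residue=aa,
                angle=((i - 1) * step) % 360.0,
                klass=klass,
                hydrophobicity=float(scale[aa]),
                glyph=GLYPHS[klass],
            )
        )
    return WheelLayout(peptide=peptide, step=float(step), residues=tuple(residues))


def hydrophobic_moment(peptide: HelixPeptide, scale: dict | None = None,
                       step: float = 100.0) -> tuple[float, float]:
    """Hydrophobic moment magnitude and direction (degrees).

    µH is the modulus of the vector sum of per-residue hydrophobicities
    placed at the wheel angles; the magnitude is invariant under any global
    angular offset, so only relative geometry matters.  Direction is the
    angle of the resultant (NaN for zero moment).
    """
    scale = EISENBERG if scale is None else scale
    angles = np.deg2rad(np.arange(len(peptide)) * step)
    h = np.array([scale[aa] for aa in peptide.sequence])
    vx = float(np.sum(h * np.cos(angles)))
    vy = float(np.sum(h * np.sin(angles)))
    mag = float(np.hypot(vx, vy))
    direction = float(np.rad2deg(np.arctan2(vy, vx)) % 360.0) if mag > 0 else float("nan")
    return mag, direction


def hydrophobic_face(layout: WheelLayout) -> dict:
    """Largest contiguous angular arc of hydrophobic residues on the wheel.

    Residues are ordered by wheel angle (ties broken by peptide index) and
    scanned circularly for the longest run classed hydrophobic.  Returns the
    arc width in degrees, its start angle, and the member residues; an
    all-hydrophilic wheel yields an empty face and an all-hydrophobic wheel a
    360° face.  Among equally long runs the one with the smallest start
    angle wins.
    """
    ordered = sorted(layout.residues, key=lambda r: (r.angle, r.index))
    flags = [r.klass == "hydrophobic" for r in ordered]
    n = len(ordered)
    if not any(flags):
        return {"width_deg": 0.0, "start_angle": None, "residues": []}
    if all(flags):
        return {
            "width_deg": 360.0,
            "start_angle": ordered[0].angle,
            "residues": [r.index for r in ordered],
        }
    # circular scan: a run starts where a hydrophobic residue follows a
    # non-hydrophobic one
    best: tuple[int, float, list] | None = None  # (length, start_angle, members)
    for i in range(n):
        if not (flags[i] and not flags[(i - 1) % n]):
            continue
        members = []
        j = i
        while flags[j % n] and len(members) < n:
            members.append(ordered[j % n])
            j += 1
        start = members[0].angle
        cand = (len(members), start, members)
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and start < best[1]):
            best = cand
    assert best is not None
    _, start, members = best
    end = members[-1].angle
    return {
        "width_deg": float((end - start) % 360.0),
        "start_angle": float(start),
        "residues": [r.index for r in members],
    }
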