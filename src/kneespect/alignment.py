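"""Coronal-plane mechanical hip-knee-ankle (HKA) alignment from landmarks.

The femoral mechanical axis runs from the femoral head centre to the tibial
plateau centre, the tibial mechanical axis from the plateau centre to the
talar centre.  Both are projected onto the coronal plane spanned by the
longitudinal and mediolateral axes of the anatomical knee frame (the
epicondyles serve only to orient that plane, removing flexion/rotation
components).  The HKA deviation is the angle between the projected axes;
the knee is *varus* when the projected distal tibial axis deviates medially
relative to the prolonged femoral axis, *valgus* when laterally.  The signed
convenience angle is positive for varus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .partition import LandmarkSet, knee_frame

__all__ = ["AlignmentResult", "CorrectionSummary", "hka_angle", "report_alignment"]

#: Angles below this magnitude (degrees) are reported as neutral.
NEUTRAL_TOL_DEG = 1e-7


@dataclass(frozen=True)
class AlignmentResult:
    """Coronal mechanical-axis deviation: magnitude, direction word, signed value."""

    angle_deg: float
    direction: str  # "varus" | "valgus" | "neutral"
    signed_deg: float

    def formatted(self, precision: int = 1) -> str:
        """Human-readable form, e.g. ``'4.0° varus'``."""
        return f"{round(self.angle_deg, precision):.{precision}f}° {self.direction}"


@dataclass(frozen=True)
class CorrectionSummary:
    """Pre/post alignment comparison (e.g. across a realignment osteotomy)."""

    pre: AlignmentResult
    post: AlignmentResult
    delta_deg: float
    crossed_neutral: bool


def hka_angle(landmarks: LandmarkSet, neutral_tol_deg: float = NEUTRAL_TOL_DEG) -> AlignmentResult:
    """Mechanical hip-knee-ankle deviation angle with varus/valgus direction.

    Raises
    ------
    GeometryError
        For degenerate landmarks (zero-length mechanical axes or an
        undefined mediolateral direction).
    """
    frame = knee_frame(landmarks)
    femoral = landmarks.tibial_plateau_center - landmarks.femoral_head_center
    tibial = landmarks.talar_center - landmarks.tibial_plateau_center
    if np.linalg.norm(femoral) < 1e-9 or np.linalg.norm(tibial) < 1e-9:
        raise GeometryError("mechanical axis has (near-)zero length")

    # 2D coordinates in the coronal plane: (mediolateral, longitudinal).
    def coronal(v: np.ndarray) -> np.ndarray:
        return np.array([np.dot(v, frame.ml), np.dot(v, frame.si)])

    f2 = coronal(femoral)
    t2 = coronal(tibial)
    nf, nt = np.linalg.norm(f2), np.linalg.norm(t2)
    if nf < 1e-9 or nt < 1e-9:
        raise GeometryError(
            "a mechanical axis is orthogonal to the coronal plane; "
            "the projected HKA angle is undefined"
        )
    cross = float(f2[0] * t2[1] - f2[1] * t2[0])
    dot = float(f2 @ t2)
    angle = math.degrees(math.atan2(abs(cross), dot))

    # Deviation of the distal tibial axis from the prolonged femoral axis,
    # resolved along the medial direction (-ml axis).
    f_hat = f2 / nf
    dev = t2 - (t2 @ f_hat) * f_hat
    medial_component = -float(dev[0])

    if angle <= neutral_tol_deg:
        return AlignmentResult(angle_deg=0.0, direction="neutral", signed_deg=0.0)
    direction = "varus" if medial_component > 0 else "valgus"
    signed = angle if direction == "varus" else -angle
    return AlignmentResult(angle_deg=angle, direction=direction, signed_deg=signed)


def report_alignment(pre: AlignmentResult, post: AlignmentResult) -> CorrectionSummary:
    """Correction achieved between two alignment measurements.

    ``delta_deg = signed_pre - signed_post`` (varus positive), so a 4° varus
    knee corrected to 4° valgus yields an 8° correction with a neutral
    crossing.
    """
    delta = pre.signed_deg - post.signed_deg
    crossed = pre.signed_deg * post.signed_deg < 0
    return CorrectionSummary(pre=pre, post=post, delta_deg=delta, crossed_neutral=crossed)
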