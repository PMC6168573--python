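"""Echocardiographic contractility indices.

FS (%) = (LVEDD - LVESD) / LVEDD x 100, from M-mode left-ventricular
end-diastolic and end-systolic diameters; EF (%) = (EDV - ESV) / EDV x 100,
from end-diastolic and end-systolic volumes. Callers supply consistent
units; both indices are scale-invariant.
"""

from __future__ import annotations

from .containers import MirnetError


def fractional_shortening(lvedd: float, lvesd: float) -> float:
    """Left-ventricular fractional shortening, percent."""
    if lvesd <= 0 or lvedd <= 0:
        raise MirnetError("diameters must be positive")
    if lvesd > lvedd:
        raise MirnetError("end-systolic diameter exceeds end-diastolic diameter")
    return (lvedd - lvesd) / lvedd * 100.0


def ejection_fraction(edv: float, esv: float) -> float:
    """Left-ventricular ejection fraction, percent."""
    if esv <= 0 or edv <= 0:
        raise MirnetError("volumes must be positive")
    if esv > edv:
        raise MirnetError("end-systolic volume exceeds end-diastolic volume")
    return (edv - esv) / edv * 100.0
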