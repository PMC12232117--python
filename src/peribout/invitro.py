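"""Quantification of sensor responses from in vitro ROI timelapses.

Works on already-extracted mean-gray-value traces per ROI (membrane ROIs
are drawn upstream in the imaging software); computes the fractional
fluorescence response dF/F0 to ligand addition and the basal-brightness
statistic over the brightest pixels of an image.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ROITrace
from .errors import DegenerateDataError, InvalidInputError

__all__ = ["dff_response", "basal_brightness"]


def dff_response(trace: ROITrace) -> tuple[np.ndarray, float]:
    """Per-frame dF/F0 and the peak post-ligand response.

    F0 is the mean of the 10 frames immediately before ligand addition;
    dF/F0(t) = (F(t) - F0) / F0.  The scalar response reported per cell is
    the maximum dF/F0 at or after the ligand frame (a plateau mean can be
    computed from the returned series when preferred).
    """
    f0 = float(np.mean(trace.frames[trace.ligand_frame - 10 : trace.ligand_frame]))
    if f0 <= 0:
        raise DegenerateDataError("baseline F0 must be positive")
    dff = (trace.frames - f0) / f0
    peak = float(np.max(dff[trace.ligand_frame :]))
    return dff, peak


def basal_brightness(image_values, top_fraction: float = 0.10) -> float:
    """Mean of the brightest ``top_fraction`` of pixel values.

    The cutoff keeps at least one pixel; ties at the cutoff value are all
    included (so the result is permutation-invariant).
    """
    v = np.asarray(image_values, dtype=float).ravel()
    if v.size == 0:
        raise InvalidInputError("empty pixel collection")
    if not 0 < top_fraction <= 1:
        raise InvalidInputError("top_fraction must be in (0, 1]")
    n_top = max(1, int(np.floor(v.size * top_fraction)))
    cutoff = np.sort(v)[-n_top]
    return float(v[v >= cutoff].mean())
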