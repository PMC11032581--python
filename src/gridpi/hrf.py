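"""Hemodynamic response: canonical double-gamma kernel and convolution.

The canonical SPM double-gamma response (peak 6 s, undershoot 16 s,
undershoot ratio 1/6) is taken from nilearn; regressors are built on a
fine time grid (0.1 s), convolved, and then sampled at the scan TR.
"""

from __future__ import annotations

import numpy as np
from nilearn.glm.first_level import glover_hrf, spm_hrf

__all__ = ["hrf_kernel", "convolve_events", "FINE_DT"]

FINE_DT = 0.1  # seconds; fine grid for neural-signal construction

_KERNELS = {"spm": spm_hrf, "glover": glover_hrf}


def hrf_kernel(name: str = "spm", dt: float = FINE_DT) -> np.ndarray:
    """Canonical response kernel sampled at ``dt`` seconds."""
    try:
        fn = _KERNELS[name]
    except KeyError:
        raise ValueError(f"unknown hrf {name!r}; choose from {sorted(_KERNELS)}")
    # nilearn samples the kernel at t_r/oversampling
    return fn(t_r=1.0, oversampling=round(1.0 / dt))


def convolve_events(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    amplitudes: np.ndarray,
    tr_s: float,
    n_timepoints: int,
    hrf: str = "spm",
) -> np.ndarray:
    """Boxcar-convolve events into a regressor sampled at the scan TRs.

    Each event contributes a boxcar of its duration (a single fine-grid
    stick when the duration is zero) scaled by its amplitude; the summed
    neural signal is convolved with the canonical kernel and linearly
    interpolated at t = k * TR.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    durations_s = np.asarray(durations_s, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    t_end = n_timepoints * tr_s + 32.0
    n_fine = int(np.ceil(t_end / FINE_DT))
    neural = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets_s, durations_s, amplitudes):
        i0 = int(round(onset / FINE_DT))
        i1 = max(int(round((onset + dur) / FINE_DT)), i0 + 1)
        neural[i0 : min(i1, n_fine)] += amp
    kernel = hrf_kernel(hrf, FINE_DT)
    bold_fine = np.convolve(neural, kernel)[:n_fine]
    t_fine = np.arange(n_fine) * FINE_DT
    t_scan = np.arange(n_timepoints) * tr_s
    return np.interp(t_scan, t_fine, bold_fine)
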