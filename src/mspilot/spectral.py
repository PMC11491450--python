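"""Welch spectra, theta-band power, and cortical-area aggregation.

Theta power (4–7.5 Hz) is the spectral feature of interest: frontal
midline theta indexes working memory and cognitive control, and the
area-level summary (frontal, central, temporal, parietal, occipital)
feeds the TASK x STAGE x AREA repeated-measures comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.signal import welch

from .recording import Recording

__all__ = [
    "PsdResult",
    "welch_psd",
    "theta_power",
    "load_area_map",
    "group_by_area",
    "AREAS",
]

AREAS = ("frontal", "central", "temporal", "parietal", "occipital")
THETA_BAND = (4.0, 7.5)


@dataclass
class PsdResult:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # (n_channels, n_freqs), µV²/Hz
    channel_names: list[str]


def welch_psd(
    rec: Recording, window_seconds: float = 2.0, overlap: float = 0.5
) -> PsdResult:
    """Per-channel Welch periodogram with Hamming windows.

    Density scaling: the integral of the PSD over frequency approximates
    the per-channel signal variance.  Frequency resolution is
    ``1/window_seconds`` Hz.
    """
    nperseg = int(round(window_seconds * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError("recording shorter than one Welch window")
    freqs, psd = welch(
        rec.data,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PsdResult(freqs=freqs, psd=psd, channel_names=list(rec.channel_names))


def theta_power(
    psd: PsdResult, band: tuple[float, float] = THETA_BAND
) -> np.ndarray:
    """Band power per channel: trapezoidal integral of the PSD over the band.

    The band is treated as a closed interval; the integral runs over the
    frequency bins inside it.
    """
    lo, hi = band
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError("band outside the PSD frequency range")
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    if sel.sum() < 2:
        raise ValueError("band narrower than the frequency resolution")
    return np.trapezoid(psd.psd[:, sel], psd.freqs[sel], axis=1)


def load_area_map() -> dict[str, str]:
    """The shipped channel-to-area map for a 64-channel 10-20 montage."""
    text = resources.files("mspilot.data").joinpath("areas_biosemi64.json").read_text()
    return json.loads(text)


def group_by_area(
    powers: np.ndarray,
    channel_names: list[str],
    area_map: dict[str, str] | None = None,
    allow_exclude: bool = False,
) -> dict[str, float]:
    """Unweighted mean band power per cortical area.

    Every channel must appear in ``area_map`` unless ``allow_exclude``
    is set, in which case unmapped channels are silently dropped.  The
    output always has exactly the five canonical areas as keys.
    """
    if area_map is None:
        area_map = load_area_map()
    sums = {a: [] for a in AREAS}
    for name, p in zip(channel_names, np.asarray(powers, dtype=float)):
        area = area_map.get(name)
        if area is None:
            if allow_exclude:
                continue
            raise ValueError(f"channel {name!r} is not mapped to an area")
        if area not in sums:
            raise ValueError(f"unknown area {area!r} for channel {name!r}")
        sums[area].append(p)
    return {a: float(np.mean(v)) if v else float("nan") for a, v in sums.items()}
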