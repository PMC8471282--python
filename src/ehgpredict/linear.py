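"""The 20 per-channel linear EHG features.

Peak-to-peak amplitude is computed on both the WBW (0.1-4 Hz) and FWH
(0.34-4 Hz) filtered signals.  All spectral features read from a Welch
power spectral density of the WBW window and are confined to the
0.2-1 Hz band where EHG energy concentrates: dominant frequencies DF1
(0.2-1 Hz) and DF2 (0.34-1 Hz), mean frequency, power-spectrum deciles
D1..D9, normalized subband energies (0.2-0.34, 0.34-0.6, 0.6-1 Hz), the
high(0.34-1)/low(0.2-0.34) energy ratio, and the spectral moment ratio.
Teager energy is a time-domain nonlinear energy operator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import MISSING

logger = logging.getLogger(__name__)

#: Band where the EHG spectral features are evaluated (Hz).
SPECTRAL_BAND = (0.2, 1.0)
NORMEN_EDGES = (0.2, 0.34, 0.6, 1.0)
DF2_BAND = (0.34, 1.0)
#: Cap applied to the high/low energy ratio when the low band is empty.
HL_CAP = 1e6
#: Default spectral-moment orders for the moment ratio (M_a / M_b).
SPMR_ORDERS = (-1, 5)

WELCH_NPERSEG = 512


@dataclass
class PSD:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_mask(self, low: float, high: float) -> np.ndarray:
        return (self.freqs >= low) & (self.freqs <= high)


def welch_psd(x, fs: float, nperseg: int = WELCH_NPERSEG) -> PSD:
    """Welch PSD: Hamming segments with 50% overlap, one-sided."""
    x = np.asarray(x, dtype=float)
    if x.size < nperseg:
        raise ValueError(f"need at least {nperseg} samples, got {x.size}")
    f, p = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")
    return PSD(freqs=f, power=p)


def peak_to_peak(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.max(x) - np.min(x))


def teager_energy(x) -> float:
    """Mean Teager-Kaiser energy, psi[n] = x[n]^2 - x[n-1]*x[n+1]."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.mean(psi))


def spectral_moment(psd: PSD, order: float, low: float, high: float) -> float:
    m = psd.band_mask(low, high)
    f, p = psd.freqs[m], psd.power[m]
    good = f > 0
    return float(np.sum(f[good] ** order * p[good]) * psd.df)


def spectral_feature_set(psd: PSD,
                         spmr_orders: tuple = SPMR_ORDERS) -> dict:
    """The spectral members of the linear feature set, from one PSD.

    Returns a dict with keys MeanF, DF1, DF2, NormEn1..3, HL_ratio,
    D1..D9 and SpMR.  Ratio features fall back to the missing sentinel
    (or a cap, for HL_ratio) on zero in-band power.
    """
    low, high = SPECTRAL_BAND
    m = psd.band_mask(low, high)
    f, p = psd.freqs[m], psd.power[m]
    total = float(np.sum(p))
    out: dict = {}
    if total <= 0.0 or f.size == 0:
        logger.info("zero in-band power; spectral features set to missing")
        for name in (["MeanF", "DF1", "DF2", "HL_ratio", "SpMR"]
                     + [f"NormEn{i}" for i in (1, 2, 3)]
                     + [f"D{k}" for k in range(1, 10)]):
            out[name] = MISSING
        return out

    out["DF1"] = float(f[np.argmax(p)])
    m2 = psd.band_mask(*DF2_BAND)
    f2, p2 = psd.freqs[m2], psd.power[m2]
    out["DF2"] = float(f2[np.argmax(p2)]) if p2.size else MISSING
    out["MeanF"] = float(np.sum(f * p) / total)

    cum = np.cumsum(p) / total
    for k in range(1, 10):
        idx = min(int(np.searchsorted(cum, k / 10.0)), f.size - 1)
        out[f"D{k}"] = float(f[idx])

    e = NORMEN_EDGES
    sub = []
    for i in range(3):
        lo, hi = e[i], e[i + 1]
        # half-open subbands except the last, so bins are not double counted
        bm = (psd.freqs >= lo) & (psd.freqs < hi if i < 2 else psd.freqs <= hi)
        sub.append(float(np.sum(psd.power[bm])))
    for i in range(3):
        out[f"NormEn{i + 1}"] = sub[i] / total

    low_pow = sub[0]
    high_pow = sub[1] + sub[2]
    out["HL_ratio"] = min(high_pow / low_pow, HL_CAP) if low_pow > 0 else HL_CAP

    a, b = spmr_orders
    ma = spectral_moment(psd, a, low, high)
    mb = spectral_moment(psd, b, low, high)
    out["SpMR"] = ma / mb if mb > 0 else MISSING
    return out


#: Names of the 20 linear features per channel, in serialization order.
def linear_feature_names() -> list:
    names = ["App_WBW", "App_FWH", "MeanF", "DF1", "DF2",
             "NormEn1", "NormEn2", "NormEn3", "HL_ratio"]
    names += [f"D{k}" for k in range(1, 10)]
    names += ["Teager", "SpMR"]
    return names
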