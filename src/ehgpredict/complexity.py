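"""Non-linear, non-entropy features: Lempel-Ziv complexity (binary and
6-state), time reversibility, Katz fractal dimension, and Poincaré
ellipse metrics (SD1, SD2, SDRR, SD1/SD2).

Each is computed per window on both the WBW- and FWH-filtered signal,
giving 16 values per channel.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .preprocess import MISSING

logger = logging.getLogger(__name__)


def _quantize(x: np.ndarray, n_states: int, scheme: str) -> np.ndarray:
    if scheme == "median":
        return (x > np.median(x)).astype(np.int64)
    if scheme == "equal_width":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            return np.zeros(x.size, dtype=np.int64)
        sym = np.floor((x - lo) / (hi - lo) * n_states).astype(np.int64)
        return np.minimum(sym, n_states - 1)
    if scheme == "equal_count":
        ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
        return (ranks * n_states // x.size).astype(np.int64)
    raise ValueError(f"unknown quantization scheme {scheme!r}")


def lz76_phrase_count(symbols: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv 1976 parsing of a symbol string.

    Classic complexity-counting scheme (Kaspar-Schuster formulation):
    scan the sequence, extending the current phrase while it occurs
    earlier in the string; each failure starts a new phrase.
    """
    s = list(symbols)
    n = len(s)
    if n == 0:
        return 0
    c = 1
    l = 1          # length already parsed
    i = 0          # candidate match start within the history
    k = 1          # current candidate extension length
    kmax = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            kmax = max(k, kmax)
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


def lempel_ziv(x, n_states: int = 2, binarization: str = "median",
               multistate_bins: str = "equal_width") -> float:
    """Normalized Lempel-Ziv complexity, c * log_alpha(N) / N.

    ``n_states=2`` thresholds at the median (robust to outliers);
    ``n_states>2`` quantizes into equal-width amplitude bins by default
    (``multistate_bins="equal_count"`` selects equal-occupancy bins).
    Both quantizations are data-relative, so the index is invariant
    under affine amplitude transforms.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if n_states == 2:
        sym = _quantize(x, 2, binarization)
    else:
        sym = _quantize(x, n_states, multistate_bins)
    c = lz76_phrase_count(sym)
    n = x.size
    return float(c * math.log(n, n_states) / n)


def time_reversibility(x) -> float:
    """Third moment of lag-1 first differences, (1/(N-1)) * sum(dx^3).

    Exactly antisymmetric under time reversal; zero for time-symmetric
    dynamics such as a pure sinusoid over whole periods.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(x)
    return float(np.sum(dx ** 3) / (x.size - 1))


def katz_fd(x) -> float:
    """Katz fractal dimension of the (i, x[i]) planar curve.

    KFD = log10(n) / (log10(n) + log10(d / L)) with n = N - 1 steps,
    L the total curve length and d the maximal distance from the first
    point.  Straight lines give exactly 1; constant input is degenerate
    and returns the missing sentinel.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = np.diff(x)
    L = float(np.sum(np.sqrt(1.0 + dx ** 2)))
    i = np.arange(x.size, dtype=float)
    d = float(np.max(np.sqrt(i ** 2 + (x - x[0]) ** 2)))
    if d == 0.0 or L == 0.0:
        logger.info("katz_fd: constant signal, returning missing")
        return MISSING
    n = x.size - 1
    return float(math.log10(n) / (math.log10(n) + math.log10(d / L)))


def poincare_metrics(x) -> dict:
    """Poincaré ellipse metrics of consecutive amplitudes (x[n] vs x[n-1]).

    SD1/SD2 are the dispersions across/along the identity line of the
    lag-1 return map of the mean-centered signal (sample variance,
    ddof=1); SDRR = sqrt((SD1^2 + SD2^2)/2).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - np.mean(x)
    u, v = xc[:-1], xc[1:]
    sd1 = math.sqrt(float(np.var(u - v, ddof=1)) / 2.0)
    sd2 = math.sqrt(float(np.var(u + v, ddof=1)) / 2.0)
    sdrr = math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    ratio = sd1 / sd2 if sd2 > 0 else MISSING
    if sd2 == 0:
        logger.info("poincare_metrics: SD2 = 0, ratio set to missing")
    return {"SD1": sd1, "SD2": sd2, "SDRR": sdrr, "SD1_SD2": ratio}


def complexity_feature_names() -> list:
    """The 8 complexity feature names (computed per band, 16/channel)."""
    return ["LZBin", "LZMulti", "TimeRev", "KFD", "SD1", "SD2", "SDRR",
            "SD1_SD2"]
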