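"""Entropy estimators for EHG regularity analysis.

Five estimators are provided:

* **Sample entropy** (SampEn): negative log conditional probability that
  templates matching for ``m`` points (Chebyshev distance, tolerance
  ``r`` times the window standard deviation) still match at ``m+1``,
  excluding self-matches.
* **Fuzzy entropy** (FuzEn): SampEn with the hard tolerance replaced by
  a graded membership function of inter-vector distance, after
  per-vector baseline (mean) removal.
* **Spectral entropy** (SpEn): normalized Shannon entropy of the
  in-band power spectral density.
* **Dispersion entropy** (DispEn): Shannon entropy of the distribution
  of ``c``-class, ``m``-length symbol patterns after a mapping function
  (linear, normal CDF, tangent/log sigmoid, or rank sorting).
* **Bubble entropy** (BubbEn): difference of order-2 Rényi entropies of
  the bubble-sort swap-count (inversion-count) distributions at
  embedding sizes ``m+1`` and ``m``, normalized by ln((m+1)/(m-1)).
  Its only internal parameter is ``m``.

Internal parameters are optimized per estimator/band/channel by the
Wilcoxon rank-sum separability of record-level medians between term and
preterm groups (:func:`optimize_entropy_params`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .linear import PSD
from .preprocess import MISSING, BandSpec
from .stats import ranksum_test

logger = logging.getLogger(__name__)

ESTIMATORS = ("SampEn", "FuzEn", "SpEn", "DispEn", "BubbEn")
DISPEN_MAPPINGS = ("linear", "ncdf", "tansig", "logsig", "sorting")
FUZEN_MEMBERSHIPS = ("triangular", "trapezoidal", "z_shaped", "bell_shaped",
                     "gaussian", "constant_gaussian", "exponential")

#: Default (r, n) per fuzzy membership family.  The exponential pair is
#: the published optimum for discriminating biomedical signals; the other
#: families' optima live in the cited fuzzy-membership literature and are
#: configurable placeholders here.
FUZEN_FAMILY_DEFAULTS: dict = {
    "exponential": (0.0077, 3),
    "gaussian": (0.12, 2),
    "constant_gaussian": (0.12, 2),
    "bell_shaped": (0.14, 2),
    "triangular": (0.3, 1),
    "trapezoidal": (0.13, 1),
    "z_shaped": (0.13, 1),
}


@dataclass(frozen=True)
class EntropyParams:
    """Internal parameter settings for one entropy estimator."""

    estimator: str
    m: int = 2
    r: float | None = None
    n: int | None = None
    c: int | None = None
    mapping: str | None = None
    membership: str | None = None
    tau: int = 1

    def as_dict(self) -> dict:
        d = {"estimator": self.estimator, "m": self.m, "tau": self.tau}
        for k in ("r", "n", "c", "mapping", "membership"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _template_match_counts(x: np.ndarray, m: int, r_abs: float,
                           tau: int) -> tuple:
    """Pairs of templates within ``r_abs`` (Chebyshev) at lengths m, m+1.

    Both counts use the same N - m*tau templates so every length-m
    template has a length-(m+1) extension; self-matches are excluded.
    """
    n = x.size
    L = n - m * tau
    if L < 2:
        raise ValueError("sequence too short for the requested embedding")
    close = np.abs(x[:, None] - x[None, :]) <= r_abs
    acc_m = np.ones((L, L), dtype=bool)
    for k in range(m):
        acc_m &= close[k * tau:k * tau + L, k * tau:k * tau + L]
    acc_m1 = acc_m & close[m * tau:m * tau + L, m * tau:m * tau + L]
    b = (int(acc_m.sum()) - L) // 2
    a = (int(acc_m1.sum()) - L) // 2
    return a, b


def sample_entropy(x, m: int, r: float, tau: int = 1) -> float:
    """Sample entropy in nats; ``r`` is a fraction of the window sd."""
    x = np.asarray(x, dtype=float)
    if r <= 0:
        raise ValueError("r must be positive")
    if x.size < m * tau + 2:
        raise ValueError("sequence too short")
    sd = float(np.std(x))
    r_abs = r * sd
    a, b = _template_match_counts(x, m, r_abs, tau)
    if a == 0 or b == 0:
        logger.info("sample_entropy: degenerate match counts (A=%d, B=%d)", a, b)
        return MISSING
    return float(-math.log(a / b))


def _membership(d: np.ndarray, r: float, n: int | None,
                family: str) -> np.ndarray:
    """Similarity mu(d; r, n) for the seven fuzzy membership families."""
    if family == "exponential":
        return np.exp(-(d ** n) / r)
    if family == "gaussian":
        return np.exp(-(d ** 2) / (2.0 * r ** 2))
    if family == "constant_gaussian":
        return np.where(d <= r, 1.0, np.exp(-np.log(2.0) * ((d - r) / r) ** 2))
    if family == "bell_shaped":
        return 1.0 / (1.0 + (d / r) ** (2 * (n or 2)))
    if family == "triangular":
        return np.clip(1.0 - d / r, 0.0, 1.0)
    if family == "trapezoidal":
        return np.clip(2.0 - d / r, 0.0, 1.0)
    if family == "z_shaped":
        out = np.zeros_like(d)
        out[d <= r] = 1.0
        mid = (d > r) & (d <= 1.5 * r)
        out[mid] = 1.0 - 2.0 * ((d[mid] - r) / r) ** 2
        upper = (d > 1.5 * r) & (d <= 2.0 * r)
        out[upper] = 2.0 * ((d[upper] - 2.0 * r) / r) ** 2
        return out
    raise ValueError(f"unknown membership family {family!r}")


def _phi_fuzzy(x: np.ndarray, m: int, r: float, n: int | None, family: str,
               tau: int, L: int) -> float:
    emb = np.empty((L, m))
    for k in range(m):
        emb[:, k] = x[k * tau:k * tau + L]
    emb -= emb.mean(axis=1, keepdims=True)
    dist = np.zeros((L, L))
    for k in range(m):
        np.maximum(dist, np.abs(emb[:, k, None] - emb[None, :, k]), out=dist)
    mu = _membership(dist, r, n, family)
    np.fill_diagonal(mu, 0.0)
    return float(mu.sum() / (L * (L - 1)))


def fuzzy_entropy(x, m: int, r: float, n: int = 2,
                  membership: str = "exponential", tau: int = 1,
                  normalize: bool = False) -> float:
    """Fuzzy entropy in nats; ``r`` is an absolute membership width.

    ``normalize=True`` z-scores the window first, which the feature
    extraction layer uses because the published membership widths
    (e.g. exponential r=0.0077) presume roughly unit-variance input.
    """
    x = np.asarray(x, dtype=float)
    if membership not in FUZEN_MEMBERSHIPS:
        raise ValueError(f"unknown membership {membership!r}")
    if x.size < m * tau + 2:
        raise ValueError("sequence too short")
    if normalize:
        sd = float(np.std(x))
        if sd > 0:
            x = (x - np.mean(x)) / sd
    L = x.size - m * tau
    phi_m = _phi_fuzzy(x, m, r, n, membership, tau, L)
    phi_m1 = _phi_fuzzy(x, m + 1, r, n, membership, tau, L)
    if phi_m <= 0.0 or phi_m1 <= 0.0:
        logger.info("fuzzy_entropy: zero similarity sum, returning missing")
        return MISSING
    return float(math.log(phi_m) - math.log(phi_m1))


def spectral_entropy(psd: PSD, band: BandSpec) -> float:
    """Normalized Shannon entropy of the in-band PSD, in [0, 1]."""
    mask = psd.band_mask(band.low, band.high)
    p = psd.power[mask]
    total = float(p.sum())
    if total <= 0.0 or p.size < 2:
        logger.info("spectral_entropy: zero in-band power")
        return MISSING
    q = p / total
    q = q[q > 0]
    h = float(-(q * np.log(q)).sum())
    return h / math.log(p.size)


def _dispersion_classes(x: np.ndarray, c: int, mapping: str) -> np.ndarray:
    """Map samples to integer classes 1..c."""
    n = x.size
    if mapping == "linear":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            return np.ones(n, dtype=np.int64)
        z = np.floor((x - lo) / (hi - lo) * c).astype(np.int64) + 1
        return np.minimum(z, c)
    if mapping == "sorting":
        ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable") + 1
        return np.ceil(ranks * c / n).astype(np.int64)
    mu, sigma = float(np.mean(x)), float(np.std(x))
    if sigma == 0.0:
        return np.ones(n, dtype=np.int64)
    s = (x - mu) / sigma
    if mapping == "ncdf":
        y = ndtr(s)
    elif mapping == "tansig":
        y = (np.tanh(s) + 1.0) / 2.0
    elif mapping == "logsig":
        y = 1.0 / (1.0 + np.exp(-s))
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    z = np.round(c * y + 0.5).astype(np.int64)
    return np.clip(z, 1, c)


def dispersion_entropy(x, m: int, c: int, mapping: str = "linear",
                       tau: int = 1, normalized: bool = False) -> float:
    """Dispersion entropy (Shannon entropy of dispersion patterns), nats.

    ``normalized=True`` divides by ln(c^m), mapping the value to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if c < 2:
        raise ValueError("c must be at least 2")
    if c ** m >= x.size:
        raise ValueError("need c^m < sequence length")
    z = _dispersion_classes(x, c, mapping)
    L = x.size - (m - 1) * tau
    # encode each m-length pattern as a base-c integer
    code = np.zeros(L, dtype=np.int64)
    for k in range(m):
        code = code * c + (z[k * tau:k * tau + L] - 1)
    _, counts = np.unique(code, return_counts=True)
    p = counts / L
    h = float(-(p * np.log(p)).sum())
    if normalized:
        h /= m * math.log(c)
    return h


def _swap_counts(x: np.ndarray, k: int) -> np.ndarray:
    """Bubble-sort swap count (inversion count) of every k-length vector."""
    L = x.size - k + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, k)
    counts = np.zeros(L, dtype=np.int64)
    for i in range(k - 1):
        for j in range(i + 1, k):
            counts += emb[:, i] > emb[:, j]
    return counts


def _renyi2_of_counts(counts: np.ndarray) -> float:
    _, occ = np.unique(counts, return_counts=True)
    p = occ / counts.size
    return float(-math.log(float((p ** 2).sum())))


def bubble_entropy(x, m: int) -> float:
    """Bubble entropy, (H2_{m+1} - H2_m) / ln((m+1)/(m-1)).

    H2_k is the order-2 Rényi entropy of the distribution of per-vector
    bubble-sort swap counts at embedding size k.  Strictly monotone
    input gives exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if m < 2:
        raise ValueError("m must be at least 2")
    if x.size < m + 2:
        raise ValueError("sequence too short")
    h_m = _renyi2_of_counts(_swap_counts(x, m))
    h_m1 = _renyi2_of_counts(_swap_counts(x, m + 1))
    return float((h_m1 - h_m) / math.log((m + 1) / (m - 1)))


# ---------------------------------------------------------------------------
# Parameter grids and the separability sweep
# ---------------------------------------------------------------------------

def parameter_grid(estimator: str, window_len: int | None = None) -> list:
    """The internal-parameter grid swept for each estimator.

    SampEn: m 2-5, r 0.05-0.30 step 0.05.  FuzEn: m 2-5 across the seven
    membership families at their per-family (r, n).  DispEn: m 2-5,
    c 3-9, five mappings, subject to c^m < window length.  BubbEn:
    m 2-40.  SpEn has no internal parameters.
    """
    grid: list = []
    if estimator == "SampEn":
        for m in range(2, 6):
            for r in [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]:
                grid.append(EntropyParams("SampEn", m=m, r=round(r, 2)))
    elif estimator == "FuzEn":
        for m in range(2, 6):
            for fam in FUZEN_MEMBERSHIPS:
                r, n = FUZEN_FAMILY_DEFAULTS[fam]
                grid.append(EntropyParams("FuzEn", m=m, r=r, n=n,
                                          membership=fam))
    elif estimator == "DispEn":
        for m in range(2, 6):
            for c in range(3, 10):
                if window_len is not None and c ** m >= window_len:
                    continue
                for mapping in DISPEN_MAPPINGS:
                    grid.append(EntropyParams("DispEn", m=m, c=c,
                                              mapping=mapping))
    elif estimator == "BubbEn":
        for m in range(2, 41):
            grid.append(EntropyParams("BubbEn", m=m))
    elif estimator == "SpEn":
        grid.append(EntropyParams("SpEn"))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return grid


def evaluate_entropy(x, params: EntropyParams, fs: float | None = None,
                     band: BandSpec | None = None,
                     psd: PSD | None = None,
                     fuzen_normalize: bool = True) -> float:
    """Evaluate one estimator on one window under the given parameters."""
    est = params.estimator
    if est == "SampEn":
        return sample_entropy(x, params.m, params.r, params.tau)
    if est == "FuzEn":
        return fuzzy_entropy(x, params.m, params.r, params.n or 2,
                             params.membership or "exponential", params.tau,
                             normalize=fuzen_normalize)
    if est == "DispEn":
        return dispersion_entropy(x, params.m, params.c,
                                  params.mapping or "linear", params.tau)
    if est == "BubbEn":
        return bubble_entropy(x, params.m)
    if est == "SpEn":
        if psd is None:
            from .linear import welch_psd
            psd = welch_psd(x, fs)
        return spectral_entropy(psd, band)
    raise ValueError(f"unknown estimator {est!r}")


@dataclass
class EntropySweepResult:
    """Outcome of an internal-parameter sweep."""

    best: EntropyParams
    p_value: float
    grid: list = field(default_factory=list)  # list of (params, p_value)


def _tie_key(p: EntropyParams):
    mapping_order = (DISPEN_MAPPINGS.index(p.mapping)
                     if p.mapping in DISPEN_MAPPINGS else
                     FUZEN_MEMBERSHIPS.index(p.membership)
                     if p.membership in FUZEN_MEMBERSHIPS else 0)
    return (p.m, p.r if p.r is not None else (p.c or 0), mapping_order)


def optimize_entropy_params(estimator: str, grid,
                            per_record_values: dict,
                            labels) -> EntropySweepResult:
    """Pick the grid point with the lowest rank-sum p-value between classes.

    ``per_record_values`` maps each grid point to its record-level
    feature values (medians over windows), aligned with ``labels``
    ('term'/'preterm').  Ties are broken by smaller m, then smaller
    r (or c), then mapping/membership list order.  Grid points whose
    values are all missing are skipped with a warning.
    """
    labels = np.asarray(labels)
    is_pre = labels == "preterm"
    if not is_pre.any() or is_pre.all():
        raise ValueError("both classes must be nonempty")
    results = []
    for params in grid:
        vals = np.asarray(per_record_values[params], dtype=float)
        good = ~np.isnan(vals)
        if not good.any():
            logger.warning("sweep: %s all-missing, skipped", params)
            continue
        x = vals[good & ~is_pre]
        y = vals[good & is_pre]
        if x.size == 0 or y.size == 0:
            logger.warning("sweep: %s one class all-missing, skipped", params)
            continue
        res = ranksum_test(x, y)
        results.append((params, res.p_value))
    if not results:
        raise ValueError("no evaluable grid points")
    best = min(results, key=lambda t: (t[1],) + _tie_key(t[0]))
    return EntropySweepResult(best=best[0], p_value=best[1], grid=results)


def sweep_entropy(windows_per_record, labels, estimator: str,
                  grid=None, fs: float | None = None,
                  band: BandSpec | None = None) -> EntropySweepResult:
    """Convenience wrapper: compute record-level medians per grid point
    (median over each record's windows) and run the sweep."""
    from .preprocess import aggregate_median

    if grid is None:
        wl = min((len(w[0]) for w in windows_per_record if w), default=None)
        grid = parameter_grid(estimator, window_len=wl)
    per_record: dict = {}
    for params in grid:
        vals = []
        for wins in windows_per_record:
            per_win = [evaluate_entropy(w, params, fs=fs, band=band)
                       for w in wins]
            vals.append(aggregate_median(per_win))
        per_record[params] = vals
    return optimize_entropy_params(estimator, grid, per_record, labels)


__all__ = [
    "ESTIMATORS", "DISPEN_MAPPINGS", "FUZEN_MEMBERSHIPS",
    "FUZEN_FAMILY_DEFAULTS", "EntropyParams", "EntropySweepResult",
    "sample_entropy", "fuzzy_entropy", "spectral_entropy",
    "dispersion_entropy", "bubble_entropy", "parameter_grid",
    "evaluate_entropy", "optimize_entropy_params", "sweep_entropy",
]
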