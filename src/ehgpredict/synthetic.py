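"""Synthetic EHG cohorts and abstract feature tables with known ground truth.

The generator emulates the structure of the public term/preterm EHG
databases (TPEHG DB, TPEHGT DS): three bipolar channels at 20 Hz,
~30 min records, a roughly 7:1 term:preterm imbalance, and obstetric
metadata.  Class differences are injected through per-class signal
parameters: oscillation amplitude/frequency, colored-noise level and a
``regularity`` knob in [0, 1] that controls phase jitter (regularity 1 is
a pure periodic oscillation).  Preterm records are generated with higher
regularity than term records, so their entropy features come out lower —
the direction reported for real preterm EHG.

None of this is a physiological uterine-contraction simulation; it is a
controlled test bed with tunable class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import CHANNELS, EHGRecord

TERM, PRETERM = "term", "preterm"

#: AR(1) pole shaping the background noise (1/f-like colored noise).
_NOISE_POLE = 0.9


@dataclass(frozen=True)
class ClassSignalParams:
    """Per-class EHG signal parameters."""

    osc_freq: float  # Hz, dominant oscillation
    osc_amp: float   # µV
    noise_amp: float  # µV (standard deviation of colored noise)
    regularity: float  # in [0, 1]; 1 -> no phase jitter

    def validate(self) -> None:
        if not (0.0 <= self.regularity <= 1.0):
            raise ValueError("regularity must lie in [0, 1]")
        if self.osc_freq <= 0:
            raise ValueError("osc_freq must be positive")


@dataclass(frozen=True)
class SynthCohortParams:
    """Cohort-level generation parameters.

    Defaults mirror the real databases' structure: 20 Hz, 30 min records,
    28 term vs 4 preterm per batch (7:1).  The preterm class is more
    regular — nearly noise-free periodic oscillation — while the term
    class carries moderate phase jitter and relative noise, so every
    entropy estimator (including bubble entropy at high embedding
    dimensions, whose response to phase jitter and relative noise is
    non-monotonic) reads lower for the preterm class.  Class center
    frequencies are kept equal; the term class's spectral broadening
    comes from its phase jitter.
    """

    n_term: int = 28
    n_preterm: int = 4
    fs: float = 20.0
    duration_s: float = 1800.0
    term_params: ClassSignalParams = field(
        default_factory=lambda: ClassSignalParams(
            osc_freq=0.45, osc_amp=50.0, noise_amp=4.5, regularity=0.70))
    preterm_params: ClassSignalParams = field(
        default_factory=lambda: ClassSignalParams(
            osc_freq=0.45, osc_amp=80.0, noise_amp=0.8, regularity=0.98))
    artifact_rate: float = 1.0  # expected artifact intervals per record
    seed: int = 0

    def validate(self) -> None:
        if self.n_term < 0 or self.n_preterm < 0:
            raise ValueError("class counts must be nonnegative")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        for p in (self.term_params, self.preterm_params):
            p.validate()
            if self.fs <= 2.0 * p.osc_freq:
                raise ValueError("fs must exceed twice the oscillation frequency")


def _colored_noise(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """AR(1)-shaped Gaussian noise scaled to standard deviation ``amp``."""
    if amp == 0.0:
        return np.zeros(n)
    e = rng.standard_normal(n)
    y = sps.lfilter([1.0], [1.0, -_NOISE_POLE], e)
    # stationary sd of AR(1): 1/sqrt(1 - pole^2)
    return amp * y * np.sqrt(1.0 - _NOISE_POLE ** 2)


def _oscillation(rng: np.random.Generator, n: int, fs: float,
                 p: ClassSignalParams) -> np.ndarray:
    t = np.arange(n) / fs
    # random-walk phase jitter, per-sample sd scaled by (1 - regularity)
    jitter_sd = 0.2 * (1.0 - p.regularity)
    if jitter_sd > 0:
        phase_jitter = np.cumsum(rng.normal(0.0, jitter_sd, n))
    else:
        phase_jitter = np.zeros(n)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return p.osc_amp * np.sin(2.0 * np.pi * p.osc_freq * t + phase0 + phase_jitter)


def gen_record(class_label: str, params: SynthCohortParams,
               seed: int) -> EHGRecord:
    """Generate one 3-channel record of ``duration_s * fs`` samples.

    Each channel is a band-limited oscillation with class-dependent
    amplitude, frequency and phase jitter, plus AR(1) colored noise.
    Obstetric metadata are drawn from plausible distributions; delivery
    is before week 37 iff the class is preterm.  Fully reproducible
    given (class_label, params, seed).
    """
    params.validate()
    if class_label not in (TERM, PRETERM):
        raise ValueError(f"unknown class label {class_label!r}")
    p = params.term_params if class_label == TERM else params.preterm_params
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs))
    sig = np.column_stack([
        _oscillation(rng, n, params.fs, p) + _colored_noise(rng, n, p.noise_amp)
        for _ in CHANNELS
    ])
    gestation_week = float(rng.uniform(22.0, 37.0))
    if class_label == PRETERM:
        delivery_week = float(rng.uniform(max(gestation_week, 29.0), 37.0))
    else:
        delivery_week = float(rng.uniform(37.0, 42.0))
    obstetric = {
        "age": float(np.clip(rng.normal(31.0, 4.0), 18.0, 45.0)),
        "parity": float(rng.poisson(0.8)),
        "abortions": float(rng.poisson(0.3)),
        "weight": float(np.clip(rng.normal(70.0, 10.0), 45.0, 120.0)),
        "gestation_week": gestation_week,
        "delivery_week": delivery_week,
    }
    artifact_intervals: dict = {}
    for ch in CHANNELS:
        k = rng.poisson(params.artifact_rate)
        ivs = []
        for _ in range(k):
            dur = rng.uniform(5.0, 60.0)
            start = rng.uniform(0.0, max(params.duration_s - dur, 0.0))
            ivs.append((start, min(start + dur, params.duration_s)))
        if ivs:
            artifact_intervals[ch] = sorted(ivs)
    return EHGRecord(
        record_id=f"{class_label}_{seed:06d}",
        signals=sig,
        fs=params.fs,
        obstetric=obstetric,
        label=class_label,
        artifact_intervals=artifact_intervals,
    )


def gen_cohort(params: SynthCohortParams) -> list:
    """Generate ``n_term + n_preterm`` labelled records.

    Per-record seeds are derived deterministically from ``params.seed``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(params.n_term + params.n_preterm) >> 1
    records = []
    for i in range(params.n_term):
        records.append(gen_record(TERM, params, int(seeds[i])))
    for j in range(params.n_preterm):
        records.append(gen_record(PRETERM, params, int(seeds[params.n_term + j])))
    return records


def gen_feature_table(n_per_class: int, n_informative: int, n_noise: int,
                      effect_size: float, seed: int):
    """Two-class Gaussian feature table with planted informative columns.

    Informative columns are unit-variance Gaussians whose class means
    differ by ``effect_size`` (standardized mean difference); noise
    columns are class-independent standard normals.  Column names flag
    the ground truth (``inf_*`` vs ``noise_*``).  Returns a
    :class:`~ehgpredict.pipeline.FeatureTable` with preterm as the class
    shifted by ``+effect_size/2``.
    """
    from .pipeline import FeatureTable

    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if n_informative < 0 or n_noise < 0:
        raise ValueError("column counts must be nonnegative")
    if n_informative + n_noise < 1:
        raise ValueError("at least one column required")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array([TERM] * n_per_class + [PRETERM] * n_per_class)
    shift = np.where(labels == PRETERM, effect_size / 2.0, -effect_size / 2.0)
    cols = {}
    for i in range(n_informative):
        cols[f"inf_{i + 1}"] = rng.standard_normal(n) + shift
    for i in range(n_noise):
        cols[f"noise_{i + 1}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols)
    return FeatureTable(X=X, labels=pd.Series(labels, name="label"),
                        provenance=np.array(["original"] * n))


__all__ = [
    "TERM", "PRETERM", "ClassSignalParams", "SynthCohortParams",
    "gen_record", "gen_cohort", "gen_feature_table",
]
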