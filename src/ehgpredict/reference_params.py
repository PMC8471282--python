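"""Reference optimum entropy parameters for term/preterm discrimination.

These per-estimator/band/channel settings are the published optima found
by sweeping each estimator's internal parameters on the Physionet
term/preterm EHG cohorts (TPEHG DB + TPEHGT DS) and selecting the
configuration with the lowest rank-sum p-value between groups.  They
ship as a packaged default so feature extraction can run without
re-optimization; :func:`ehgpredict.entropy.sweep_entropy` regenerates
such a table from any labelled cohort.
"""

from __future__ import annotations

from .entropy import EntropyParams

_EXP = {"membership": "exponential", "n": 3, "r": 0.0077}

#: keyed by (estimator, band name, channel)
REFERENCE_ENTROPY_PARAMS: dict = {
    # SampEn: m, r (fraction of window sd)
    ("SampEn", "WBW", "S1"): EntropyParams("SampEn", m=3, r=0.15),
    ("SampEn", "WBW", "S2"): EntropyParams("SampEn", m=3, r=0.10),
    ("SampEn", "WBW", "S3"): EntropyParams("SampEn", m=2, r=0.10),
    ("SampEn", "FWH", "S1"): EntropyParams("SampEn", m=2, r=0.30),
    ("SampEn", "FWH", "S2"): EntropyParams("SampEn", m=3, r=0.10),
    ("SampEn", "FWH", "S3"): EntropyParams("SampEn", m=2, r=0.30),
    # FuzEn: exponential membership, r = 0.0077, n = 3
    ("FuzEn", "WBW", "S1"): EntropyParams("FuzEn", m=5, **_EXP),
    ("FuzEn", "WBW", "S2"): EntropyParams("FuzEn", m=5, **_EXP),
    ("FuzEn", "WBW", "S3"): EntropyParams("FuzEn", m=2, **_EXP),
    ("FuzEn", "FWH", "S1"): EntropyParams("FuzEn", m=5, **_EXP),
    ("FuzEn", "FWH", "S2"): EntropyParams("FuzEn", m=5, **_EXP),
    ("FuzEn", "FWH", "S3"): EntropyParams("FuzEn", m=2, **_EXP),
    # DispEn: m, number of classes c, mapping
    ("DispEn", "WBW", "S1"): EntropyParams("DispEn", m=2, c=3, mapping="linear"),
    ("DispEn", "WBW", "S2"): EntropyParams("DispEn", m=2, c=3, mapping="linear"),
    ("DispEn", "WBW", "S3"): EntropyParams("DispEn", m=2, c=3, mapping="linear"),
    ("DispEn", "FWH", "S1"): EntropyParams("DispEn", m=2, c=3, mapping="linear"),
    ("DispEn", "FWH", "S2"): EntropyParams("DispEn", m=3, c=4, mapping="linear"),
    ("DispEn", "FWH", "S3"): EntropyParams("DispEn", m=2, c=7, mapping="logsig"),
    # BubbEn: embedding dimension only
    ("BubbEn", "WBW", "S1"): EntropyParams("BubbEn", m=23),
    ("BubbEn", "WBW", "S2"): EntropyParams("BubbEn", m=23),
    ("BubbEn", "WBW", "S3"): EntropyParams("BubbEn", m=26),
    ("BubbEn", "FWH", "S1"): EntropyParams("BubbEn", m=25),
    ("BubbEn", "FWH", "S2"): EntropyParams("BubbEn", m=24),
    ("BubbEn", "FWH", "S3"): EntropyParams("BubbEn", m=24),
}


def get_entropy_params(estimator: str, band: str, channel: str,
                       overrides: dict | None = None) -> EntropyParams:
    """Look up the reference setting, allowing per-key overrides."""
    key = (estimator, band, channel)
    if overrides and key in overrides:
        return overrides[key]
    if estimator == "SpEn":
        return EntropyParams("SpEn")
    return REFERENCE_ENTROPY_PARAMS[key]
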