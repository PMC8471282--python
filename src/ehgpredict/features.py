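"""Record-level feature extraction: 46 EHG features per channel.

Per channel the inventory is 20 linear features, 16 non-linear
(complexity) features (8 statistics x 2 bands) and 10 entropy features
(5 estimators x 2 bands).  Each feature is computed per 120 s window
(50% overlap) on the artifact-free, band-pass-filtered signal and
reduced to one value per record by the median over windows.  Obstetric
metadata (age, parity, abortions, weight, week of gestation) add 5
cohort-level columns.

Feature names serialize as ``<Feature>_<Band>_<Channel>`` for two-band
features (e.g. ``App_FWH_S2``, ``KFD_WBW_S1``) and ``<Feature>_<Channel>``
for the single-band spectral features (e.g. ``DF1_S2``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import complexity as cx
from . import entropy as ent
from . import linear as lin
from .preprocess import (BANDS, CHANNELS, MISSING, OBSTETRIC_FIELDS, EHGRecord,
                         aggregate_median, artifact_free_segments,
                         segment_windows, zero_phase_bandpass)
from .reference_params import get_entropy_params

logger = logging.getLogger(__name__)

OBSTETRIC_COLUMNS = ("Age", "Parity", "Abortions", "Weight", "WoG")
_OBSTETRIC_MAP = dict(zip(OBSTETRIC_COLUMNS, OBSTETRIC_FIELDS))


def ehg_feature_names() -> list:
    """All 46 EHG feature names for one channel (without channel suffix)."""
    names = []
    for f in lin.linear_feature_names():
        names.append(f)  # App_WBW / App_FWH already carry the band
    for band in BANDS:
        for f in cx.complexity_feature_names():
            names.append(f"{f}_{band.name}")
    for band in BANDS:
        for e in ent.ESTIMATORS:
            names.append(f"{e}_{band.name}")
    return names


def all_feature_columns() -> list:
    """The full 143-column inventory: 46 x 3 channels + 5 obstetric."""
    cols = []
    for ch in CHANNELS:
        cols += [f"{n}_{ch}" for n in ehg_feature_names()]
    cols += list(OBSTETRIC_COLUMNS)
    return cols


def extract_channel_features(record: EHGRecord, channel: str,
                             entropy_overrides: dict | None = None,
                             win_s: float = 120.0,
                             overlap: float = 0.5) -> dict:
    """Compute the 46 features of one channel, median-aggregated over windows.

    Filtering (per band), artifact excision and windowing happen here;
    every window lies wholly inside an artifact-free segment.
    """
    fs = record.fs
    values: dict = {name: [] for name in ehg_feature_names()}
    band_windows = {}
    for band in BANDS:
        filtered = zero_phase_bandpass(record.channel(channel), fs, band)
        segs = artifact_free_segments(record, channel, signal=filtered)
        band_windows[band.name] = segment_windows(segs, fs, win_s, overlap)

    wbw_ws = band_windows["WBW"]
    fwh_ws = band_windows["FWH"]
    n_windows = min(len(wbw_ws), len(fwh_ws))
    if n_windows == 0:
        logger.warning("record %s channel %s: no artifact-free windows",
                       record.record_id, channel)

    for i in range(n_windows):
        w_wbw = wbw_ws.windows[i]
        w_fwh = fwh_ws.windows[i]
        psd = lin.welch_psd(w_wbw, fs) if w_wbw.size >= lin.WELCH_NPERSEG else None

        values["App_WBW"].append(lin.peak_to_peak(w_wbw))
        values["App_FWH"].append(lin.peak_to_peak(w_fwh))
        values["Teager"].append(lin.teager_energy(w_wbw))
        if psd is not None:
            spec = lin.spectral_feature_set(psd)
            for k, v in spec.items():
                values[k].append(v)
        for band, w in (("WBW", w_wbw), ("FWH", w_fwh)):
            values[f"LZBin_{band}"].append(cx.lempel_ziv(w, 2))
            values[f"LZMulti_{band}"].append(cx.lempel_ziv(w, 6))
            values[f"TimeRev_{band}"].append(cx.time_reversibility(w))
            values[f"KFD_{band}"].append(cx.katz_fd(w))
            for k, v in cx.poincare_metrics(w).items():
                values[f"{k}_{band}"].append(v)
        for band_spec, w in ((BANDS[0], w_wbw), (BANDS[1], w_fwh)):
            band = band_spec.name
            band_psd = (psd if band == "WBW" else
                        (lin.welch_psd(w, fs) if w.size >= lin.WELCH_NPERSEG
                         else None))
            for est in ent.ESTIMATORS:
                params = get_entropy_params(est, band, channel,
                                            entropy_overrides)
                try:
                    v = ent.evaluate_entropy(w, params, fs=fs, band=band_spec,
                                             psd=band_psd)
                except ValueError:
                    v = MISSING
                values[f"{est}_{band}"].append(v)

    return {name: aggregate_median(vals) for name, vals in values.items()}


def extract_feature_table(records, entropy_overrides: dict | None = None,
                          win_s: float = 120.0, overlap: float = 0.5):
    """Extract the full feature table (143 columns) for a cohort.

    Returns a :class:`~ehgpredict.pipeline.FeatureTable`; missing values
    are left as NaN here and median-imputed at model-matrix build time.
    """
    from .pipeline import FeatureTable

    rows, labels, ids = [], [], []
    for rec in records:
        row: dict = {}
        for ch in CHANNELS:
            feats = extract_channel_features(rec, ch, entropy_overrides,
                                             win_s, overlap)
            for name, v in feats.items():
                row[f"{name}_{ch}"] = v
        for col, fld in _OBSTETRIC_MAP.items():
            row[col] = rec.obstetric.get(fld, MISSING)
        rows.append(row)
        labels.append(rec.label)
        ids.append(rec.record_id)
    X = pd.DataFrame(rows, index=ids, columns=all_feature_columns())
    return FeatureTable(X=X, labels=pd.Series(labels, index=ids, name="label"),
                        provenance=np.array(["original"] * len(rows)))
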