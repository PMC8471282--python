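"""Generate a synthetic term/preterm EHG cohort and write it to CSV.

The generator mimics the structure of the public term/preterm EHG
databases: 3 bipolar channels at 20 Hz, obstetric metadata, a 7:1
class imbalance, and artifact-interval annotations.  The preterm class
is more regular (less phase jitter, less relative noise), so its
entropy features come out lower — the direction reported for real
preterm EHG.
"""

import ehgpredict as ep

params = ep.SynthCohortParams(n_term=14, n_preterm=2, duration_s=300.0,
                              seed=1)
records = ep.gen_cohort(params)
ep.write_cohort(records, "scratch/example_cohort")

print(f"cohort: {len(records)} records "
      f"({sum(r.label == 'preterm' for r in records)} preterm)")
rec = records[0]
print(f"first record: {rec.record_id}, {rec.signals.shape[0]} samples/channel "
      f"@ {rec.fs:g} Hz")
print(f"  gestation week at recording: {rec.obstetric['gestation_week']:.1f}")
print(f"  artifact intervals on S1: {rec.artifact_intervals.get('S1', [])}")
# Each record is one CSV (t, S1, S2, S3); manifest.csv carries labels and
# obstetric metadata; artifacts.csv the corrupt-segment annotations.
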