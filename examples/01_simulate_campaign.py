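"""Generate one synthetic participant-week and look at what it contains.

The generator emulates a wearable personal-exposure campaign: a semi-Markov
schedule over five microenvironments (nights at home), environment-dependent
pollutant levels, GPS, and ledger-recorded sensor faults.
"""

import wearaq as wq

schedule = wq.generate_schedule(duration_days=7, seed=1)
print("schedule:", len(schedule), "bouts")
print("realized occupancy (fraction of time per environment):")
for env, frac in sorted(schedule.occupancy().items(), key=lambda kv: -kv[1]):
    print(f"  {env:<10} {frac:6.1%}")

traces = wq.generate_traces(schedule, seed=2, participant_id="p01")
print("\nchannels:", [s.channel for s in traces.channels])
print("GPS points:", len(traces.gps))
print("injected sensor faults (ground-truth ledger):")
print(traces.artifact_ledger["kind"].value_counts().to_string())
# The occupancy above is what the analysis should recover downstream; the
# ledger is what the curation chain should remove.
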