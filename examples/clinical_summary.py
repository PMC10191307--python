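"""Clinical sleep metrics of one synthetic night.

Generates a full 960-epoch (8-h) four-class night and prints the derived
hypnogram summary: total sleep time, efficiency, onset latency (first run
of three consecutive sleep epochs), fragmentation, the sleep transition
index, and per-stage times and fractions. Stage fractions are over sleep
epochs only, so they sum to 1 across Light/Deep/REM.
"""

from somnoseq import HypnogramModel, clinical_metrics, gen_hypnogram

hyp = gen_hypnogram(HypnogramModel(), n_epochs=960, seed=3)
m = clinical_metrics(hyp)

print(f"recording time        {m.recording_time_h:5.2f} h")
print(f"total sleep time      {m.total_sleep_time_h:5.2f} h")
print(f"sleep efficiency      {m.sleep_efficiency:5.2f}")
print(f"sleep onset latency   {m.sleep_onset_latency_min:5.1f} min")
print(f"sleep fragmentation   {m.sleep_fragmentation:5.2f} awakenings/h of sleep")
print(f"sleep transition idx  {m.sleep_transition_index:5.2f}")
for lab, t in m.stage_time_h.items():
    frac = m.stage_fraction.get(lab)
    extra = f"  ({frac:.2f} of sleep)" if frac is not None else ""
    print(f"  time in {lab:<6} {t:5.2f} h{extra}")
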