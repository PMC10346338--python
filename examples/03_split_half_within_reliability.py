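"""Within-person reliability: split-half mixed-model slopes, sleep vs wake.

Each participant-day-state cell's samples are split into two halves; a mixed
model predicts one half-mean from the other with a participant random
intercept.  The slope beta is the reliability: near 1 when repeated samples
of the same state agree, near 0 when they are mostly noise.  HRV is simulated
with far noisier wakeful samples, so sleep should beat wake.
"""

from pulserel import (
    detect_sleep_periods,
    fit_split_model,
    label_state,
    random_split_distribution,
    remove_zero_samples,
    rmssd_study_config,
    bpm_study_config,
    split_time_sensitive,
)
from pulserel.synthetic import simulate_stream

hrv = simulate_stream(rmssd_study_config(seed=23), n_days=7, metric="rmssd").stream
bpm = simulate_stream(bpm_study_config(seed=23), n_days=7).stream  # defines sleep periods
stream = remove_zero_samples(label_state(hrv, detect_sleep_periods(bpm)))

for state in ("sleep", "wake"):
    sub = stream.with_records(stream.records[stream.records["state"] == state])

    pairs = split_time_sensitive(sub, "study2", metric="rmssd")
    ts = fit_split_model(pairs, random_factors=("participant",))
    print(f"{state:5s} time-sensitive: beta = {ts.beta:.3f}, "
          f"t({ts.df:.1f}) = {ts.t_stat:.2f}, p = {ts.p_value:.2g} ({ts.n_units} units)")

    summary = random_split_distribution(
        sub, "study2", ("participant",), n_iterations=300, master_seed=4, metric="rmssd"
    )
    print(f"{state:5s} random x300   : mean beta = {summary.mean_beta:.3f}, "
          f"SD = {summary.sd_beta:.3f}")

print()
print("Sleep HRV is highly consistent within a night; wakeful HRV is not --\n"
      "the same ordering the toolkit is designed to expose on real streams.")
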