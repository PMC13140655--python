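"""Estimate directed information flow on one coupled channel pair.

Simulates a recording with a single strong HR -> RF coupling at the
5-breath horizon, estimates TE in both directions, scans lags 1..5 and
runs the 100-shuffle surrogate test.
"""

from breathnet import (CouplingSpec, Edge, TEConfig,
                       generate_participant_recording, lag_scan,
                       surrogate_test, transfer_entropy)

spec = CouplingSpec(edges=(Edge("HR", "RF", 5, 0.9), Edge("HR", "RF", 4, 0.9)))
rec = generate_participant_recording(spec, rf=20, window_minutes=5, seed=1)
cfg = TEConfig(lag=5)

fwd = transfer_entropy(rec["HR"], rec["RF"], cfg)
rev = transfer_entropy(rec["RF"], rec["HR"], cfg)
print(f"TE(HR->RF) = {fwd:.3f} bits   TE(RF->HR) = {rev:.3f} bits")

scan = lag_scan(rec["HR"], rec["RF"], cfg)
print("lag scan:", {int(l): round(float(v), 3) for l, v in
                    zip(scan.lags, scan.te_values)},
      "plateau at lag", scan.plateau_lag)

res = surrogate_test(rec["HR"], rec["RF"], cfg, seed=3)
print(f"surrogate test: observed {res.observed_te:.3f} vs threshold "
      f"{res.threshold:.3f} -> significant={res.significant}")
# Raw TE values carry a small-sample bias (both directions are positive);
# only the surrogate comparison says which direction is real information
# flow rather than shared bias.
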