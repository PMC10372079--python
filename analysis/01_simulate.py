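#!/usr/bin/env python
"""Simulate a two-session study: one 5-HT2A-class session (127 Hz HFO
carrier, head twitches, broad rate suppression) and one NMDA-class session
(143 Hz carrier, interneuron excitation).  Sessions are written as HDF5
containers under scratch/sessions/ and the ground truth (channel lags, unit
phase preferences, twitch times) as CSV under results/ground_truth/.

Durations are scaled to 260 s (100 s pre / 140 s post injection) with the
same epoch logic as the full-length protocol; see docs/methods.md.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hfosync.session import write_session
from hfosync.synth import HtrConfig, SpikeConfig, gen_session, preset

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out_sessions = ROOT / "scratch" / "sessions"
    out_truth = ROOT / "results" / "ground_truth"
    out_sessions.mkdir(parents=True, exist_ok=True)
    out_truth.mkdir(parents=True, exist_ok=True)

    twitches = list(130.0 + 18.0 * np.arange(7))  # post-injection head twitches
    configs = {
        "session_5ht2a": preset(
            "5HT2A", duration=260.0, injection_time=120.0,
            structures={"OB": 2, "vStr": 4, "mPFC": 2},
            spikes=SpikeConfig(base_rate=5.0, n_units={"PC": 2, "IN": 2}),
            htr=HtrConfig(event_times=twitches),
            seed=args.seed * 1000 + 1,
        ),
        "session_nmda": preset(
            "NMDA", duration=260.0, injection_time=120.0,
            structures={"OB": 2, "vStr": 4, "mPFC": 2},
            spikes=SpikeConfig(base_rate=5.0, n_units={"PC": 2, "IN": 2}),
            seed=args.seed * 1000 + 2,
        ),
    }

    for name, cfg in configs.items():
        sess, gt = gen_session(cfg)
        write_session(sess, out_sessions / f"{name}.h5")
        pd.DataFrame(
            {"channel_id": [c.channel_id for c in sess.channels],
             "structure": [c.structure for c in sess.channels],
             "true_lag_rad": gt.channel_lags}
        ).to_csv(out_truth / f"{name}_channel_lags.csv", index=False)
        pd.DataFrame(gt.units).to_csv(out_truth / f"{name}_units.csv", index=False)
        pd.DataFrame({"twitch_time_s": gt.twitch_times}).to_csv(
            out_truth / f"{name}_twitches.csv", index=False)
        n_spk = sum(len(u.spike_times) for u in sess.units)
        print(f"{name}: {sess.lfp.shape[0]} channels x {sess.duration:.0f} s at "
              f"{sess.fs_lfp:.0f} Hz, {len(sess.units)} units ({n_spk} spikes), "
              f"carrier {cfg.hfo.carrier_freq:.0f} Hz, {len(gt.twitch_times)} twitches")

    print(f"containers -> {out_sessions}, ground truth -> {out_truth}")


if __name__ == "__main__":
    main()
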