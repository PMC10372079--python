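#!/usr/bin/env python
"""Summarize the pipeline outputs against the simulated ground truth:
prevalence classes per structure/condition, phase-lag medians and inversion
counts, entrainment and modulation fractions per cell class, head-twitch
detection performance, and the strongest directed couplings.  Writes
results/summary.csv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "results" / "pipeline"


def main():
    if not PIPE.exists():
        raise SystemExit("no pipeline outputs; run analysis/02_run_pipeline.py first")
    rows = []

    prev = pd.read_csv(PIPE / "prevalence.csv")
    print("HFO prevalence classes (structure x condition):")
    print(prev.pivot_table(index="structure", columns=["drug_class", "epoch"],
                           values="class", aggfunc="first"))
    for _, r in prev.iterrows():
        rows.append(("prevalence", f"{r.structure}/{r.drug_class}/{r.epoch}", r["class"]))

    lags = pd.read_csv(PIPE / "structure_lags.csv")
    if len(lags):
        print("\nmedian phase lag vs reference structure (rad; positive = leads):")
        print(lags.round(3).to_string(index=False))
        for _, r in lags.iterrows():
            rows.append(("median_lag_rad", f"{r.session}/{r.structure}", round(r.median_lag, 4)))

    pairs = pd.read_csv(PIPE / "phase_pairs.csv")
    if len(pairs):
        strong = pairs[pairs.kappa > 1]
        frac_strong = len(strong) / len(pairs)
        frac_zero = (strong.dphi.abs() < np.pi / 4).mean() if len(strong) else np.nan
        frac_inv = pairs.inverted.mean()
        print(f"\nphase pairs: {100*frac_strong:.0f}% with kappa>1; of those "
              f"{100*frac_zero:.0f}% near zero lag; {100*frac_inv:.1f}% inverted")
        rows += [("pairs_kappa_gt1_pct", "all", round(100 * frac_strong, 1)),
                 ("pairs_zero_lag_pct", "kappa>1", round(100 * frac_zero, 1)),
                 ("pairs_inverted_pct", "all", round(100 * frac_inv, 2))]

    ent = pd.read_csv(PIPE / "entrainment.csv")
    fit = ent[~ent.mu.isna()]
    if len(fit):
        frac = fit.entrained.mean()
        mu_mean = np.angle(np.exp(1j * fit[fit.entrained].mu).mean()) if fit.entrained.any() else np.nan
        print(f"\nentrainment: {100*frac:.0f}% of units entrained; "
              f"population preferred phase {mu_mean:.2f} rad (trough = 0)")
        rows += [("entrained_pct", "all", round(100 * frac, 1)),
                 ("preferred_phase_rad", "entrained", round(float(mu_mean), 3))]

    mods = pd.read_csv(PIPE / "rate_modulation.csv")
    ok = mods[~mods.excluded]
    if len(ok):
        for cls, grp in ok.groupby("mod_class"):
            rows.append(("modulated_pct", cls, round(100 * len(grp) / len(ok), 1)))
        print("\nrate modulation classes:")
        print(ok.mod_class.value_counts().to_string())

    htr = pd.read_csv(PIPE / "htr_events.csv")
    truth_files = sorted((ROOT / "results" / "ground_truth").glob("*_twitches.csv"))
    n_truth = sum(len(pd.read_csv(f)) for f in truth_files)
    print(f"\nhead twitches: {len(htr)} detected / {n_truth} simulated")
    rows.append(("htr_detected", "all", len(htr)))

    gc = pd.read_csv(PIPE / "granger.csv")
    with_peak = gc.dropna(subset=["median_peak"])
    if len(with_peak):
        top = with_peak.sort_values("median_peak", ascending=False).head(3)
        print("\nstrongest directed couplings (median GC peak):")
        print(top[["session", "direction", "median_peak"]].round(3).to_string(index=False))
        for _, r in top.iterrows():
            rows.append(("granger_peak", f"{r.session}/{r.direction}", round(r.median_peak, 3)))

    out = ROOT / "results" / "summary.csv"
    pd.DataFrame(rows, columns=["measure", "key", "value"]).to_csv(out, index=False)
    print(f"\nsummary -> {out}")


if __name__ == "__main__":
    main()
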