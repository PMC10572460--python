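"""Simulate one example recording per modality and write it to disk.

Produces, under results/simulated/: a wide CSV of astrocyte fluorescence
traces, a spontaneous-EPSC sweep, a paired-pulse sweep, a compound PSC, a
field-potential input-output family, and an LFP recording with one
after-discharge — each with a JSON ground-truth sidecar.
"""

import json
from pathlib import Path

import pandas as pd

from epiphys.io import write_signal_csv, write_table
from epiphys.synthetic import (
    CaSimConfig,
    LfpSimConfig,
    PscSimConfig,
    gen_calcium_traces,
    gen_compound_psc,
    gen_fepsp_family,
    gen_lfp,
    gen_paired_pulse,
    gen_psc_sweep,
)

SEED = 1
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = {"seed": SEED}

    traces, ca_truth = gen_calcium_traces(CaSimConfig(n_cells=5, seed=SEED))
    wide = pd.DataFrame({tr.cell_id: tr.values for tr in traces})
    wide.insert(0, "frame", range(len(traces[0].values)))
    write_table(OUT / "calcium_traces.csv", wide, meta)
    ca_truth.events.to_json(OUT / "calcium_truth.json", orient="records")
    print(f"calcium: {len(traces)} cells, {ca_truth.n_events} true transients")

    sweep, psc_truth = gen_psc_sweep(PscSimConfig(seed=SEED))
    write_signal_csv(OUT / "sepsc_sweep.csv", sweep.times_ms, sweep.values,
                     meta | {"units": "pA"})
    psc_truth.events.to_json(OUT / "sepsc_truth.json", orient="records")
    print(f"sEPSC sweep: {psc_truth.n_events} events in "
          f"{sweep.duration_s:.0f} s")

    pp = gen_paired_pulse(100.0, 0.8, kernel=PscSimConfig(seed=SEED))
    write_signal_csv(OUT / "paired_pulse.csv", pp.times_ms, pp.values,
                     meta | {"units": "pA", "stim_times_ms": pp.stim_times_ms,
                             "ppr_true": 0.8})

    cp = gen_compound_psc(200.0, 4000.0, 150.0, 3500.0, noise_sd_pa=3.0,
                          seed=SEED)
    write_signal_csv(OUT / "compound_psc.csv", cp.times_ms, cp.values,
                     meta | {"units": "pA", "holding_mv": -40.0})

    family = gen_fepsp_family([20, 40, 60, 80, 100], 1.0, 60.0,
                              noise_sd_mv=0.005, seed=SEED)
    for inten, sw in family:
        write_signal_csv(OUT / f"fepsp_{int(inten):03d}uA.csv",
                         sw.times_ms, sw.values, meta | {"units": "mV"})
    print(f"fEPSP family: {len(family)} intensities")

    lfp_cfg = LfpSimConfig(duration_s=120.0, injection_time_s=60.0,
                           ad_schedule=[(65.0, 10.0, 2.0, 0.5)],
                           spike_schedule=[(20.0, 40.0, 0.5)], seed=SEED)
    rec, lfp_truth = gen_lfp(lfp_cfg)
    write_signal_csv(OUT / "lfp.csv", rec.times_s, rec.values,
                     meta | {"units": "mV", "injection_time_s": 60.0})
    lfp_truth.events.to_json(OUT / "lfp_truth.json", orient="records")
    print(f"LFP: {rec.duration_s:.0f} s with "
          f"{lfp_truth.n_events} scheduled events -> {OUT}/")


if __name__ == "__main__":
    main()
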