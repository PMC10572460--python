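"""LFP: multitaper spectra, after-discharges and interictal spikes.

Compares an early-kindling-style recording (one short after-discharge)
with a late-stage one (several longer ADs): incidence per minute, latency
from injection, durations, 1-3 Hz band power, and spike counts.
"""

from epiphys.io import RunConfig, config_hash, write_table
from epiphys.pipeline import stage_lfp


def main() -> None:
    cfg = RunConfig(seed=1)
    out = stage_lfp(cfg)
    meta = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    write_table("results/lfp_summary.csv", out["lfp_table"], meta)

    print(out["lfp_table"].to_string(index=False))
    print(f"1-3 Hz band-power fold (late/early): "
          f"{out['band_power_fold']:.1f}")


if __name__ == "__main__":
    main()
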