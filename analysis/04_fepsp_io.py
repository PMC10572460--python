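"""Field potentials: input-output curves and population-spike threshold.

Measures fiber volley, fEPSP amplitude and slope across stimulus
intensities for both conditions, compares the curves per intensity, and
locates the population-spike threshold (postsynaptic excitability).
"""

from epiphys.io import RunConfig, config_hash, write_table
from epiphys.pipeline import stage_fepsp


def main() -> None:
    cfg = RunConfig(seed=1)
    out = stage_fepsp(cfg)
    meta = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    write_table("results/fepsp_io.csv", out["io_table"], meta)
    write_table("results/fepsp_ratios.csv", out["ratio_table"], meta)

    print("per-intensity amplitude ratio (kindled/control):")
    for _, row in out["ratio_table"].iterrows():
        print(f"  {row.intensity_ua:5.0f} uA  ratio {row.ratio:.2f}")
    print(f"mean fold change: {out['fepsp_fold_recovered']:.2f}")
    print(f"Ps threshold  control {out['ps_threshold_control']:.0f} uA  "
          f"kindled {out['ps_threshold_kindled']:.0f} uA")


if __name__ == "__main__":
    main()
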