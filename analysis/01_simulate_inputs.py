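#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Emits, under results/simulated/: per-specimen composition tables, a
chromatogram-derived peak table, a Langmuir 3GA dose series with its
proteome shares, quantal lethality and hemorrhage tables, and truth.json
with the generating parameters.
"""

import json
from pathlib import Path

from venomics import GeneratorConfig, integrate_peaks
from venomics import io as vio
from venomics.chains import composition_table
from venomics.synthetic import (
    gen_binding_series,
    gen_chromatogram,
    gen_compositions,
    gen_hemorrhage,
    gen_lethality,
)

SEED = 20260924
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)

    obs, comps = gen_compositions(cfg, n_per_species=5)
    obs.to_csv(OUT / "observations.csv", index=False)
    vio.write_composition(composition_table(comps), OUT / "compositions.csv")

    trace, bounds, fams, truth = gen_chromatogram(comps[0])
    peaks = integrate_peaks(trace, bounds, fams)
    vio.write_peak_table(peaks, OUT / "peaks.csv")
    vio.write_peak_table(truth, OUT / "peaks_truth.csv")

    series, bmax_truth = gen_binding_series(cfg)
    vio.write_antivenomics(series.observations, OUT / "antivenomics.csv")
    (OUT / "proteome_shares.json").write_text(
        json.dumps(series.proteome_shares, indent=2)
    )

    vio.write_dose_table(gen_lethality(cfg), OUT / "lethality.csv")
    gen_hemorrhage(cfg).to_csv(OUT / "hemorrhage.csv", index=False)

    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "lethality": {
                    "median_ug": cfg.lethality_median,
                    "slope": cfg.lethality_slope,
                },
                "langmuir_bmax_ug": bmax_truth,
                "hemorrhage_mhd_ug": cfg.hemorrhage_mhd,
            },
            indent=2,
        )
    )
    print(f"wrote {len(list(OUT.iterdir()))} synthetic input files to {OUT}")
    print(f"  specimens: {len(obs)}; 3GA toxins: {len(bmax_truth)}")


if __name__ == "__main__":
    main()
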