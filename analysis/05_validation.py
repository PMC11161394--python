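#!/usr/bin/env python
"""Seeded validation experiments for the whole pipeline.

Re-runs the package's benchmark suite (leave-one-out exactness, null
calibration, patch recovery, threshold monotonicity, permutation-GLM type-I
error, effect-size recovery, end-to-end phenotype detection) and writes the
summary numbers to results/validation.json.  This is the same machinery the
acceptance harness uses; see scripts/acceptance.py for the canonical entry
point with a configurable seed.
"""

import json
from pathlib import Path

from surfload import benchmarks

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    out = {}
    out["loo_zmap_max_abs_deviation"] = benchmarks.loo_zmap_deviation(SEED)
    out["null_calibration"] = benchmarks.null_calibration(SEED, min_area=100.0)
    out["patch_recovery"] = benchmarks.patch_recovery(SEED)
    out["monotonicity"] = benchmarks.load_monotonicity(SEED)
    out["glm_type1"] = benchmarks.glm_type1_error(SEED, n_replicates=100,
                                                  n_perm=500)
    out["effect_size_recovery"] = benchmarks.effect_size_recovery(
        SEED, n_replicates=100)
    out["phenotype_detection"] = benchmarks.phenotype_detection(
        SEED, n_replicates=50)
    out["null_battery"] = benchmarks.null_battery_false_positives(
        SEED, n_replicates=20)

    ROOT.mkdir(parents=True, exist_ok=True)
    with open(ROOT / "validation.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for key, val in out.items():
        print(f"{key}: {val}")


if __name__ == "__main__":
    main()
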