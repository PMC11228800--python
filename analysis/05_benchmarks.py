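#!/usr/bin/env python
"""Run the full benchmark studies against planted ground truth.

Covers array fidelity, the exhaustive-null oracle check, hotspot-test
calibration and power, gradient recovery, and topic-model K selection.
Writes results/benchmarks.json. Same computations as
scripts/acceptance.py; this driver is the narrative entry point.
"""

import argparse
import json
from pathlib import Path

from stniche import studies


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = {}
    out["array"] = studies.array_fidelity()
    print("array:", out["array"])
    out["oracle_gap"] = studies.exhaustive_oracle_gap(seed=args.seed)
    print("exhaustive oracle gap:", out["oracle_gap"])
    out["calibration"] = studies.stenrich_calibration(args.seed)
    print("null calibration:", out["calibration"])
    out["power"] = studies.stenrich_power(args.seed)
    print("hotspot power:", out["power"])
    out["gradient_recovery"] = studies.gradient_recovery(args.seed)
    print("gradient recovery:", out["gradient_recovery"])
    out["noise_free_rho"] = studies.noise_free_gradient_rho()
    print("noise-free rho:", out["noise_free_rho"])
    ks = studies.k_selection_study(args.seed)
    out["k_selection"] = {
        "k3_selection_rate": ks.k3_selection_rate,
        "pure_spot_niche_accuracy": ks.pure_spot_niche_accuracy,
        "n_seeds": ks.n_seeds,
    }
    print("k selection:", out["k_selection"])

    with open(args.out / "benchmarks.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"\nwrote {args.out / 'benchmarks.json'}")


if __name__ == "__main__":
    main()
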