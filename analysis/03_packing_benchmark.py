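"""Benchmark observed transition densities against molecular packing.

Computes the single-molecule mass loadings of a 150 kDa IgG in flat-on
(125 nm²) and side-on (72 nm²) orientation, the critical surface
densities Γ_ind·Φ∞ under random (Φ∞ = 0.55) and hexagonal close
(Φ∞ ≈ 0.91) packing, estimates the random-sequential-adsorption disk
jamming fraction by Monte Carlo, and tabulates which packing scenario is
compatible with the transition densities recovered from the APTES
analysis.  Writes results/packing/packing_comparison.csv and rsa.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from igg_orient.packing import (
    PackingParams,
    hex_close_packing_fraction,
    rsa_disk_jamming,
)
from igg_orient.pipeline import compare_packing

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    out = ROOT / "packing"
    out.mkdir(parents=True, exist_ok=True)
    params = PackingParams()
    for orientation in ("flat_on", "side_on"):
        print(
            f"{orientation}: Gamma_ind = {params.gamma_ind(orientation):.2f} mg/m^2, "
            f"critical (phi=0.55) = {params.gamma_critical(orientation):.2f} mg/m^2"
        )
    print(f"hexagonal close packing: {hex_close_packing_fraction():.4f}")

    covs = []
    for s in range(seed, seed + 5):
        cov, n = rsa_disk_jamming(box_side=30.0, max_failures=500_000, seed=s)
        covs.append(cov)
        print(f"RSA seed {s}: coverage {cov:.4f} ({n} disks)")
    print(f"RSA mean coverage over 5 seeds: {np.mean(covs):.4f}")
    (out / "rsa.json").write_text(
        json.dumps(
            {"coverages": covs, "mean": float(np.mean(covs)), "seed0": seed},
            indent=2,
        )
    )

    summary_path = ROOT / "analysis" / "APTES" / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        bounds = summary["segmentation"]["boundaries"]
        rows = compare_packing(tuple(bounds), params)
        df = pd.DataFrame(rows)
        df.to_csv(out / "packing_comparison.csv", index=False)
        print(df.to_string(index=False))
    else:
        print("run 02_orientation_analysis.py first for the comparison table")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
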