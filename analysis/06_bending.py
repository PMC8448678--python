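"""Protofilament bending-angle recovery.

Imposes known inter-dimer bends on the sheet lattice -- an 11-degree tilt of
the plus-end heterodimers and a 4-degree body-wide curl, the two regimes the
bending statistics are meant to resolve -- and recovers them as class means
of the monomer-COM bending angle, noise-free and under isotropic noise.
Writes per-class summaries and 1-degree histograms.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from assembly_ed.experiments import bending_recovery

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    clean = bending_recovery(seed=seed, n_frames=100)
    noisy = bending_recovery(seed=seed, n_frames=300, noise_variance=4e-4)

    print("imposed-bend recovery (inter-dimer angle, class means):")
    print(f"  straight lattice: max |angle| = {clean['straight_max_deg']:.2e} deg")
    print(f"  plus-end 11 deg : {clean['plus_mean_deg']:.3f} deg noise-free, "
          f"{noisy['plus_mean_deg']:.3f} deg with noise")
    print(f"  body-wide 4 deg : {clean['body_mean_deg']:.3f} deg noise-free, "
          f"{noisy['body_mean_deg']:.3f} deg with noise")

    noisy["plus_summary"].stats.to_csv(RESULTS / "bending_plus_end_summary.csv", index=False)
    noisy["body_summary"].stats.to_csv(RESULTS / "bending_body_summary.csv", index=False)
    hist_rows = []
    for name, summary in (("plus_end_run", noisy["plus_summary"]), ("body_run", noisy["body_summary"])):
        for cls, counts in summary.histograms.items():
            occupied = np.nonzero(counts)[0]
            for b in occupied:
                hist_rows.append({"run": name, "pair_class": cls,
                                  "angle_bin_deg": float(summary.bin_edges[b]), "count": int(counts[b])})
    pd.DataFrame(hist_rows).to_csv(RESULTS / "bending_histograms.csv", index=False)
    print(f"wrote bending summaries + histograms under {RESULTS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
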