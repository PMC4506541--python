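#!/usr/bin/env python
"""Active-site ligand-density scoring and the occupancy-ladder experiment.

Scores the three designated sites per phantom half on maps simulated at
occupancies 1.0/0.6/0.3, repeats the ranking over 20 noise realizations,
and runs the occupancy-0 null — the quantitative analogue of judging
inhibitor-density visibility across the three proteolytic sites.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from picoem.core import VolumeMap
from picoem.ligand_density import (
    DEFAULT_MASK_RADIUS_A,
    DEFAULT_SHELL_RADII_A,
    rank_sites,
    scores_to_frame,
    site_density_score,
)
from picoem.simulator import PhantomSpec, build_phantom, gaussian_peak

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    phantom, vol = build_phantom(PhantomSpec(ligand_occupancies=(1.0, 0.6, 0.3)))
    sd = 0.1 * gaussian_peak(phantom.ligand_weight, phantom.ligand_sigma, vol.voxel_size)
    sites = [
        {"site_id": s.site_id, "centre": s.centre,
         "mask_radius": DEFAULT_MASK_RADIUS_A, "shell_radii": DEFAULT_SHELL_RADII_A}
        for s in phantom.ligand_sites if s.site_id.endswith("a")
    ]

    rows, wins = [], 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        noisy = VolumeMap(vol.data + rng.normal(0, sd, vol.shape), vol.voxel_size)
        scores = rank_sites(noisy, sites)
        wins += [s.site_id for s in scores] == ["beta1_a", "beta2_a", "beta5_a"]
        df = scores_to_frame(scores)
        df["replicate"] = seed
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(OUT / "ligand_site_scores.csv", index=False)

    ph0, vol0 = build_phantom(PhantomSpec(ligand_occupancies=(0.0, 0.0, 0.0)))
    null = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        noisy = VolumeMap(vol0.data + rng.normal(0, sd, vol0.shape), vol0.voxel_size)
        null.append(site_density_score(noisy, ph0.ligand_sites[0].centre,
                                       DEFAULT_MASK_RADIUS_A,
                                       DEFAULT_SHELL_RADII_A).z_score)

    means = table.groupby("site_id").z_score.mean().round(2).to_dict()
    summary = {
        "occupancies": {"beta1": 1.0, "beta2": 0.6, "beta5": 0.3},
        "mean_z_by_site": means,
        "correct_rankings_of_20": int(wins),
        "null_max_abs_z": float(np.max(np.abs(null))),
    }
    with open(OUT / "ligand_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
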