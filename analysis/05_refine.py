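#!/usr/bin/env python
"""Projection-matching refinement of a noisy synthetic particle stack.

Simulates 300 CTF-modulated, phase-flipped particles at SNR 0.1, refines
for three rounds (15/10/7.5 degree sampling, C2, amplitude-corrected
reconstruction) from the 20 A-filtered phantom, and reports the angular
recovery against ground truth plus the gain from amplitude correction.
"""

import json
import time
from pathlib import Path

import numpy as np

from picoem.core import AcquisitionParams
from picoem.geometry import angular_distance_deg
from picoem.io import write_mrc, write_table
from picoem.refine3d import reconstruct, refine
from picoem.simulator import PhantomSpec, build_phantom, simulate_particle_stack

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    _, volume = build_phantom(PhantomSpec())
    acq = AcquisitionParams(pixel_size=volume.voxel_size)
    particles, truth = simulate_particle_stack(
        volume, 300, acq, defocus_range_um=(1.7, 3.0), snr=0.1,
        apply_ctf=True, do_phase_flip=True, shift_max_px=3, seed=13,
    )
    t0 = time.time()
    final, log = refine(
        particles, volume, rounds=3, grid_schedule=(15.0, 10.0, 7.5),
        symmetry="C2", ctf_mode="amplitude", acquisition=acq,
        max_shift_px=8, start_lowpass_A=20.0,
    )
    runtime = time.time() - t0
    write_mrc(SCRATCH / "refined_map.mrc", final.data, final.voxel_size)
    write_table(log, OUT / "refinement_orientations.csv")

    errs = np.array([
        angular_distance_deg(
            tuple(truth.particles.loc[i, ["rot", "tilt", "psi"]]),
            tuple(particles.metadata.loc[i, ["rot", "tilt", "psi"]]), "C2")
        for i in range(len(particles))
    ])
    uncorrected = reconstruct(particles, acq, symmetry="C2", ctf_correction="none")

    def phantom_corr(m):
        a, b = m.data - m.data.mean(), volume.data - volume.data.mean()
        return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

    summary = {
        "n_particles": len(particles),
        "rounds": 3,
        "median_angular_error_deg": float(np.median(errs)),
        "fraction_within_final_step": float((errs <= 7.5).mean()),
        "median_shift_error_px": float(np.median(np.hypot(
            particles.metadata.shift_x - truth.particles.shift_x,
            particles.metadata.shift_y - truth.particles.shift_y))),
        "phantom_corr_amplitude_corrected": phantom_corr(final),
        "phantom_corr_uncorrected": phantom_corr(uncorrected),
        "runtime_s": runtime,
    }
    with open(OUT / "refinement_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
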