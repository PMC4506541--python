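#!/usr/bin/env python
"""Build the barrel phantom and a small dose-fractionated dataset.

Writes the phantom map and pseudo-atom model, a 17-frame movie of a field
of particles with early-frame drift, and the ground-truth tables that the
later stages are checked against.
"""

from pathlib import Path

import numpy as np

from picoem.core import AcquisitionParams, CTFParams
from picoem.io import atoms_to_pdb, write_mrc, write_table
from picoem.simulator import PhantomSpec, build_phantom, simulate_movie

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    spec = PhantomSpec(ligand_occupancies=(1.0, 0.6, 0.3))
    phantom, volume = build_phantom(spec)
    write_mrc(SCRATCH / "phantom.mrc", volume.data, volume.voxel_size)
    atoms_to_pdb(phantom.all_atoms(), SCRATCH / "phantom.pdb")
    print(f"phantom: {len(phantom.atoms)} subunit blobs, "
          f"{len(phantom.ligand_sites)} ligand sites, "
          f"box {volume.shape[0]} @ {volume.voxel_size} A/voxel")

    acq = AcquisitionParams(pixel_size=volume.voxel_size)
    ctf = CTFParams(2.2, 2.0, 30.0)
    movie, truth = simulate_movie(
        volume, 12, acq, ctf=ctf, noise_level=0.02,
        drift={"early_px": 2.0, "late_px": 0.1}, seed=1, shape=(512, 512),
    )
    write_mrc(SCRATCH / "movie.mrcs", movie.frames, acq.pixel_size)
    write_table(truth.particles, OUT / "movie_truth_particles.csv")
    np.savetxt(OUT / "movie_truth_drift.csv", truth.drift, delimiter=",",
               header="cum_x_px,cum_y_px", comments="")
    print(f"movie: {movie.n_frames} frames of {movie.frames.shape[1:]},"
          f" {len(truth.particles)} particles, defocus {ctf.defocus_u_um}/"
          f"{ctf.defocus_v_um} um")


if __name__ == "__main__":
    main()
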