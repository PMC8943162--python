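#!/usr/bin/env python
"""Generate the synthetic study systems used by the downstream analyses.

Writes, under results/fixtures/:

* ``channel/``  — a 4-pseudo-monomer channel-like trajectory (the four
  analysed segments per chain, 5 heavy atoms per residue) with one planted
  lid-to-loop coupling of known mutual information;
* ``pocket/``   — twelve replicate two-state Markov pocket-width units with
  stationary closed fraction 0.25 (the Table-2-style occupancy truth);
* ``pore/``     — an hourglass toy pore whose probe-radius profile is exact
  ring geometry.

Each directory carries a ``truth.json`` sidecar with the analytic answers.
"""

import argparse
import json
from pathlib import Path

from mdcoupling.synthetic import (
    MarkovPocketSpec,
    gen_markov_pocket,
    gen_toy_pore,
    pocket_frameset_from_widths,
    trpa1_like_fixture,
)
from mdcoupling.trajectory import FrameSet, write_frames_binary, write_frames_pdb

HOURGLASS_RINGS = [(-8.0, 5.0), (-4.0, 4.2), (0.0, 3.0), (4.0, 4.2),
                   (8.0, 5.0)]
MARKOV_RATES = dict(rate_open_to_closed=0.04, rate_closed_to_open=0.12)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--frames", type=int, default=300)
    parser.add_argument("--out", type=Path,
                        default=Path("results/fixtures"))
    args = parser.parse_args()

    channel_dir = args.out / "channel"
    channel_dir.mkdir(parents=True, exist_ok=True)
    frames, analytic_mi = trpa1_like_fixture(n_frames=args.frames,
                                             seed=args.seed, n_monomers=4)
    write_frames_binary(frames, channel_dir / "frames.mdcoord")
    write_frames_pdb(FrameSet(frames.coordinates[:1], frames.times[:1],
                              frames.topology),
                     channel_dir / "topology.pdb")
    (channel_dir / "truth.json").write_text(json.dumps({
        "planted_pair": [671, 988],
        "planted_pair_analytic_mi_nats": analytic_mi,
    }, indent=2))
    print(f"channel fixture: {frames.n_frames} frames × "
          f"{frames.n_atoms} atoms, planted MI {analytic_mi:.3f} nats "
          f"between residues 671 and 988")

    pocket_dir = args.out / "pocket"
    pocket_dir.mkdir(parents=True, exist_ok=True)
    truth = None
    for unit in range(12):
        result = gen_markov_pocket(
            MarkovPocketSpec(duration_ns=1000.0, dt_ns=0.1,
                             seed=args.seed * 100 + unit, **MARKOV_RATES))
        truth = result.true_closed_fraction
        unit_frames = pocket_frameset_from_widths(result.series)
        write_frames_binary(unit_frames,
                            pocket_dir / f"unit_{unit:02d}.mdcoord")
        if unit == 0:
            write_frames_pdb(
                FrameSet(unit_frames.coordinates[:1], unit_frames.times[:1],
                         unit_frames.topology),
                pocket_dir / "topology.pdb")
    (pocket_dir / "truth.json").write_text(json.dumps({
        "stationary_closed_fraction": truth}, indent=2))
    print(f"pocket fixtures: 12 × 1 µs-equivalent units, "
          f"stationary closed fraction {truth:.2f}")

    pore_dir = args.out / "pore"
    pore_dir.mkdir(parents=True, exist_ok=True)
    _, pore_frames, profile = gen_toy_pore(HOURGLASS_RINGS,
                                           atoms_per_ring=16)
    write_frames_pdb(pore_frames, pore_dir / "frames.pdb")
    (pore_dir / "truth.json").write_text(json.dumps(
        {f"z_{z:+.1f}": r for z, r in profile.items()}, indent=2))
    print(f"pore fixture: hourglass of {len(HOURGLASS_RINGS)} rings, "
          f"true minimum radius {min(profile.values()):.2f} Å at z = 0")


if __name__ == "__main__":
    main()
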