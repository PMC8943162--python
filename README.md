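# mdcoupling

Trajectory-analysis toolkit for studying how motion in one part of an ion
channel informs another — built around the allosteric coupling between the
cytosolic electrophile-binding pocket and the transmembrane pore of TRPA1,
but applicable to any per-monomer segment analysis of a channel MD
trajectory.

Three analyses are provided, each as library functions, a CLI subcommand,
and a numbered driver under `analysis/`:

1. **Gaussian mutual-information pathways.** For a coordinate set **X**
   (all heavy atoms of a residue, superposed frames), the quasi-harmonic
   configurational entropy is

   *H*(**X**) = ½ ln |2π*e* C(**X**)|  (nats),

   where C(**X**) is the trajectory covariance, entries
   ⟨X<sub>ij</sub>X<sub>kl</sub>⟩ − ⟨X<sub>ij</sub>⟩⟨X<sub>kl</sub>⟩. The
   coupling of residues A and B is

   MI(A,B) = *H*(**X**<sub>A</sub>) + *H*(**X**<sub>B</sub>) −
   *H*(**X**<sub>A,B</sub>) = ½ ln(|C<sub>A</sub>||C<sub>B</sub>|/|C<sub>AB</sub>|) ≥ 0.

   Per-residue-pair values are computed per (run, monomer), max-aggregated
   across all units, summarised per segment pair as the mean of each
   residue's best-partner value, and ranked into a pathway edge list.

2. **Pocket open/closed occupancy.** Pocket width is the Cα–Cα distance
   between the lower-lid residue K610 and the upper-lid residue L667
   (15.5 Å in deposited pocket-open structures, 9.4 Å in pocket-closed);
   a frame is *closed* when the width is strictly below 11 Å. Occupancy
   pools the time-weighted closed fraction over all (run × monomer) units,
   with the standard deviation across units as dispersion, plus a
   2 ns moving average for plotting and an out-of-pocket ligand occupancy
   based on minimum heavy-atom contact distances.

3. **Pore-radius profiles.** A simplified probe-sphere profiler (the
   HOLE/CHAP family, reduced to a straight axis): at each slice along the
   channel axis the largest sphere clearing all vdW-inflated atoms is found
   by a seeded derivative-free search, giving radius-vs-axis profiles,
   per-frame minimum radii, and frame-averaged profiles with per-slice
   standard deviations.

Because MD studies rarely deposit trajectories, the `synthetic` module
generates every input with a known answer: Gaussian trajectories with
specified covariance (closed-form MI), two-state Markov pocket widths
(stationary closed fraction k<sub>oc</sub>/(k<sub>oc</sub>+k<sub>co</sub>)),
toy ring-stack pores (exact radii), and rigid-motion trajectories for
superposition tests. Every stage is validated against these oracles.

## Worked example

```
python analysis/01_simulate.py --seed 1
python analysis/02_mutual_information.py
python analysis/03_pocket_occupancy.py
python analysis/04_pore_profile.py
```

The first script writes a channel-like fixture — 4 pseudo-monomers carrying
the four analysed segments (pocket lid 663–676, S1 706–730, S4 842–865,
TRP-like/S6 961–1005; 5 heavy atoms per residue) with one planted coupling
between residues 671 and 988 — plus twelve Markov pocket units and an
hourglass toy pore. The MI driver then prints:

```
segment_a segment_b  mean_residue_pair_max_nats
      lid        S1                    1.015387
      lid        S4                    0.788090
      lid   TRPL_S6                    0.653953
       S1        S4                    0.755536
       S1   TRPL_S6                    0.561332
       S4   TRPL_S6                    0.545306

strongest pair: [671, 988] at 3.163 nats (planted [671, 988] at 3.492 nats analytic) — recovered
```

The planted lid-to-loop pair heads the edge list near its analytic value;
the segment-pair means quantify the finite-sample bias floor of every
uncoupled pair. The pocket driver reports

```
pooled closed population: 27.2% ± 4.5 over 12 units (12 µs total)
stationary truth 25%: within 3 standard errors (3.9 points)
```

and the pore driver recovers the hourglass constriction exactly
(`minimum radius 1.30 Å at z = +0.0 Å`, deviation ≤ 0.001 Å from the ring
geometry).

The same pipelines are available as CLI subcommands
(`mdcoupling simulate | align | mi | pocket | pore`), each writing TSV
outputs plus a manifest JSON and an echo of its configuration for
reproducibility.

## Layout

- `src/mdcoupling/` — library: `trajectory` (PDB + binary frame IO,
  selections), `superpose` (Kabsch), `mutualinfo`, `pocket`, `pore`,
  `synthetic`, `config`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
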