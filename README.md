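# omega-access

Geometric accessibility analysis of cytochrome P450 hydroxylation sites
from MD trajectories.

## The problem

CYP4-family P450s hydroxylate long aliphatic chains at the terminal (ω)
carbon — the position whose C–H bonds are the *strongest* and therefore the
least reactive toward hydrogen-atom transfer (HAT) by the iron(IV)-oxo
species Compound I. Intrinsic reactivity alone predicts the wrong
regioselectivity: for vitamin K1 (phylloquinone), DFT barriers put the
secondary/tertiary ω-1…ω-3 hydrogens 6–25 kJ/mol below the ω hydrogens, yet
the enzyme produces the ω-alcohol. The selectivity has to come from the
active site holding the ω end next to the oxo.

`omega-access` quantifies that steric control. For every trajectory frame
it measures, for each candidate site hydrogen H:

* **d** — the H···O(oxo) distance (Å), and
* **θ** — the H–O–Fe angle at the oxo vertex (degrees),

and classifies the frame as a *near-attack* configuration for a site when

1. that site's hydrogen is the closest of all candidate hydrogens to the
   oxo atom,
2. d ≤ 2.8 Å, and
3. 125° ≤ θ ≤ 150°

(all bounds inclusive). The per-site frequencies among satisfying frames
form the **accessibility profile**; a distance-only variant attributes
every frame to the site of the globally closest hydrogen. A moving-block
bootstrap supplies confidence intervals, prochiral methylene hydrogens are
split into pro-R/pro-S by a signed-volume rule, frames are labelled by
terminal-chain conformer (anti vs gauche branch torsion), and the packaged
DFT activation-energy table lets you rank candidate sites of metabolism by
accessibility, by reactivity, or by the combined rule (accessibility first,
barriers as tie-break).

Because MD data behind published analyses of this kind are rarely
deposited, the package includes a first-class synthetic-trajectory
generator with known ground truth (per-site occupancies, window-pass
probability, conformer fractions) used for end-to-end parameter-recovery
testing.

## Worked example

Simulate 2,000 frames of the ω-dominant regime (true occupancies
ω 0.92 / ω-1 0.05 / ω-2R 0.02 / ω-2S 0.01, true pass probability 0.30),
analyze them, and rank the sites:

```bash
omega-access simulate --preset vk1-like --n 2000 --seed 7 \
    --out traj.pdb --truth truth.json
omega-access analyze --traj traj.pdb --boot 500 --block 50 --seed 7 --out-dir .
omega-access report traj.profile.json
```

`traj.profile.json` then contains (abridged):

```
satisfying_fraction: 0.2905            # truth: 0.30
site_frequencies:    omega 0.9088, omega-1 0.0568,
                     omega-2R 0.0207, omega-2S 0.0138
distance_only:       omega 0.9205, omega-1 0.0505, ...
ci (95%, block bootstrap): omega [0.8867, 0.9318],
                     satisfying_fraction [0.2702, 0.3095]
conformer census (all frames): 1: 0.852, 2: 0.148
```

About 29% of frames are near-attack configurations, ~91% of them at the ω
site, and the true generator parameters sit inside the bootstrap intervals.
The report command prints the ranking conflict at the heart of the problem:

```
combined order:   [omega, omega-1, omega-2R, omega-2S, omega-3R, omega-3S]
reactivity order: [omega-1, omega-3R, omega-2R, omega-2S, omega-3S, omega]
note on omega:    accessibility rank 1 vs reactivity rank 6
                  (freq 0.909, min barrier 51.78 kJ/mol)
```

ω ranks first on the combined basis despite carrying the highest intrinsic
barrier — accessibility, not reactivity, drives the predicted selectivity.

`omega-access reactivity` prints the packaged activation-energy table with
its arithmetic: the ω-family barriers span 51.78–59.44 kJ/mol and exceed
every internal-site barrier by 6.65–23.96 kJ/mol across both conformers.

## Layout

```
src/omega_access/
  structures_io.py   atoms/frames/trajectories, multi-model PDB, TSV, YAML sites
  geometry.py        d and theta kernels, closest-H reduction, prochirality
  accessibility.py   criteria engine, profiles, block bootstrap, run pooling
  conformers.py      dihedrals, conformer bins, circular-safe k-means
  reactivity.py      packaged activation energies, SOM ranking
  synthetic_data.py  ground-truth record- and coordinate-level generators
  cli.py             omega-access {simulate, analyze, report, reactivity}
docs/methods.md      model, conventions, parameter choices, limitations
```
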