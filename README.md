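# twistslide

A desk-scale model of active nucleosome repositioning by a chromatin
remodeler translocase, for structural and computational chromatin
biologists who want to explore the mechanics of ATP-driven DNA sliding
without running residue-level simulations.

The Snf2-family translocase binds nucleosomal DNA two helical turns from
the dyad (superhelical location 2) and slides it toward the dyad one base
pair per ATP cycle. `twistslide` reduces this machine to 16 coordinates —
the DNA displacement Δbp_i at the 14 strong histone–DNA contact points and
the two lobe registrations Δbp_L1, Δbp_L2 — evolving by overdamped Langevin
dynamics on a switching potential (apo → ATP → ADP). The ratchet works
through twist defects: closure of the two RecA-like lobes (lobe 1 stepping
toward lobe 2) stretches an electrostatic spring between the lobe-1 basic
patch and the distal DNA gyre; the spring recaptures the DNA by nucleating
a +1 bp / −1 bp defect pair at SHLs 1 and 2; the missing base pair escapes
through the entry/exit while hydrolysis opens the enzyme with a forward
lobe-2 step. A twist defect at SHL i is d_i = Δbp_{i+0.5} − Δbp_{i−0.5};
metastable states carry labels like `o0 → cA0 → cB0 → cC1 → cD1 → o1`.

The package also implements the full analysis pipeline: contact-index and
defect timelines, metastable-state labeling, free-energy landscapes by
Boltzmann inversion (F = −ln p̂), label-state Markov models (lag-time
transition matrices with detailed balance by count symmetrization, implied
timescales t_i = −τ/ln λ_i, mean first-passage times by the absorbing-chain
linear solve), minimum-energy pathways on 2-D landscapes, and the mapping
from DNA sequence (polyApG, poly(dA:dT) and TpA elements, a 601-like
positioning construct) to twist-defect energetics. Synthetic fixtures with
known statistical structure (scripted label paths, Markov chains with known
transition matrices, exact Boltzmann samplers) make every analysis stage
testable without simulation. The science and the numerical conventions are
documented in `docs/methods.md`.

## Worked example

```python
import numpy as np
from twistslide import cv
from twistslide.dynamics import IntegratorConfig, Schedule, run_ensemble
from twistslide.model import RemodelerParams
from twistslide.sequences import build_sequence, profile_from_sequence

profile = profile_from_sequence(build_sequence("polyApG"))
trajs, summary = run_ensemble(
    20, 1, Schedule.default(), RemodelerParams(), profile, IntegratorConfig()
)
print(cv.ensemble_probability(summary.lobe_step))
print(summary.label_path.iloc[0][:40], "...")
```

prints (the probability table and the start of one cycle's label path)

```
   outcome  count     p    ci_low   ci_high
0        0      1  0.05  0.008881  0.236131
1        1     19  0.95  0.763869  0.991119
o0->cB0->cC1->cD1->cC1->cD1->cC1->cD1 ...
```

Nineteen of twenty ATP cycles end with the translocase advanced one base
pair (outcome +1, with its Wilson 95% interval); the label path shows the
canonical route — closure (`cB0`), defect-pair creation at the binding
site (`cC1`), release of the missing base pair through the exit (`cD1`,
with thermal re-crossing of the last step before hydrolysis locks it in) —
and ends, after opening, in `o1`: the register advanced with the remaining
+1 bp defect parked near the dyad.

The same protocols are available from a shell:

```bash
twistslide simulate --n 100 --seed 1 --out runs/          # TSV trajectories
twistslide analyze  --traj-glob 'runs/traj_*.tsv' --out summary.tsv
twistslide landscape --coord shl2 --traj-glob 'runs/traj_*.tsv' --out fep.tsv
twistslide msm --traj-glob 'runs/traj_*.tsv' --lag 2.5 --targets cD1 --out msm/
twistslide sequence --kind polyApG --element TpA --shl 2 --out seq.fa
twistslide write-config --out config.toml                  # editable defaults
```

All model parameters live in a TOML config (`[remodeler]`, `[sequence]`,
`[dynamics]` sections) whose keys match the dataclass fields in
`twistslide.model.RemodelerParams`, `twistslide.sequences.MappingRules` and
`twistslide.dynamics.IntegratorConfig`; `twistslide simulate --config`
accepts an edited copy.

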