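# mcfold

Multicanonical (flat-histogram) sampling on toy energy landscapes, and
ensemble analysis of coupled folding and binding — the situation in
which an intrinsically disordered peptide such as the phosphorylated
kinase-inducible domain (pKID) acquires its helix-loop-helix structure
only upon binding its partner domain (KIX).

The package is for computational biophysicists who want the machinery
of a multicanonical study — iterative weight estimation, merged
independent trajectories, canonical reweighting, and the structural
observables used to interrogate the resulting ensembles — in a form
that can be verified end to end against exact oracles and planted
ground truth, without atomistic simulation.

## What it computes

**Sampling.**  A multicanonical run is constant-temperature Langevin
dynamics on the modified energy

    E_mc = E + R T ln P_c(E, T),

where `P_c(E, T)` is the canonical energy distribution; because
`P_c = n(E) exp(-E/RT)/Z`, this makes the sampled energy histogram flat
and lets trajectories cross barriers.  `P_c` is unknown a priori and is
built iteratively: a hot canonical seed run (700 K), polynomial fits of
`ln P_c` on a growing energy range bounded by soft energy walls, one
re-expression of the weight at 200 K (where the polynomial represents
`ln P_c` best), and merged independent trajectories at every stage.
The canonical ensemble at any target temperature `T_tag` is then pure
post-processing: each sample gets the log-weight
`E_mc(E_i)/(R T_sim) - E_i/(R T_tag)`.  Exact canonical oracles
(closed-form, quadrature, transfer-matrix) for the built-in landscapes
make every step checkable.

**Analysis.**  For conformational ensembles of a flexible ligand on a
rigid receptor frame: region RMSD against a multi-model reference
(minimum over models), centroid-displacement reaction coordinates
R_aA/R_aB and the potential of mean force `-RT ln P` over them,
helix-axis orientation inner products, side-chain-centre contacts with
the >= 8-of-17-models native-contact rule and N_nc/N_nnc counts,
hydrogen-bond (Kabsch-Sander) helix assignment and per-residue helix
content, Shrake-Rupley accessible surface area per region, and radial /
voxel densities of a marker atom (the phosphoserine anchor).  A
synthetic-data generator plants known helicities, binding-pose mixtures
and contact lists so each observable can be tested against exact truth.

## Worked example

```python
import numpy as np
from mcfold import (SamplerParams, ProtocolSchedule, iterate_weights,
                    make_double_well, reweight, expectation)

dw = make_double_well(1.0, 0.2)          # barrier 1 kcal/mol, tilted
params = SamplerParams(dt=0.01, n_steps=100_000, sample_every=10,
                       seed=1, wall_stiffness=0.25)
schedule = ProtocolSchedule(max_iterations=12, n_traj=8)

weight, report, run = iterate_weights(dw, schedule, params)
print(report[["iteration", "T_sim", "E_lo", "E_hi", "flatness"]].to_string(index=False))

ens = reweight(run, weight, 315.0)
p, se = expectation(ens, lambda x: float(x[0] < 0))
window = (weight.E_lo, weight.E_hi)
print(f"P(x<0) at 315 K: {p:.3f} +/- {se:.3f}  "
      f"(oracle {dw.oracle.prob(315.0, lambda x: x[0] < 0, window=window):.3f})")
```

prints

```
 iteration  T_sim      E_lo    E_hi   flatness
         1  700.0 -0.152034 2.16668  72.526786
         2  200.0 -0.210001 2.16668  45.214286
         3  200.0 -0.210001 2.16668  35.046154
         4  200.0 -0.210001 2.16668  30.230769
P(x<0) at 315 K: 0.640 +/- 0.019  (oracle 0.632)
```

Reading this: the seed at 700 K trusted energies down to -0.15; the
first update extended the range to the landscape's minimum and the
weight was re-expressed at 200 K; the flatness ratio then settles at the
representational floor of a polynomial weight on a one-dimensional
landscape (see `docs/methods.md`) and the iteration stops.  The
reweighted left-well population at 315 K agrees with the exact
quadrature oracle within one standard error — reweighting is exact
whatever the realised histogram looks like, because it corrects through
the same `E_mc` that biased the run.

A pipeline-style interface with TOML configs is also available:
`mcfold synth|simulate|weights|reweight|analyze|report --config run.toml`.

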