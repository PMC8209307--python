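# dendrodiam

Predict dendritic diameters from neuronal morphology, and check the
predictions with passive cable simulation.

Many reconstructions in public archives (e.g. NeuroMorpho.org) carry
accurate 3-D skeletons but unreliable or constant dendritic diameters, which
makes them unusable for compartmental simulation of electrical activity:
diameter sets both the membrane area and the axial current flow of every
compartment. `dendrodiam` addresses this for computational neuroscientists
who want to reuse such morphologies: it estimates each node's diameter from
diameter-independent features of the reconstruction itself, then rewrites
the SWC file with the predicted diameters.

## The model

Each dendritic node of an SWC reconstruction is described by seven
morphometric features:

| Feature | Meaning |
|---|---|
| D  | node diameter (2 × SWC radius), μm |
| PD | parent diameter; the soma diameter for initial nodes, μm |
| IB | initial branch order: 1 at initial nodes, +1 after each branch point |
| TD | terminal degree: number of terminal tips in the node's subtree |
| PS | path distance from the soma, μm |
| LP | longest downstream path to a terminal end, μm |
| TL | total dendritic length rooted at the node, μm |

and classified as **initial** (parent is a soma node), **branching child**
(parent is a branch point) or **continuing** (everything else). Per class
and dendrite type, diameter is modelled as a linear equation through the
origin,

    D̂ = β₁·f₁ (+ β₂·f₂),

with at most two features chosen by stepwise selection on the uncentered
adjusted R² (a pair replaces a single only if it beats both of its singles
by an improvement constant, default 0.001). Prediction runs soma-outward:
initial nodes use the soma diameter as PD, and every node further out uses
the *predicted* parent diameter, so a whole morphology needs only the soma
diameter and geometry. Published equation sets for hippocampal pyramidal,
cerebellar Purkinje and striatal spiny projection neurons ship with the
package (`hippocampal`, `cerebellar`, `striatal`, `striatal-lai`,
`striatal-luebke`); for example the
hippocampal apical continuing-node equation is D̂ = 0.9968 × PD.

Prediction quality is assessed two ways: per-tree Pearson R² between
original and predicted diameters, and passive compartmental simulation
(backward-Euler cable solver; frustum surface areas, exact tapered axial
resistances) comparing time constants (τ₁, τ₂ from a double-exponential fit
to a brief 1 ms / 1.5 nA somatic pulse), steady-state deflection ΔV (800 ms
/ 30 pA step) and synaptic peaks (10 pS dual-exponential conductance) as
normalized differences |pred − orig| / |orig|. A synthetic-morphology
generator with ground-truth diameter rules makes the whole pipeline testable
without downloads.

## Worked example

Generate a synthetic striatal-like archive whose ground-truth diameters
follow the packaged pooled-striatal equations, refit equations from half of
it, and predict diameters for one cell:

```bash
dendrodiam synth --out archive/ --n 6 --seed 11 --models striatal
dendrodiam fit archive/ --out fitted.yaml --seed 1 --report report.json
dendrodiam predict --swc archive/synthetic_000.swc --models fitted.yaml --out predicted.swc
dendrodiam compare --original archive/synthetic_000.swc --predicted predicted.swc
```

The fit log reports `wrote model set with 3 models to fitted.yaml`; the
fitted file recovers the generator's equations from the noisy archive
(diameter noise σ = 0.05 μm) — continuing nodes fit `0.98341 × PD` against
the ground-truth `0.9834 × PD`, branch children `0.92106 × PD` against
`0.921 × PD`, and initial nodes recover the {LP, TL} pair
(`0.00712 × LP + 0.00114 × TL`). Prediction prints the mean absolute
diameter change (`mean |dD| = 0.1173 um` here), and `compare` reports the
per-tree correlation between original and predicted diameters:

```json
{
  "r2": {
    "basal": 0.9181692578477485,
    "all": 0.9181692578477485
  }
}
```

i.e. the soma-outward predictions explain ~92% of the diameter variance of
this cell. `dendrodiam simulate --swc predicted.swc --protocol brief --out
trace.tsv` writes the somatic voltage transient, and
`dendrodiam compare --original ... --predicted ... --simulate` adds the
τ/ΔV normalized differences to the report.

The same machinery is available as a library:

```python
import dendrodiam as dd

ms = dd.load_packaged_model_set("hippocampal")
model = ms.lookup("continuing", "apical")
model.evaluate({"PD": 1.0})   # -> 0.9968 (μm)
```

## Documentation

`docs/methods.md` describes the model, the solver, the synthetic-data
generator and the numerical choices in detail.
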