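# psdanet

Decoupling gene-specific transcriptional regulation from growth physiology
in protein time series, and reverse-engineering the Boolean regulatory
circuits behind dose-dependent cell-fate decisions.

## The problem

In the yeast mating response, pheromone dose decides cell fate: a high dose
arrests growth and triggers shmoo formation, an intermediate dose triggers
chemotropic elongated growth. Time-lapse fluorescence measurements of
GFP-tagged proteins confound two signals — the regulation of each gene and
the condition-wide change in growth (protein dilution) and synthesis
capacity. A protein can *rise* 1.5-fold while its synthesis is being
*repressed*, simply because dilution slowed more than synthesis did.

`psdanet` separates the two with a kinetic model of the protein life cycle,

    dP/dt = R(t) · S_g(t) − (d + γ(t)) · P(t)

where `γ(t)` is the dilution rate from cell-mass accumulation, `d` the
degradation rate from protein half-lives, `S_g(t)` a condition-wide
(physiology-only) synthesis rate rescaled per gene, and `R(t)` a
gene-specific pulse-like regulation multiplier (fold `F` over a window
`[t_on, t_off)`; `F > 1` activation, `F < 1` inhibition) fitted by budgeted
simulated annealing against the observed trajectory. Genes sharing a
temporal regulation pattern are clustered into meta-genes, thresholded into
a Boolean trajectory, and the ternary-signed networks (`a_ji ∈ {−1,0,+1}`,
synchronous threshold/hold update, always-ON input node) consistent with
that trajectory are counted exactly, reduced to minimal (no-redundant-edge)
circuits, and analysed as attractor landscapes over all 2^N states.

Intended users: systems biologists with per-gene abundance and growth-rate
time courses who want regulation events and circuit hypotheses rather than
raw fold changes.

## Worked example

Everything below is computed from a synthetic high-dose (shmoo) cohort with
known ground truth — 195 genes, 5-min sampling over 6 h, 5% multiplicative
noise — generated by the package itself:

```python
import psdanet as pn

ds = pn.generate(pn.GeneratorConfig(seed=42))          # 195-gene shmoo cohort
null = pn.GlobalNullModel(ds.expression, ds.growth, ds.degradation,
                          mode="median").fit()
print(null.summary())
```

```
Global-null (physiology-only) model
===================================
genes paired:            195
global profile:          median of 195 genes
fold-change definition:  peak
Pearson r:               -0.0085
p-value:                 0.906
variance explained r^2:  0.0001
```

With ~70% of genes carrying regulation events, the physiology-only null
explains essentially none of the fold-change variance — the point of
decoupling. Fitting the pulse model per gene and clustering the detected
events into six meta-genes:

```python
res = pn.PsdaModel(ds.expression, ds.growth, ds.degradation,
                   null.global_profile).fit(seed=0)
print(res.summary().head(4).round(3)[["t_on", "t_off", "fold", "log2_fold", "class"]])
```

```
         t_on    t_off   fold  log2_fold      class
gene
G0000  28.818  153.058  0.411     -1.284  inhibited
G0001  -3.332  144.812  0.521     -0.940  inhibited
G0002  -0.257  142.175  0.472     -1.083  inhibited
G0003   6.454  132.658  0.283     -1.824  inhibited
```

```python
reg = res.regulation_matrix()
event = [g for g, f in res.fits.items() if f.classification != "none"]
traces = {g: reg.loc[g].to_numpy() for g in event}
asg = pn.kmeans_cluster(traces, ds.growth.grid, k=6, n_restarts=50, seed=0)
for a in pn.meta_gene_activity(asg, traces, ds.growth.grid):
    print(f"C{a.cluster}: {a.sign:10s} half-time {a.half_time:6.1f} min")
```

```
C1: inhibited  half-time    7.1 min
C2: activated  half-time   25.1 min
C3: activated  half-time   59.6 min
C4: activated  half-time  106.8 min
C5: inhibited  half-time  136.3 min
C6: activated  half-time  216.7 min
```

Two inhibitory and four activating meta-genes, ordered by their 50%
activation/inhibition times — matching the generator's template structure.
Discretizing at 50% of peak and enumerating consistent circuits:

```python
act = pn.meta_gene_activity(asg, traces, ds.growth.grid)
traj = pn.discretize(act, threshold=0.5)
print("consistent networks:", pn.count_consistent_networks(traj))
print("minimal networks:   ", pn.count_minimal_networks(traj))
ls = pn.attractor_landscape(pn.minimal_networks(traj)[0])
print("attractors:", len(ls.attractors), "| basin sizes:", ls.basin_sizes)
```

```
consistent networks: 9377280
minimal networks:    24
attractors: 1 | basin sizes: [64]
```

The 12-step Boolean trajectory admits ~9.4 million consistent signed
networks, of which 24 have no redundant edge; the first minimal circuit
funnels all 64 states into a single attractor — the terminal regulation
state of the shmoo response.

A `psdanet` console script exposes the stages (`synth`, `rates`,
`global-null`, `psda`, `infer`, `attractors`, `run-all`) with explicit
seeds and a reproducibility manifest; see `psdanet --help`.

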