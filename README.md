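# fermdf — thermodynamic diagnosis of stuck ethanol fermentations

High-titer batch fermentations often stop producing ethanol while substrate
is still available ("stuck" fermentation).  `fermdf` turns metabolite time
courses from such fermentations into a thermodynamic diagnosis: it computes,
at every sampled time point, the **max-min driving force (MDF)** of the
fermentation pathway, identifies the **bottleneck reactions** that pin it,
and quantifies how sensitive that diagnosis is to measurement error in each
metabolite.  It is aimed at metabolic engineers and systems biologists who
collect intracellular metabolomics during high-substrate fermentations of
organisms such as *Escherichia coli* (EMP glycolysis + Pdc/Adh),
*Thermoanaerobacterium saccharolyticum* (EMP + PFOR/ALDH/ADHP) and
*Zymomonas mobilis* (Entner–Doudoroff pathway).

## The model

For a pathway with stoichiometric matrix $S$ and standard transformed Gibbs
energies $\Delta_r G'^\circ_j$, the driving force of reaction $j$ at molar
metabolite concentrations $c$ is $-\Delta_r G'_j$ with

$$\Delta_r G'_j = \Delta_r G'^\circ_j + RT \sum_i S_{ij} \ln c_i .$$

The MDF is the optimum of the linear program

$$\max_{B,\,x}\ B \quad \text{s.t.} \quad \Delta_r G'^\circ_j + RT\,(S^\top x)_j \le -B
\;\;\forall j, \qquad \ln c_i^{\min} \le x_i \le \ln c_i^{\max},$$

where $x_i = \ln c_i$.  Metabolites quantified by LC-MS are fixed at their
measured concentrations ($c^{\min}=c^{\max}=c^{\text{measured}}$);
unquantified metabolites range over 1 µM – 100 mM; metabolites measured at
zero are pinned at the 1 µM floor.  A pathway is thermodynamically feasible
when $B > 0$; the bottleneck reactions are those whose driving force equals
$B$ at the optimum and cannot be moved off it.  Two error analyses probe the
diagnosis: a *global* relaxation replaces each measured bound $(c, c)$ by
$(c/f,\ c\,f)$ for factors $f \in \{1, 1.5, 2, 5, 100\}$, and a
*single-metabolite* relaxation frees one measured metabolite to the full
1 µM – 100 mM box.

The package also covers the surrounding workflow: LC-MS peak-area →
concentration conversion via external-standard calibration and the
intracellular volume (single-cell volume × OD₆₀₀ × cells/mL at OD₆₀₀ = 1 ×
volume filtered), fermentation phase segmentation (growth-coupled /
growth-uncoupled / no-production), diagnostic metabolite ratios and
adenylate energy charge, z-scored trajectory heatmaps with average-linkage
(UPGMA) correlation-distance clustering, and a synthetic fermentation
generator with ground truth for validating every stage.

## Worked example

```python
import fermdf as f

net = f.bundled_network("eco")          # EMP glycolysis + PDC/ADH
thermo = f.bundled_thermo_table("eco")  # ΔrG′° fixtures (kJ/mol)
ds, truth = f.generate(f.GeneratorConfig(seed=1))   # synthetic fermentation

seg = f.segment_phases(ds.time_h, ds.od, ds.extracellular["etoh"])
print(f"growth ends at {seg.t_growth_end:.1f} h, "
      f"production ends at {seg.t_production_end:.1f} h")

tc = f.mdf_timecourse(net, thermo, ds)
for t, res in zip(ds.time_h[::6], tc.results[::6]):
    print(f"t={t:5.1f} h  MDF={res.mdf:6.2f} kJ/mol  "
          f"bottleneck={','.join(sorted(res.bottlenecks))}")
```

prints

```
growth ends at 22.5 h, production ends at 45.0 h
t=  0.0 h  MDF=  5.93 kJ/mol  bottleneck=FBA,GAP
t= 15.0 h  MDF=  5.60 kJ/mol  bottleneck=TPI
t= 30.0 h  MDF=  5.23 kJ/mol  bottleneck=PYK
t= 45.0 h  MDF=  0.71 kJ/mol  bottleneck=PYK
t= 60.0 h  MDF= -0.03 kJ/mol  bottleneck=PYK
```

While the culture grows, the MDF is comfortably positive (≈5–6 kJ/mol) and
the bottleneck wanders among near-equilibrium glycolytic steps.  As ethanol
production ceases the MDF collapses to ≈0: pyruvate kinase (PYK) reaches
local thermodynamic equilibrium — this synthetic run injects exactly that
signature, and the pipeline recovers it.  The single-metabolite error
analysis confirms the diagnosis: only the PYK participants raise the MDF
when relaxed,

```python
mask = (seg.labels == "no_production").to_numpy()
reports = f.relaxation_scan(net, thermo, ds, "single",
                            baseline=tc, no_production_mask=mask)
print([(r.key, round(r.mean_delta(mask), 2)) for r in reports[:4]])
# [('pep', 5.48), ('pyr', 5.48), ('adp', 3.57), ('atp', 3.57)]
```

i.e. freeing pep, pyr, adp or atp recovers 3.6–5.5 kJ/mol of driving force
in the no-production phase, while all other metabolites change nothing.

The same analysis runs from the shell:

```sh
fermdf run-all --organism eco --seed 1 --outdir out/
```

writing the dataset, phase/ratio diagnostics, clustered heatmap, per-time
MDF and relaxation tables plus a `manifest.json` into `out/`.

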