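# wntredox

A stochastic reaction-network model of **redox-driven Wnt/β-catenin
signaling** in osteoblast-like (MG-63) cells on micro-structured titanium,
for systems biologists studying how surface topography perturbs intracellular
signaling. Sharp-edged micro-pillars impose oxidative stress; the package
asks, quantitatively, how a cell can accumulate β-catenin in the nucleus
without switching on Wnt target genes.

## The model in brief

The pathway is modeled as a continuous-time Markov chain over integer copy
numbers in two compartments (cytosol, nucleus), simulated exactly with
Gillespie's direct method (SSA) and, in the mean-field limit, as the ODE
system dx/dt = Sᵀ·v(x). There is no extracellular Wnt stimulus; β-catenin
(BC) is stabilized Wnt-independently through the redox arm:

```
ROS ⟶ NRX·DVL → DVL_free  (redox release)
      DVL_free ⇌ DVL_agg   (Hill switch: a = c·x·xⁿ/(Kⁿ+xⁿ))
      DVL_agg + AXIN ⇌ DVL·AXIN → DVL_agg   (high-affinity capture + turnover)
      AXIN ⇌ DC;  BC --DC--> ∅              (destruction complex starves)
```

AXIN is the low-copy, rate-limiting destruction-complex component, so its
sequestration by DVL aggregates lets β-catenin accumulate and enter the
nucleus, where BC + TCF ⇌ TCF/β-catenin (TCFBC) drives target-gene
expression at rate k_tx·TCFBC and feeds back on AXIN production (AXIN2).
Two inhibitors regulate the output: ICAT binds β-catenin reversibly in both
compartments (a nucleus→cytosol pump, no degradation), and nuclear SOX17
catalytically degrades the entire TCF/β-catenin complex, independent of the
destruction complex.

The P5 (micro-pillar) scenario applies the measured mRNA fold changes as
synthesis-rate multipliers — ICAT ×1.65, SOX17 ×1.58, TCF ×1.55 — plus a
calibrated ROS input; the Ref scenario is baseline. Protein folds are
emergent. A small `deg_filter` module implements the microarray filtering
arithmetic (|fold change| > 1.5, p < 0.05, signed convention), and
`synthetic_data` generates expression tables and noisy time courses so the
whole pipeline runs without downloads.

## Worked example

```python
from wntredox import build_network, make_scenario, run_virtual_experiment

net = build_network()                       # calibrated defaults
out = run_virtual_experiment(net, make_scenario("ref"), make_scenario("p5"),
                             engine="ode")
print(out.summary_frame().to_string(index=False))
```

```
 time_h  nuclear_bc_a  nuclear_bc_b  nuclear_bc_fold  cytosolic_bc_fold    tcfbc  target_rate_a  target_rate_b  target_expression_ratio  tcf_free
    1.0    260.854917    256.976927         0.985134           1.101034 1.142215       1.373657       1.142215                 0.831514 51.662619
   24.0    261.454172    355.394794         1.359301           1.585249 1.361169       1.375747       1.361169                 0.989404 60.656677
```

Reading the 24 h row: on micro-pillars nuclear β-catenin is **1.36-fold**
above the reference (and cytosolic β-catenin 1.59-fold) while the
target-gene expression rate is essentially **unchanged** (ratio 0.99) — the
coordinated upregulation of ICAT, SOX17 and TCF absorbs the redox-driven
accumulation. Re-running with a scenario that elevates only ROS (no
inhibitor multipliers) pushes the target ratio to ≈1.16, which is the point
of the regulatory arm.

The filtering stage reproduces the printed microarray arithmetic:

```python
from wntredox import WNT_PATHWAY_TABLE, filter_records
[r.symbol for r in filter_records(WNT_PATHWAY_TABLE, tag="Wnt")]
# ['WLS', 'SOST', 'CTNNBIP1', 'SOX17', 'TCF4', 'SFRP4']  (6 genes;
#  AXIN2 fails the p cutoff, DVL3 the fold cutoff)
```

A CLI mirrors the library (`wntredox simulate|experiment|scan|fit|degfilter|
synth`, plus `export-model` for the YAML network); run `wntredox --help`.

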