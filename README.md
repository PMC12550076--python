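# mtfounder

Founder analysis of mitochondrial haplotypes: a pipeline for dating
island colonizations (and other range expansions) from whole-mitogenome
variation, built around the ρ statistic, reduced-median haplotype
networks and a purifying-selection-corrected molecular clock. It is
aimed at phylogeographers working with rCRS-aligned mitogenomes — the
motivating application is the settlement of the Pacific, where the
near-fixed B4a1a1 lineage (the "Polynesian motif") lets genetic founder
ages be checked island-by-island against radiocarbon chronology.

## What it computes

**ρ and its error.** For a sample set against a clade root haplotype,

ρ = (1/n) Σᵢ d(root, tipᵢ),

the mean number of substitutions on the root-to-tip path, equivalently
Σₑ mₑ·nₑ/n over tree edges (mₑ mutations on edge *e*, nₑ samples below
it). Its standard error treats per-edge mutation counts as Poisson:
σ² = Σₑ mₑ·(nₑ/n)². Both formulations are computed and cross-checked.

**Networks.** Haplotypes are encoded as binary presence/absence
characters (one per derived allele per position, after masking
unstable positions such as the 303–315 poly-C stretch and 16519), with
nine hypervariable hotspot positions down-weighted from 10 to 7. A
reduced-median network is built by median closure, and reticulations
are resolved to a rooted tree by a minimum-weight Steiner search —
recurrent changes land on the cheap hotspot characters, near-ties keep
sample-rich clades intact. Small instances are solved exactly
(Dreyfus–Wagner); large datasets use a median-joining-style insertion
builder.

**Founder analysis.** Regions are ordered into nested west-to-east
areas; for each sink region the source is everything in earlier areas.
Each sink lineage's founder node is the most derived ancestor
attributable to the source, and only the mutations *private* to the
sink are counted: founder ρ = Σ private mutations / n sink samples,
pooled across founder clusters.

**Clock.** The default calibration is a time-dependent whole-mitogenome
clock: the expected substitutions per lineage after *t* years are

ρ(t) = t/B + A·(1 − e^(−t/τ)),  B = 3624 yr/substitution, A ≈ 4.27, τ ≈ 36.9 kyr,

i.e. a long-term neutral rate plus a transient excess of young, mildly
deleterious variants that purifying selection later removes. Ages are
the monotone inverse of this curve; 95% CIs transform ρ ± 1.96σ and are
truncated at 0 BP. A strictly linear clock (used to validate against
simulation truth) and table-based calibrations are pluggable.

**Surfaces and radiocarbon.** Per-island diversity and age values are
interpolated by ordinary kriging (linear variogram, exact at data
points), with heavy-drift outliers excludable; genetic founder ages are
classified against published 2σ radiocarbon settlement ranges by
closed-interval overlap and correlated west to east.

**Simulator.** A forward island-colonization simulator (founder
bottlenecks, Poisson substitution accumulation on a linear clock,
hotspot homoplasy, optional heavy-drift resampling) generates datasets
with fully recorded mutation histories, so every stage of the pipeline
can be scored against a known truth.

## Worked example

Simulate the packaged Pacific scenario (15 islands, sample sizes
mirroring the study regions, colonization truths at the radiocarbon
midpoints) and run the full pipeline with the matching linear clock:

```python
from mtfounder.pipeline import RunConfig, run_all
from mtfounder.simulate import pacific_scenario, simulate

dataset, truth = simulate(pacific_scenario(seed=1))
res = run_all(RunConfig(out_dir="demo-out", seed=1, clock="linear:3624"),
              dataset=dataset)
print(res["founder"][res["founder"].region.isin(["Vanuatu", "Tonga", "Cook Islands"])])
```

which prints (founder ages in years BP, CI bounds rounded to 10 y):

```
      region   n  founder_rho  founder_sigma  age_bp  ci_lo  ci_hi  n_clusters
     Vanuatu 103        0.786          0.087    2850   2230   3470           4
       Tonga  47        0.702          0.122    2540   1680   3410           2
Cook Islands  70        0.214          0.055     780    380   1170           5
```

The true (simulated) colonization times are 3230, 2838 and 938 BP —
each inside its 95% CI. `demo-out/` also receives the per-region
diversity table (n, π, ρ, σ), the resolved tree as newick, kriged
π/ρ/age surfaces (CSV + Surfer ASCII grid) and a comparison against
the packaged radiocarbon table.

The same stages are available from the shell:

```bash
mtfounder simulate --seed 1 --out sim
mtfounder founder sim/haplotypes.tsv sim/metadata.csv --clock linear:3624 --out founder.csv
mtfounder date 2.464            # -> age: 6450 BP [6450-6450] (selection-corrected)
mtfounder compare               # -> 5 non-overlapping regions: ...
```

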