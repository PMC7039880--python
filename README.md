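# micrm

A microbial consumer-resource model (MiCRM) with metabolic
cross-feeding, for asking which large-scale microbiome survey patterns
are reproduced by randomly sampled ecosystems assembled under resource
competition and stochastic colonization — and which require taxonomic
or metabolic structure.

The intended users are theoretical ecologists and microbiome
researchers who want a reproducible generator of synthetic community
data (an in-silico "survey") together with the standard pattern
analyses applied to real surveys.

## Model

Populations `N_i` and resources `R_α` in a well-mixed chemostat-like
habitat follow

```
dN_i/dt = g_i N_i [ Σ_α w_α (1−l_α) c_iα R_α − (m_i + m_env) ]
dR_α/dt = κ_α − R_α/τ_R − Σ_i c_iα N_i R_α + Σ_{i,β} D_αβ (w_β/w_α) l_β c_iβ N_i R_β
```

A fraction `l` of consumed energy leaks back as byproducts,
redistributed by the column-stochastic metabolic matrix `D`; `m_env`
is an environment-wide "harshness" offset to all maintenance costs.
Ecosystems are sampled randomly but with tunable structure: resources
fall into classes, species into specialist families that focus a
fraction `q` of their consumption on a preferred class, and byproducts
flow preferentially to a waste class (`f_w`) and the input's own class
(`f_s`) with sparsity `s`.  Communities are stochastically colonized
from a regional pool and integrated to an (approximately) uninvadable
steady state.

Implemented analyses: richness vs. harshness, NODF nestedness,
rarefaction + species-abundance distributions (Fisher log series
`s(n) = α xⁿ/n` and a truncated-Gaussian null), dissimilarity–overlap
curves (root-Jensen-Shannon on the shared pool), Jensen-Shannon PCoA,
mixture additivity, and reduction to an effective generalized
Lotka-Volterra model (carrying capacities `K_i`, interactions `α_ij`,
rates `r_i`) via implicit differentiation of the resource equilibrium.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from micrm import run_emp

# global-survey scenario: one pool of 180 species on 90 resources,
# 60 samples differing in environmental harshness m_env ~ U(-0.5, 9.5)
table = run_emp("simple", scale=1.0, n_samples=60, master_seed=7)
conv = table.converged()
rho = spearmanr(conv.sample_meta["m_env"], conv.sample_meta["richness"]).statistic
print(f"{conv.n_samples} converged samples")
print(f"Spearman rho(harshness, richness) = {rho:.3f}")
print(f"richness range: {conv.sample_meta['richness'].min()}"
      f"..{conv.sample_meta['richness'].max()}")
```

prints

```
60 converged samples
Spearman rho(harshness, richness) = -0.924
richness range: 5..26
```

i.e. communities in energetically harsher environments retain far
fewer species at steady state — harshness alone, with identical
species pools, generates the richness gradient seen across survey
samples.  The same table feeds the other analyses
(`micrm.patterns.presence_absence` + `nodf` for nestedness,
`doc_analysis` for dissimilarity–overlap, `js_distance_matrix` +
`pcoa` for ordination).

A command-line interface mirrors the library:

```
micrm run emp --kind simple --scale 0.25 --samples 50 --seed 7 -o out/
micrm analyze nestedness --table out/
micrm analyze doc --table out/ --pairs 1000 --seed 1 -o out/doc/
```

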