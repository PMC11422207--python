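# ecoassembly

Community-assembly inference for microbiome OTU tables.

Soil and host-associated microbiome studies routinely ask whether a
community was assembled by *deterministic* processes (environmental
selection) or *stochastic* ones (drift, dispersal). `ecoassembly`
implements the standard inference chain used in temporal soil-microbiome
work, end to end and fully testable on synthetic data:

* **Phylogenetic null model.** For every pair of samples, the
  abundance-weighted β-mean-nearest-taxon distance

  βMNTD(j,k) = ½ [ Σᵢ f_ij · min_{i′∈k} d(i,i′) + Σᵢ f_ik · min_{i′∈j} d(i,i′) ]

  is z-scored against 999 tip-label shuffles of the patristic distance
  matrix, giving βNTI = (βMNTD_obs − μ_null)/σ_null. |βNTI| > 2 indicates
  selection-driven turnover; |βNTI| < 2 a stochastic regime.
* **Taxonomic null model.** The Bray–Curtis Raup–Crick metric RC_bray
  locates the observed dissimilarity inside a null distribution of
  probabilistically reassembled communities (observed richness and read
  totals preserved; taxa drawn by occupancy, reads by metacommunity
  abundance), rescaled to [−1, 1]. Together (βNTI, RC_bray) assign each
  pair one of five processes: variable selection, homogeneous selection,
  dispersal limitation, homogenizing dispersal, undominated.
* **Sloan neutral community model.** A taxon's occurrence frequency is
  predicted from its mean relative abundance p as
  F(p) = 1 − I_{1/N}(Nmp, Nm(1−p)); the migration rate m is fitted by
  nonlinear least squares and taxa are partitioned against the 95% Wilson
  band.
* **Levins niche breadth.** B = 1/Σᵢ P²ᵢⱼ with Pianka overlap and
  generalist/specialist calls against a fixed-fixed permutation null that
  preserves all row and column totals.
* **Co-occurrence networks.** Spearman |r| > 0.9, p < 0.05 edges on the
  top-300 taxa per group; Gephi-equivalent topology metrics; Louvain
  modules; Zi–Pi node roles (thresholds 2.5 / 0.62) and keystone calls;
  AAT/CAT/ART/CRT/MT/CRAT abundance categories; core-taxa Venn regions.

A synthetic-data module generates neutral communities (Beta-marginal drift
with immigration, plus a slow forward Moran simulator as cross-check),
selection-structured communities on simulated phylogenies (Brownian traits
with Gaussian environmental filtering), and planted-module networks with
known hub/connector ground truth — so every stage is validated against
data whose generating process is known.

## Worked example

```python
import numpy as np
from ecoassembly.synthetic import NeutralScenario, simulate_neutral, simulate_tree
from ecoassembly.phylo import patristic_matrix
from ecoassembly.assembly import AssemblyModel
from ecoassembly.ncm import NeutralCommunityModel

scenario = NeutralScenario(n_taxa=200, n_samples=20, m_true=0.3,
                           reads=2000, seed=1)
table, meta = simulate_neutral(scenario)
tree = simulate_tree(200, seed=2)

res = AssemblyModel(table, patristic_matrix(tree, table.taxon_ids)).fit(
    reps=999, seed=3)
print(res.summary())

fit = NeutralCommunityModel(table).fit()
print(fit.summary())
```

prints

```
Community assembly (betaNTI / RC_bray null models)
  pairs: 190   randomizations: 999

group  n_pairs  variable_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
  all      190                0.53                   0.00                  0.00                    0.00        99.47

Sloan neutral community model
  samples: 20   taxa: 196
  m = 0.3959   Nm = 791.8   R^2 = 0.9155
  within 95% band: 72.45%   above: 26.02%   below: 1.53%
```

Read: on neutral-drift data nearly all pairs fall in the stochastic band
(|βNTI| < 2, here 99.5% undominated), and the neutral model fits the
occurrence–abundance relationship well (R² = 0.92) — the signature the
same pipeline looks for in real tables. The fitted m (0.40 for a true
0.3) carries a known upward bias, and at only 20 samples the 95% Wilson
band is tight enough that a quarter of taxa sit above it; both effects
are quantified in `docs/methods.md`.

There is also a CLI: `ecoassembly simulate | diversity | assembly | ncm |
niche | network | run` (see `ecoassembly --help`).

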