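# isoniche

Bayesian probabilistic isotopic-niche analysis for multispecies stable-isotope
data.

Ecologists compare how sympatric species share habitat and diet by comparing
their *isotopic niches*: the regions of multivariate isotope space (here
δ¹³C × δ¹⁵N × δ³⁴S, in ‰) occupied by each species. `isoniche` implements the
probabilistic niche framework for an arbitrary number of isotope dimensions:

- Each species' isotope values are modelled as multivariate normal with
  unknown mean μ and covariance Σ. Under a noninformative
  Normal-Inverse-Wishart prior the joint posterior is available in closed
  form, Σ | X ~ Inverse-Wishart(n − 1, S) and μ | Σ, X ~ N(x̄, Σ/n), and is
  sampled exactly (10,000 independent joint draws by default).
- The **niche region** at level α (default 0.95) is the ellipsoid
  {x : (x − μ)ᵀ Σ⁻¹ (x − μ) ≤ χ²_{d,α}} containing a fraction α of the
  species' distribution.
- The **niche size** is its hypervolume
  V = π^{d/2}/Γ(d/2 + 1) · (χ²_{d,α})^{d/2} · √det Σ (‰³ for three
  isotopes), reported as a posterior distribution with its mean and
  equal-tailed 95% credible interval, plus pairwise **exceedance
  probabilities** P(V_A > V_B) across paired posterior draws.
- The **directional overlap** of species A onto species B is the probability
  that a random individual of A falls inside B's niche region, estimated per
  posterior draw by Monte Carlo; it is asymmetric by construction.

A seeded synthetic-data generator reproduces the design of a three-species
marine-turtle foraging aggregation (loggerhead *Cc* n = 104, green *Cm*
n = 95, Kemp's ridley *Lk* n = 49) from its published per-species means and
SDs, so the whole pipeline runs and is tested without any data download.

## Worked example

```python
import numpy as np
from isoniche import NicheModel, generate_scenario, table1_defaults

datasets = generate_scenario(table1_defaults(seed=1))          # Cc/Cm/Lk
X = np.vstack([ds.values for ds in datasets.values()])
y = np.concatenate([np.full(ds.n, lab) for lab, ds in datasets.items()])

model = NicheModel(n_draws=10_000, alpha=0.95, m_points=1_000,
                   random_state=1).fit(X, y)
print(model.size_table().round(2).to_string(index=False))
print(model.overlap_matrix().round(2).to_string())
```

prints

```
species  size_mean  ci_low  ci_high
     Cc     795.63  624.80  1011.21
     Cm    1157.83  901.14  1477.69
     Lk     517.07  359.42   730.27

       Cc     Cm     Lk
Cc    NaN  76.48  70.08
Cm  68.51    NaN  61.11
Lk  89.29  89.87    NaN
```

`size_mean` is the posterior-mean 95%-probability niche hypervolume in ‰³
with its 95% credible interval: on this synthetic scenario the green turtle
(Cm) occupies the largest niche and Kemp's ridley (Lk) the smallest. The
overlap matrix reads across rows: an individual of the row species has the
stated percent probability of falling inside the column species' niche
region — e.g. a Kemp's ridley individual is found in the loggerhead (Cc)
niche 89.29% of the time, while the reverse direction is only 70.08%. Note
these synthetic values assume zero inter-isotope correlation (the generator's
default, configurable); niche volumes shrink as real correlations tighten
det Σ.

The same analysis is available from the shell:

```sh
isoniche simulate --seed 1 --out turtles.csv
isoniche run --csv turtles.csv --seed 1 --out report/ --plots
```

which writes summary, size, exceedance and overlap CSV tables, a JSON run
manifest recording every seed and parameter, and optional figures.
`isoniche run --csv your_data.csv ...` works on any CSV with `species`,
`d13C`, `d15N`, `d34S` columns (arbitrary names via a column map).

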