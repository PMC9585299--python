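# divgrad

Hill-number diversity profiles — taxonomic (TD), functional (FD) and
phylogenetic (PD) — for plot-based community data, plus the
negative-binomial GLM/GLMM inference layer used to relate those profiles
to environmental gradients. The package is aimed at community ecologists
analysing forest-inventory-style data: a plot × taxon abundance matrix, a
per-taxon trait table, a dated phylogeny covering the taxa, and a per-plot
environment table (latitude, temperature seasonality, annual
precipitation, soil pH, soil bulk density, region).

## The measures

All three attributes are expressed as **effective numbers of entities**
via Hill numbers of order *q*, which tunes sensitivity to rarity
(*q* = 0 richness, *q* = 1 Shannon-weighted, *q* = 2 dominance-weighted):

- **TD** — ordinary Hill numbers,
  `qD = (Σ_i p_i^q)^{1/(1−q)}`, with `exp(−Σ p_i ln p_i)` at *q* = 1.
- **PD** — branch segments are the entities. Each branch *i* of length
  `L_i` carries the summed relative abundance `a_i` of its descendant
  tips; with `T̄ = Σ L_i a_i`, the mean diversity is
  `qD̄ = [Σ_i (L_i/T̄) a_i^q]^{1/(1−q)}` and the reported quantity is the
  effective total branch length `T̄ · qD̄`, which at *q* = 0 is Faith's PD.
- **FD** — pairwise trait distances are the entities. With Rao's
  `Q = Σ_ij d_ij p_i p_j`, the effective number of equally distinct
  species is `qD(Q) = [Σ_ij (d_ij/Q)(p_i p_j)^q]^{1/(2(1−q))}`
  (Gower distances over SLA, leaf thickness and wood density by default).

The inference layer fits NB2 GLMs (dispersion θ jointly ML-estimated)
between attributes and against latitude, reports the Cragg–Uhler
pseudo-R², and fits NB GLMMs with a Gaussian region intercept (marginal
likelihood via adaptive Gauss–Hermite quadrature) over all 16 main-effect
subsets of the four environmental predictors. Model selection rejects
candidates with ΔAICc ≥ 2 and keeps the most complex of the remainder;
Nakagawa marginal/conditional R² summarise the selected fit.

A fully seeded synthetic-study generator (five regions across ~10° of
tropical latitude, seasonality near-collinear with latitude, birth–death
phylogeny with Brownian traits, log-series abundances) provides known
ground truth for every stage.

## Worked example

```python
>>> from divgrad import branch_abundances, hill_phylo, parse_newick
>>> tree = parse_newick("((A:1,B:1):1,C:2);")
>>> bas = branch_abundances(tree, {"A": 0.25, "B": 0.25, "C": 0.5})
>>> bas.T_bar
2.0
>>> hill_phylo(bas, 0)     # (mean lineages, total PD = Faith's PD)
(2.5, 5.0)
>>> hill_phylo(bas, 2)
(2.2857142857142856, 4.571428571428571)
```

The abundance-weighted tree depth is 2.0; the community spans 5.0 units
of branch length (Faith's PD), behaving like 2.5 maximally distinct
lineages; weighting by dominance (*q* = 2) shrinks that to ~2.29.

Each capability has a narrative script under `examples/`; for instance

```bash
python examples/synthetic_gradient.py
```

simulates the default five-region study and prints the latitudinal NB
GLM for each attribute — with the default effect sizes, TD at *q* = 0
yields a significant positive slope on signed latitude (pR² ≈ 0.36 at
seed 1), i.e. diversity rising toward the Equator.

The pipeline is also a CLI:

```bash
divgrad simulate --seed 7 --out runs/demo   # synthetic study + analysis
divgrad run --config run.toml               # your own CSV/newick inputs
divgrad report runs/demo                    # markdown summary
```

A run directory contains `diversity_profile.csv`, `attribute_glms.csv`,
`latitude_glms.csv`, `glmm_candidates.csv`, `glmm_selected.csv`,
`correlation_matrix.csv`, `coverage_report.csv` and `run.log`, each
stamped with a hash of the configuration.

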