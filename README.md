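# dbtlsim

Simulated design–build–test–learn (DBTL) cycles for combinatorial metabolic
pathway optimization.

## The problem

Combinatorial pathway optimization varies the expression level of each of the
*N* enzymes of a pathway over *P* discrete levels (achievable with a promoter
or RBS library), giving a design space of *P*^*N*^ strains — far too many to
build. Practitioners therefore iterate DBTL cycles: build a small batch of
strains, measure product flux, learn a model, and use it to choose the next
batch. Real multi-cycle datasets are scarce, which makes it hard to answer
basic questions: which regression models work in the low-data regime, how
robust are they to library biases and measurement noise, and how should a
fixed strain budget be split over cycles?

`dbtlsim` answers these questions in simulation. A kinetic ODE model of a
seven-reaction synthetic pathway (irreversible/reversible Michaelis–Menten
and generalized reversible Hill kinetics, equilibrium constants fixed by the
reaction ΔG° via *K*eq = exp(−ΔG°/RT)) provides the ground truth: changing an
enzyme's expression *e*-fold scales its *V*max = *k*cat·[E] *e*-fold, and the
steady-state flux through the terminal reaction, relative to the wild type,
is the quantity to optimize. Kinetic parameters are produced by a built-in
thermodynamically consistent sampler, so the package needs no external data.

On top of the simulator:

- **Benchmark** — seven regressors (elastic net, linear SVM, random forest,
  gradient boosting, neural network, RBF SVR, k-NN) trained on small design
  subsets under three library-bias scenarios and two Gaussian noise models,
  scored by the squared Pearson correlation *R*² over the design space and by
  |predicted top-*k* ∩ true top-*k*|.
- **Recommendation** — a model-free algorithm: sweep a threshold λ* from 0 to
  the maximum predicted flux, track each enzyme level's frequency among
  designs predicted above λ*, take the area under each frequency curve and
  normalize per enzyme. The result is a per-enzyme sampling distribution for
  the next cycle's library.
- **DBTL loop** — multi-cycle experiments with cumulative retraining and
  strategy comparison (e.g. front-loaded (150,50,25,25) vs back-loaded
  (25,25,50,150) splits of a 250-strain budget).

## Worked example

```python
import numpy as np
from dbtlsim import default_pathway, generate_parameters, default_grid
from dbtlsim.design_space import DesignGrid, enumerate_designs, simulate_landscape
from dbtlsim.learn import ModelSpec, run_benchmark, summarize_benchmark

spec = default_pathway()                      # 7 reactions, Keq from dG
params = generate_parameters(spec, seed=0)    # stable, thermo-consistent set

grid = default_grid(spec)                     # P = 6 levels, N = 7 enzymes
print(grid.size)                              # 279936

toy = DesignGrid(enzymes=("rA", "rC", "rD", "rG"), levels=(0.5, 1.0, 2.0))
land = simulate_landscape(params, toy)        # 81 designs, relative fluxes
print(land["relative_flux"].min(), land["relative_flux"].max())
# 0.5069450191703101 1.3271422908839927   (wild-type row is exactly 1.0)

res = run_benchmark([ModelSpec("gradient_boosting"), ModelSpec("elastic_net")],
                    toy, land, n_train=[20], runs=5, seed=0, k=10)
print(summarize_benchmark(res)[["model", "r2_mean", "topk_mean"]])
#                model   r2_mean  topk_mean
# 0        elastic_net  0.453655        7.0
# 1  gradient_boosting  0.689546        7.4
```

The landscape spans designs roughly 0.5–1.3× the wild-type flux; with only 20
training strains the gradient-boosting regressor predicts the 81-design space
better than the linear model and recovers slightly more of the true top-10
designs.

A command-line interface mirrors the pipeline stages
(`dbtlsim simulate-landscape`, `benchmark`, `recommend`, `dbtl`); run
`dbtlsim --help` for details.

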