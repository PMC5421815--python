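# aggscaff

**Aggregation–removal modelling of post-synaptic scaffold domains.**

How does a synapse keep a protein domain of well-defined size when its
molecular constituents turn over within minutes to hours?  At inhibitory
synapses the gephyrin scaffold is delivered to the neuronal membrane,
diffuses laterally while bound to glycine receptors, aggregates on
encounter, and is continuously removed back into the cytoplasm.
`aggscaff` implements this aggregation–removal model end to end, for
biophysicists studying membrane protein clustering and for analysts
fitting super-resolution (PALM) cluster counts:

* **analytic single-domain balance** — a domain absorbing diffusing
  particles at its edge and losing them over its area reaches the
  stationary size `N = rho (D0/k) Phi(c0/rho)`, with `Phi(u) = pi x^2`
  from the screened-diffusion flux balance `x K0(x)/K1(x) = 2u`;
* **particle-based simulation** — Brownian clusters in a periodic box
  with size-dependent diffusion `D(n) = D0 n^-sigma`, contact fusion,
  binomial desorption and monomer reinsertion (exact particle
  conservation); disc-rearranged and fractal (no-rearrangement) variants;
* **Smoluchowski rate equations** — stationary cluster-size
  distributions `c_n` with source and per-particle removal and kernel
  `K(i,j) = B (i^-sigma + j^-sigma)`; the `-3/2` power law at sigma = 0
  and the typical-size scaling `<<n>> ~ (c0 D0/k)^(1/(1+sigma))`;
* **tagged-cluster dynamics** — Gillespie jump-process trajectories of
  one cluster against the stationary bath; autocorrelation `C2(tau)`
  decaying on the turnover timescale 1/k, and the time-reversal moment
  `Y(tau)`, whose non-zero value certifies a non-equilibrium steady
  state;
* **Poisson maximum-likelihood fitting** — grid fits of predicted
  distributions to per-culture cluster counts with per-culture
  concentration profiling and bootstrap confidence regions, plus a
  synthetic-data generator (counts, localisation clouds with blinking
  noise, 50 nm single-link re-clustering) to validate the pipeline.

## Worked example

```python
import aggscaff as ag

params = ag.PhysicalParams(D0=0.02, k=1/1800, c0=4/3, rho=5000/3)
sol = ag.domain_size(params)
print(f"lambda = {sol.lam:.1f} um, R = {1000*sol.R:.0f} nm, "
      f"N = {sol.N:.1f} trimers")
```

prints

```
lambda = 6.0 um, R = 119 nm, N = 74.7 trimers
```

With literature values for the receptor-bound diffusion constant
(0.02 um^2/s), gephyrin turnover (30 min) and membrane concentration
(4/3 trimers/um^2), the flux balance predicts a domain of ~75 gephyrin
trimers (~220 monomers) with a 6 um depletion halo — the measured size
scale of synaptic gephyrin domains, from diffusion, aggregation and
turnover alone.

The `examples/` directory holds one short script per capability:

| script | what it shows |
| --- | --- |
| `single_domain.py` | analytic domain size and parameter sweeps |
| `cluster_size_distribution.py` | stationary `c_n`, the -3/2 power law, effect of sigma |
| `particle_simulation.py` | particle sim vs rate equations after one-constant calibration |
| `tagged_cluster_dynamics.py` | `C2(tau)`, `Y(tau)` and the 1/k fluctuation timescale |
| `fit_cluster_counts.py` | likelihood fit + bootstrap on synthetic counts |

A thin CLI mirrors the library (`aggscaff domain|simulate|rateeq|trajectories|fit|synth --help`).

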