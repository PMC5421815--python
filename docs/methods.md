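# Methods

`aggscaff` models the formation and maintenance of post-synaptic scaffold
domains (gephyrin at inhibitory synapses, carried by glycine receptors) as
a balance between three membrane processes: delivery of scaffold particles
to the membrane, lateral diffusion with aggregation on contact, and
turnover (removal) of individual particles into the cytoplasm.  The
elementary "particle" throughout is the gephyrin trimer.  Aggregation with
removal is a non-equilibrium phase separation: instead of coarsening into
one macroscopic condensate, the membrane maintains a stationary
distribution of cluster sizes whose scale is tunable by the kinetic
parameters.

## Single-domain flux balance (`domain`, `params`)

A condensed domain of radius R absorbs diffusing particles at its edge;
removal at rate k per particle drains its area.  The free concentration
obeys the screened diffusion equation `D0 lap(c) - k c + J = 0` outside
the disc with `c(R) = 0` and far field `c0 = J/k`, giving
`c(r) = c0 [1 - K0(r/lam)/K0(R/lam)]` with depletion length
`lam = sqrt(D0/k)`.  Equating the perimeter influx `2 pi R D0 c'(R)` with
the area efflux `k N` (N = rho pi R^2) yields

    N = rho (D0/k) Phi(c0/rho),     Phi(u) = pi x(u)^2,
    x K0(x)/K1(x) = 2 u,            x = R/lam.

The root is bracketed on x in [1e-12, 1e3] and solved with Brent's method
at relative tolerance 1e-14 (the left bracket follows the small-x law
`x^2 (ln(2/x) - gamma) = 2u`).  With the literature reference values
(D0 = 0.02 um^2/s, k = 1/30 min, c0 = 4/3 um^-2, rho = 5000/3 um^-2) this
gives N = 74.7 trimers (~220 monomers), i.e. a realistic synaptic domain.
All public interfaces use um and seconds; the simulator uses the natural
units a (particle diameter) and t0 = a^2/D0.

## Particle-based simulation (`particle_sim`)

Clusters live in a periodic square box, positions in [0, L).  Each step of
dt = 0.02 t0: (1) Gaussian displacements with per-axis variance
`2 dt D(n)`, `D(n) = D0 n^-sigma`; (2) fusion of overlapping clusters,
swept to a fixpoint; (3) binomial desorption, m ~ Bin(n, dt k) per
cluster; (4) reinsertion of exactly m monomers at uniform positions, so
the total particle number is conserved exactly — the delivery flux J is
represented by this recycling, pinning c0 = J/k by construction.

Mode A (default) rearranges each cluster into a disc of radius
`sqrt(n/(pi rho))` with rho = 0.77 a^-2 (hexagonal packing); overlap means
centre distance below the radius sum.  Mode B performs no rearrangement:
clusters are rigid unions of member particles and fuse when any two
members of different clusters come within one diameter.  Choices the
underlying scheme leaves open were fixed as follows: fusion cascades are
resolved by connected components processed in ascending id order and
re-swept to a fixpoint; merged clusters sit at the size-weighted centroid
(minimum-image); a pinned (immobile) cluster anchors any merger at its own
centre; desorption shrinks a disc in place and removes uniformly chosen
members of a rigid cluster; reinserted monomers that land on a cluster
fuse in the same step.  Neighbour search uses a periodic k-d tree per
sweep.  A single seeded PCG64 generator with a fixed draw order
(displacements, binomials, reinsertions — each in id order) makes runs
bit-reproducible.

Two numerical properties matter for interpretation.  First-passage
(fusion) times under discrete-time contact checking carry an O(sqrt(dt))
upward bias relative to the continuous process; this shifts the effective
aggregation rate but is absorbed downstream into the calibrated kernel
constant.  Second, the disc-radius convention makes two monomers fuse at
1.29 a in mode A but 1.0 a in mode B; in the dilute regime the 2D
encounter rate depends on the capture radius only logarithmically, so the
modes agree — at dense packings they genuinely would not.

Default sampling: burn-in 5/k, sampling window 10/k, snapshots every
0.5/k (the size memory time is ~1/k).  Where snapshots feed a formal
two-sample test we space them 2/k apart to keep them weakly correlated.

## Rate equations (`rate_equations`)

The mean-field counterpart is the Smoluchowski source-sink system

    dc_n/dt = 1/2 sum_{i+j=n} K_ij c_i c_j - c_n sum_j K_nj c_j
              - n k c_n + (n+1) k c_{n+1} + J delta_{n1},

with aggregation kernel `K(i,j) = B (i^-sigma + j^-sigma)`, i.e.
proportional to the sum of the diffusion constants; the weak logarithmic
radius dependence of 2D encounter rates is absorbed into the single
kinetic constant B, which is calibrated once against particle simulations
(log-concentration least squares over sizes with at least 10 sampled
clusters, coarse log-grid scan plus bounded refinement — the objective is
not unimodal in log B).  One calibration transfers across sigma.

Numerics: the system is solved in normalised variables (concentrations in
units of c0, time in units of 1/k), in which only `B c0/k` and sigma
remain, making the solver insensitive to the absolute input scale.  The
truncation at n_max is made mass-consistent by discarding fusions that
would exceed n_max, so stationarity implies `sum n c_n = c0` exactly;
n_max doubles adaptively (warm-started) until
`n_max c_{n_max} < 1e-6 c0` (cap 2^16).  The steady state is found by
semi-implicit Euler marching (removal cascade and linearised coagulation
loss implicit via a bidiagonal solve; gain explicit; dt ramping to 2/k)
followed by a Jacobian-free Newton–Krylov polish preconditioned with the
frozen bidiagonal linear part, to residual max|dc/dt| < 1e-11 of the peak
rate scale.  The n^2-weighted typical size `<<n>> = sum n^2 c_n / sum n c_n`
is tail-sensitive; sweeps that report it tighten the tail criterion to
1e-10.

For sigma = 0 the stationary distribution is the constant-kernel power law
`c_n ~ n^{-3/2}` with an exponential cutoff; generally
`<<n>> ~ (c0 D0/k)^alpha` with `alpha ~ 1/(1+sigma)` (measured 0.99, 0.68,
0.53 for sigma = 0, 0.5, 1 over ratios 30–1000).

## Tagged-cluster dynamics (`dynamics`)

A single cluster against the frozen stationary bath follows a jump
process: gains of m particles at rate `K(n, m) c_m`, losses of one at rate
`k n` (mean-field: the tagged cluster does not deplete the bath, and
spatial correlations are ignored).  Trajectories are simulated exactly
(Gillespie); partner sizes are drawn from a two-component mixture of fixed
distributions, since the kernel splits as `B n^-sigma c_m + B m^-sigma c_m`.
The autocorrelation `C2(tau)` and the time-reversal moment
`Y(tau) = <n(t+tau) n(t)^2> - <n(t+tau)^2 n(t)>` are estimated by pooling
trajectory segments after a 5/k burn-in, with jackknife standard errors
across trajectories.

For sigma = 0 the gain rate is size-independent and C2 decays at exactly
k.  For sigma > 0 the gain decreases with n, stiffening the restoring
force: at the reference conditions (sigma = 0.5) the fitted decay rate is
~1.2 k, i.e. k tau_fluc ~ 0.82 — the turnover time still sets the
fluctuation timescale, with a ~20% kernel correction.  Y(tau) is zero at
tau = 0 by construction, vanishes identically for any detailed-balance
process (verified against an M/M/inf control chain), and for the model
follows `exp(-k tau)[1 - exp(-k tau)]` up to the same rate correction, so
its peak sits slightly below ln2/k.  This asymmetry — gradual shrinkage,
sudden growth — is the direct signature that aggregation-removal operates
out of thermodynamic equilibrium.

## Likelihood fit (`fit`)

Observed inputs are per-culture cluster-size histograms `#_i` (sizes in
trimers) with the imaged membrane area A_exp.  For parameters
S = (k/D0, sigma, c0) the stationary solution predicts means
`n_i = A_exp c_i(S)` and the likelihood is a product of Poissons over
sizes i = 2..i_max (monomers are excluded as noise-dominated; i_max is the
largest observed size).  Only k/D0 and c0 identify the stationary shape:
we set B = D0, so the unknown dimensionless encounter prefactor is a
recognised systematic scale factor on the inferred k/D0.  Concentrations
are non-dimensionalised by rho = 5000/3 trimers/um^2.

The fit scans a grid (defaults: sigma in {0, .25, .5, .75, 1}, k/D0
log-spaced over the plausible 1.4e-2–4.2e-1 um^-2, c0 log-spaced over
0.3–8 um^-2), profiles c0 per culture (ties towards smaller c0; edge
argmaxes flagged), and maximises the summed profiled log-likelihood over
(k/D0, sigma).  Grid points where a positive count meets a zero predicted
mean are excluded with a warning.  Bootstrap confidence regions resample
individual clusters (size >= 2) with replacement per culture and refit
each resample against a precomputed model table, honouring the resample's
own i_max; the region is the smallest set of grid points covering 95% of
resample argmaxes.

## Synthetic data (`synthetic`)

The experimental counts are emulated at three levels.  (1) Counts:
`#_i ~ Poisson(A_exp c_i)` independently per size and culture — exactly
the sampling model the likelihood assumes.  The bundled reference
conditions are sigma = 0.5, D0/k = 30 um^2, c0 = {0.5, 2, 5} um^-2,
A_exp = 1e3 um^2 per culture, matching the experimentally inferred regime
(largest clusters of order tens of trimers).  (2) Localisations: each
cluster of i trimers holds 3i monomers packed uniformly in a disc at
density 3 rho; monomers are labeled with a given efficiency and emit a
geometric number of detections (mean 1 by default; blinking statistics
are not published, so the multiplicity is configurable) scattered with
Gaussian precision 20 nm.  Clusters are placed on a shuffled jittered grid
with >= 200 nm edge separation so single-link cannot merge distinct
clusters by construction.  (3) Re-clustering: single-link at 50 nm
(connected components of the proximity graph), then size =
round(detections / f) with f = 3 x labeling efficiency x detections per
monomer.

What passing tests show — and do not show.  The generator reproduces the
fit's statistical assumptions (independent Poisson counts, isolated
clusters, known calibration factor), so parameter-recovery results
validate the inference machinery, not the model's biological adequacy.
Real PALM data add unmodelled structure: spatially clumped synaptic vs
extrasynaptic clusters, fluorophore blinking beyond a geometric law,
drift residuals, cluster overlap at 50 nm, and an uncertain
detections-to-size calibration.

## Scale choices

Tests and the acceptance script run at reduced scale chosen to preserve
each regime rather than the full reference sizes: simulations use 150–400
particles with turnover rates 2e-3–0.05 per t0 (full reference:
~1e4 particles, k = 1.54e-5); the tagged-cluster ensembles use >= 1000
trajectories of 30/k; the power-law check runs at B c0/k = 5000 where the
scaling window spans a decade; the pinned-domain comparison pools six
seeded runs per condition at k = 0.02.  The disc/fractal comparison runs
at c0 = 0.002 a^-2 — dilute enough that the logarithmic radius dependence
of 2D encounters keeps the two geometries equivalent, as at the reference
concentration.

## Known limitations

* Phi is the absorbing-disc reconstruction; a different analytic
  convention could shift N by a prefactor of order 10% (the reference
  prediction is quoted as ~70–75 trimers).
* The kernel form `B (i^-sigma + j^-sigma)` absorbs all geometry into one
  constant; only ratios of kinetic parameters are identifiable, and the
  inferred k/D0 scale inherits the unknown O(1) prefactor.
* The mean-field tagged-cluster description ignores spatial correlations;
  its occupation distribution is known to deviate slightly from the
  particle simulation, and its C2/Y timescales carry the ~20% sigma
  correction described above.
* No lateral desorption ("vapor pressure"), no explicit receptor species,
  no cluster fragmentation: a rigid mode-B cluster whose bridging member
  desorbs remains one cluster.
* Gelation-like loss of mass beyond n_max is prevented by construction,
  not analysed.
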