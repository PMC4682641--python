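# frapkit

Quantification of live-cell photobleaching experiments — FRAP
(fluorescence recovery after photobleaching), FLIP (fluorescence loss in
photobleaching) and high-speed line-scan FRAP — for nuclear proteins
that exchange between a free pool, chromatin-bound foci and an RNA-bound
state, such as the HP1-family heterochromatin protein Swi6 of fission
yeast. The package pairs the analysis with an exact stochastic simulator
of the underlying three-state exchange kinetics, so every stage of the
pipeline can be validated against known ground truth without any
microscopy data.

Intended users: cell biologists and microscopists quantifying
photobleaching time series of focally enriched nuclear proteins, and
method developers who need a fully synthetic, ground-truth-bearing test
bed for FRAP analysis code.

## The model

A bleached locus recovers as unbleached molecules exchange in. In the
reaction-dominant regime (diffusion fast relative to binding turnover)
the normalized post-bleach intensity is fitted with

    one component:  y(x) = a (1 − exp(−b x))
    two components: y(x) = a (1 − exp(−b x)) + c (1 − exp(−d x)),  b ≥ d

by unweighted nonlinear least squares; the half-recovery time is
t½ = ln 2 / b (one component) or the numerically solved time at which
y reaches (a + c)/2. A nested F-test decides whether the second
component is warranted. The mobile fraction of a locus is

    F_M = (F∞ / F_initial) / (N_after / N_before),

the recovery ratio corrected by the whole-nucleus fluorescence totals
from pre/post z-stacks — necessary because bleaching a single focus
destroys 20–35% of total nuclear fluorescence, and because loci drift
out of a fixed confocal plane (z-stack sums are drift-invariant,
single-plane intensities are not).

The simulator realises the three-state scheme — free ⇄ chromatin-bound
⇄ RNA-bound — as independent continuous-time Markov chains per
molecule, renders nuclei with 2–6 bright foci into noisy image stacks
(Gaussian spots, axial Ornstein–Uhlenbeck locus drift, acquisition
photobleaching, Poisson shot noise), and carries a matrix-exponential
mean-field oracle giving the exact expected recovery curve, expected
t½ and true mobile fraction.

## Worked example

```python
import frapkit as fk

kin = fk.default_kinetics()          # heterochromatin-like exchange
geo = fk.default_geometry()          # 1 µm nucleus, three foci
img = fk.default_imaging()           # 120 frames every 60 ms, 20 ms bleach

exp = fk.simulate_frap_experiment(kin, geo, img, seed=1)
trace = fk.analyze_trace(exp)        # extract → subtract → detect → normalize
model = fk.ExponentialRecoveryModel.from_trace(trace)
res = model.fit()
print(res.summary())
print(f"expected t_half: {1000 * exp.truth.expected_t_half:.1f} ms")
```

Output:

```
Exponential recovery fit (1 component)
  n obs: 110    SSE: 0.00666446    R^2: 0.9987    AIC: -1064.26
  t_half: 514.2 ms
  a = 1.00673 +/- 0.000988
  b = 1.34805 +/- 0.00718
expected t_half: 483.4 ms
```

The fitted half-recovery time of this single synthetic experiment
(514 ms) sits within sampling error of the mean-field expectation
(483 ms) for the default exchange rates; `a ≈ 1` says the locus recovers
fully, i.e. no immobile population. Mobile fractions, FLIP curves and
line-scan half-times follow the same pattern, e.g.
`fk.mobile_fraction_of(exp)` or `fk.simulate_linescan(...)` +
`fk.linescan_halftime(...)`.

A command-line interface covers the same flow
(`frapkit simulate|extract|normalize|fit|fraction|linescan|report`).

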