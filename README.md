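# fovcrowd

Bayesian analysis of **foveal crowding**: the impairment of letter
identification at the center of gaze caused by nearby flanking letters.
With the eye's optical aberrations corrected (adaptive optics), crowding in
the fovea operates over fractions of an arcminute, and characterizing it
requires fitting non-monotonic psychometric curves, comparing hierarchical
sharing structures across observers and sizes, and extracting critical
spacings with honest uncertainty.  This package implements that full
pipeline for psychophysicists working with flanked-optotype identification
data — and, because trial-level data from such experiments are rarely
deposited, it ships a synthetic-data generator with the statistical
structure of the adaptive-optics study design so every stage is testable.

## The model

Performance vs. edge-to-edge flanker gap *x* (arcmin) is the pointwise
maximum of a linear *recovery* branch and a guess-corrected cumulative
Gaussian *crowding* branch:

```
Ψ(x)          = max(Ψ_recovery(x), Ψ_crowding(x))
Ψ_recovery(x) = m·x + b
Ψ_crowding(x) = γ + (A − γ)·Φ((x − μ)/σ),   γ = 0.25 (4AFC Tumbling E)
```

Five free parameters per condition: asymptote *A*, sigmoid location μ and
width σ (arcmin), recovery slope *m* ≤ 0 and intercept *b*.  Unflanked
trials are the *x* → ∞ limit (probability exactly *A*).  The package
provides:

- **model core** — curve evaluation, guess correction, and the probit
  ("Z-unit") normalization that expresses each curve as a reduction in
  Z-scores from its own asymptote (a 95%→90% drop is 0.363 Z-units).
- **Bayesian fitting** — per-condition MCMC (vectorized ensemble sampler
  with differential-evolution moves) under uniform priors
  A(0,1), σ(0,5), μ(−1,1), m(−1,0), b(0,1), with split-R̂ convergence
  flags and retained posterior draws.
- **model family** — the 12-member constraint lattice over (σ, μ, m) with
  codes F/O/C/N (shared overall / per observer / per observer×optics /
  free per cell), fit jointly by hard parameter sharing and ranked by WAIC.
- **critical spacing** — closed-form crossing of Ψ with *A* − 0.025, 95%
  Monte-Carlo intervals from posterior draws, edge-to-edge ↔
  center-to-center conversions, and the size-limited reference line
  CS = 1.4 × size.
- **synthetic data** — seeded trial-level generation for the 3-observer,
  2-optical-condition factorial design.

## Worked example

Fit one condition (observer S2 with AO correction, 0.47-arcmin strokes,
200 trials per spacing) and extract its critical spacing:

```python
import fovcrowd as fc

design = fc.DesignSpec(
    subjects=("S2",), strokes={("S2", "AO"): (0.47,)},
    gaps=tuple(round(0.2 * i, 10) for i in range(9)), trials_per_cell=200,
)
truth = fc.canonical_truth(design)
trials = fc.simulate(design, truth, seed=42)
fit = fc.fit_condition(trials, seed=0)
print(fit.summary().round(3))
cs = fc.cs_interval(fit, seed=1)
print(f"critical spacing: {cs.value:.2f} arcmin edge-to-edge "
      f"(95% CI {cs.ci_low:.2f}-{cs.ci_high:.2f})")
conv = fc.SpacingConversion("letters", target_size=5 * 0.47)
print(f"center-to-center: {fc.center_to_center(cs.value, conv):.2f} arcmin "
      f"(size-limited prediction {fc.size_limited_line(5 * 0.47):.2f})")
```

prints

```
        mean  median   q2.5  q97.5
A      0.868   0.868  0.840  0.900
mu     0.276   0.280  0.117  0.423
sigma  0.515   0.516  0.291  0.765
m     -0.447  -0.406 -0.961 -0.029
b      0.625   0.624  0.566  0.684
critical spacing: 1.17 arcmin edge-to-edge (95% CI 0.89-1.51)
center-to-center: 3.52 arcmin (size-limited prediction 3.29)
```

The posterior recovers the generating curve (A = 0.861, μ = 0.30,
σ = 0.40, m = −0.30, b = 0.66 all inside their 95% intervals), and the
fitted critical spacing — the gap at which performance drops 0.025 below
the asymptote — lands just above one arcminute, in the range typical for
conditions with 80–95% unflanked performance.

## The analysis, step by step

Numbered drivers under `analysis/` run the full study on synthetic data and
write their tables under `results/`:

```
python analysis/01_simulate.py          # trial table for the full design
python analysis/02_fit_curves.py        # per-condition posteriors
python analysis/03_model_comparison.py  # 12-model lattice ranked by WAIC
python analysis/04_critical_spacing.py  # spacing table + figures
```

The same steps are available as a CLI (`fovcrowd simulate | fit | compare |
spacing | report`); every stochastic command takes `--seed` and reproduces
its outputs byte-for-byte.

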