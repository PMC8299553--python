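# sdefit

Identification of nonlinear scalar stochastic differential equations
(Langevin-type models) from a single long time series — including series
driven by time-correlated ("coloured") forcing.

The method combines four ingredients:

1. **Binned conditional moments.** The series is deliberately subsampled at
   a stride where unresolved forcing has decorrelated, then binned; the
   per-bin means of the increment and its square estimate the finite-time
   conditional moments.
2. **Adjoint Fokker–Planck correction.** For a candidate model, the *exact*
   finite-time moments at sampling gap τ are computed by propagating the
   observables x and x² through the matrix exponential of the discretized
   adjoint Fokker–Planck operator, undoing the distortion that coarse
   sampling introduces into naive Kramers–Moyal estimates.
3. **Stationary-density regularization.** The weighted moment mismatch is
   augmented with η·D_KL between the empirical histogram and the model's
   stationary density (analytic in 1D, or the null vector of the discrete
   forward operator).
4. **Stepwise sparse regression.** When the functional form is unknown,
   a reverse-greedy pass over polynomial candidate libraries repeatedly
   removes the term whose elimination least increases the refitted cost;
   the cost jump along the path selects the parsimonious model.

Coefficients are optimized with restarted Nelder–Mead, warm-started from an
uncorrected weighted-least-squares baseline.  Radial (polar-coordinate)
models carry the structural Itô drift term σ(r)²/2r automatically.

## Layout

| module | contents |
| --- | --- |
| `sdefit.models` | function libraries, `LangevinModel`, JSON schema |
| `sdefit.moments` | `TimeSeries`, subsampling, binned moments, empirical PDF, Markov-scale diagnostic |
| `sdefit.fokker_planck` | forward/adjoint operators, finite-time moments, stationary densities |
| `sdefit.fitting` | cost functions, `fit`, `fit_no_adjoint`, `ssr` model selection |
| `sdefit.simulate` | Euler–Maruyama generators for benchmark systems, dwell times, power spectra |
| `sdefit.io`, `sdefit.pipeline`, `sdefit.cli` | file formats, end-to-end pipelines, command line |

## Command line

```sh
# generate a benchmark trajectory (cubic drift forced by an OU process)
sdefit simulate --system colored_pitchfork --dt 0.01 --n-steps 1000000 \
    --seed 1 --initial-state 1.0 0.0 --out traj.csv

# sampling-scale diagnostics, PSD, dwell times
sdefit diagnose --input traj.csv --dt 0.01 --strides 1,5,10,25,50,100 \
    --upper 0.5 --lower -0.5 --out diag/

# fit a fixed structure (odd cubic drift + additive noise) at stride 50
sdefit fit --input traj.csv --dt 0.01 --stride 50 \
    --drift-degree 3 --drift-parity odd --diffusion-degree 0 --out results/

# discover the structure by stepwise sparse regression
sdefit select --input traj.csv --dt 0.01 --stride 50 \
    --drift-degree 5 --drift-parity odd --diffusion-degree 2 --out results/
```

`fit`/`select` write the model as JSON (`model.json`), the binned-moment
table, an empirical-vs-model PDF table, the SSR path table, and a
`run_log.json` with every effective setting and the seed, so runs are
exactly reproducible.  All options can also be given in a YAML/JSON file
via `--config` (command line takes precedence).

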