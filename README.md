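# frapcme

Entry/exit-rate decomposition of FRAP and FLAP turnover curves via the
chemical master equation, with closed-form curve prediction, K-fold
cross-validation, and Gillespie simulation of protein-interaction
perturbations.

## The problem

Fluorescence recovery after photobleaching (FRAP) and fluorescence loss after
photobleaching (FLAP) measure how quickly a fluorescently tagged protein
exchanges between a region of interest — here a focal adhesion (FA) — and the
surrounding pool. The standard analysis fits the intensity curve with

    y(t) = y0 + A·exp(R0·t)

and reports a single turnover rate `kT = |R0|`. That one number hides *why* a
protein turns over: does it enter the adhesion rarely, or leave it quickly?

Modeling the interior copy number as a one-dimensional birth–death process
(a chemical master equation with a gain channel from the exterior pool and a
loss channel from the interior), the mean intensity relaxes exponentially with
rate `kT = kIn + kOut` toward a stationary interior fraction `n̄`. Two
measured quantities — `kT` and the plateau `n̄` — therefore determine the
entry/exit pair exactly:

    kOut = n̄ · kT,        kIn = kT − kOut.

(The parameterization follows the published rate tables for the twelve FA
proteins, in which the stationary fraction carries `kOut` in the numerator;
see `docs/methods.md` for a discussion of this labeling convention.)

The same framework extends to interactions: removing a stabilizing partner
(vinculin, for talin) adds an interior-loss channel `kIn^V·nIn`, constitutive
actomyosin engagement (via the α-actinin entry rate) adds an interior-gain
channel `kIn^A·nIn`. These perturbed models have no closed form and are
solved numerically with the Gillespie stochastic simulation algorithm,
averaging 1000 runs.

## Worked example

Generate a synthetic 12-replicate FRAP data set with known ground truth
(kIn = 4.94×10⁻³/s, kOut = 6.35×10⁻³/s, Gaussian intensity noise σ = 0.02),
then run the full workflow:

```sh
frapcme synth --k-in 0.00494 --k-out 0.00635 --noise-sigma 0.02 \
        --n-traces 12 --seed 7 --out tensin_like.csv
frapcme fit --input tensin_like.csv --modality frap --out-dir .
```

which prints

```
tensin_like: kT = 11.526 ± 0.210 e-3/s, kIn = 5.088 ± 0.099 e-3/s,
kOut = 6.438 ± 0.122 e-3/s, n̄ = 0.559 ± 0.003
```

The fitted turnover rate (11.53×10⁻³/s vs the generating 11.29×10⁻³/s) and
plateau (0.559 vs 0.562) invert into entry/exit rates within a few percent of
truth. Cross-validate the predictive quality and simulate a perturbation:

```sh
frapcme validate --input tensin_like.csv --k 3 --k 5 --k 10 --reps 20 --seed 7 --out cv.tsv
frapcme simulate --scenario vinculin_loss --n-runs 300 --n-tot 1000 \
        --t-max 600 --seed 7 --out vinc.tsv
```

```
K=3: MAPE = 6.18 ± 0.05% (Highly accurate)
K=5: MAPE = 6.95 ± 0.10% (Highly accurate)
K=10: MAPE = 8.69 ± 0.07% (Highly accurate)
vinculin_loss: plateau mean = 0.3569 ± 0.0009 (mean-field fixed point 0.3564)
```

MAPE below 10% means the closed-form curve predicts held-out replicates to
within a few percent ("highly accurate" band; below 20% is considered
suitable). The vinculin-loss ensemble plateaus at the mean-field fixed point
`kOut/(kT + kIn^V)` — lower than the base talin plateau of 0.481, i.e. loss
of the vinculin interaction makes talin more likely to stay outside the
adhesion.

The same operations are available as a library (`frapcme.fit_exponential`,
`frapcme.invert_rates`, `frapcme.kfold_cv`, `frapcme.ensemble`, …).

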