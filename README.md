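# adipowaves

Bayesian detection of periodicity in longitudinal adipose cell-size
distributions, plus a minimal ODE model of why such periodicity arises.

## The problem

Adipose tissue grows by two interleaved processes: hypertrophy (existing
adipocytes fill with lipid and enlarge) and hyperplasia (new small
adipocytes are recruited). Longitudinal micro-biopsies of the inguinal fat
depot of obese (Zucker *fa/fa*) rats, measured as Coulter-counter diameter
histograms (80 logarithmic bins spanning 20–240 µm, ~6,000 cells per
measurement, 4 replicates per biopsy), suggest these processes alternate in
*waves*. The statistical difficulty is that the sampling is sparse and
irregular — 14–16 biopsy days spread over ~160 days — so standard spectral
methods do not apply. This package implements a discrete Bayesian
model-comparison approach for exactly this setting, aimed at quantitative
physiologists and biostatisticians working with sparse longitudinal
histogram data.

## The method

A candidate periodic model divides a period T = N_b·d into N_b period-bins
of d days each, with an integer phase φ ∈ [0, d−1] locating day 0. Each
biopsy day t is assigned the period-bin

    b(t) = ⌊(t + φ)/d⌋ mod N_b .

Models inducing the same assignment sequence are one model; models in which
some period-bin only covers one contiguous run of days are untestable and
dropped, as are periods outside the detectable ~30–100-day window.

Within one cell-size bin i, the measured percentage y on the days mapped to
period-bin b is modelled as lognormal with bin-specific parameters,

    log p(y | µ_{i,b}, σ_{i,b}) = −log y − log σ − ½log 2π − (log y − µ)²/(2σ²),

and the model's score is the marginal likelihood with (µ, σ) integrated out
against proper uninformative priors (uniform µ, log-uniform σ),
independently per period-bin and per cell-size bin; one cell-size bin is
excluded for the percentage-normalization constraint. The marginalization
runs by parallel-tempered MCMC with thermodynamic integration,

    log Z = ∫₀¹ ⟨log L⟩_β dβ ,

validated against a deterministic 2-D quadrature oracle to 0.1 nats.
Evidences are compared across all surviving models plus the no-period
model, and marginalized into 5-day period intervals to give a posterior
over the period itself.

Because the original rat histograms are unpublished, the package ships a
synthetic-data generator reproducing their statistical structure (bimodal
lognormal mixture, multinomial counting, replicate noise, the printed
biopsy schedule) with a configurable true period, so the whole pipeline is
testable end to end by parameter recovery.

The companion ODE module realizes the proposed mechanism: PPAR signalling P
switches on when lipid flux L exceeds the uptake capacity U = u·N_m of
medium-size adipocytes,

    dP/dt  = δ·(θ(L − U) − P)
    dNs/dt = r·P − g·Ns
    dNm/dt = g·Ns − k·L·Nm
    dNl/dt = k·L·Nm ,

a relaxation oscillator whose recruitment period decreases with L.

## Worked example

```bash
python examples/04_evidence_and_selection.py
```

generates periodic synthetic data (true period 56 d, 20 diameter bins) and
runs the full comparison:

```
models scored:      529 periodic + null
best model:         7 bins x 8 d (phase 7) -> period 56 d
log evidence:       -1078.2
null model gap:     941.1 nats
modal period:       [55, 60) days
```

The best model recovers the generator's 7×8-day structure exactly; the
no-period model loses by ~941 nats, and the period posterior concentrates
on the 5-day interval containing the truth. The other examples cover the
generator (`01`), fractional-difference diagnostics (`02`), model-space
enumeration (`03`) and the recruitment oscillator (`05`). The same stages
are available as a CLI: `adipowaves simulate-data | model-space | fit |
report | ode`.

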