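"""Bayesian model comparison: score the model space and recover the period.

Generates periodic synthetic data (true period 56 days) on a reduced 20-bin
diameter grid, computes the marginal likelihood of every pruned periodic
model plus the no-period model by parallel-tempered thermodynamic
integration, and marginalizes into 5-day period intervals.
Takes about half a minute on one core.
"""

from adipowaves import GeneratorConfig, make_log_grid, run_pipeline, sample_dataset
from adipowaves.evidence import fast_pt_config

config = GeneratorConfig(
    grid=make_log_grid(20), seed=7, mode="piecewise_constant",
    true_period=56.0, n_period_bins_true=7, w_small_amplitude=0.2,
)
dataset, _ = sample_dataset(config)
summary = run_pipeline(dataset, pt=fast_pt_config(seed=7), report_dir="fit_out")

best = summary["best_model"]
print(f"models scored:      {summary['n_models_scored']} periodic + null")
print(f"best model:         {best['n_bins']} bins x {best['bin_width']} d "
      f"(phase {best['phase']}) -> period {best['period']:.0f} d")
print(f"log evidence:       {best['logZ']:.1f}")
print(f"null model gap:     {summary['null_gap']:.1f} nats")
lo, hi = summary["modal_period_interval"]
print(f"modal period:       [{lo:.0f}, {hi:.0f}) days")
# The modal 5-day interval of the period posterior should contain the
# generator's 56-day truth, and the no-period model should lose by a large
# evidence margin; reports are written under fit_out/.
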