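"""Experimentally provided context: rank effects on satisfaction ratings.

Simulates raters judging feedback times drawn from unimodal vs bimodal
contexts, then runs the full analysis stage: QC, per-rater maximum-likelihood
fits of the full / rank-only / range-only models, and nested LR tests.
"""

from ranksat import AnalysisConfig, SimulationConfig, gen_exp1, run_exp1

cfg = SimulationConfig(seed=12, n_exp1=8, w=0.3, s=0.4)
dataset = gen_exp1(cfg, conditions=("unimodal", "bimodal"))
report = run_exp1(dataset, AnalysisConfig(seed=12, n_restarts=4))

for key, cond in report["conditions"].items():
    cp = cond["critical_point_means"]
    print(f"{key}: n={cond['n_retained']}, "
          f"mean dissatisfaction at 23 days = {cp['23.0']:.2f}, "
          f"at 49 days = {cp['49.0']:.2f}")
    rank, rng = cond["effect_of_rank"], cond["effect_of_range"]
    print(f"  rank effect:  chi2({rank['df']}) = {rank['chi2']:.1f}, p = {rank['p']:.3g}")
    print(f"  range effect: chi2({rng['df']}) = {rng['chi2']:.1f}, p = {rng['p']:.3g}")

# 23 days ranks 2nd among the unimodal times but 5th among the bimodal ones,
# so the same objective wait draws less dissatisfaction in the unimodal
# context; 49 days (rank 10 vs 7) reverses — the crossover that isolates a
# pure rank effect. The LR tests ask whether dropping the rank (or range)
# component of the fitted judgement model significantly hurts the likelihood.
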