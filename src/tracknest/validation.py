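"""Monte-Carlo validation scenarios for the analysis ladder.

Each function defines one *study condition* -- a simulator configuration that
isolates a statistical property of the ladder -- and a per-replicate runner
returning the quantities the property is judged on:

* ``calibration_replicate``: null population effect with cell-level
  heterogeneity; the mixed model should reject at its nominal level while the
  step-pooled t-test, blind to the dependence among a cell's steps, rejects
  far too often.
* ``coverage_replicate``: injected dye and interaction effects on log speed;
  factorial-ANOVA confidence intervals should cover the truth at 95%.
* ``censoring_replicate``: boundary censoring over-represents slow cells in
  pooled steps; the cell-controlling mixed estimate should sit closer to the
  true mean cell speed than the pooled mean.
* ``reversal_replicate``: unbalanced dye assignment with opposing
  interaction effects makes the naive pooled comparison reverse the true
  population-effect sign; the factorial and mixed fits keep the right sign.

Seeds are taken explicitly so replicate loops stay reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .motility import cell_summaries, compute_steps
from .simulate import Design, SimConfig, simulate_experiment
from .stats import MotilityANOVA, t_test

__all__ = [
    "child_seeds",
    "null_calibration_config",
    "calibration_replicate",
    "coverage_replicate",
    "censoring_replicate",
    "reversal_replicate",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2**31) derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def null_calibration_config(seed: int) -> SimConfig:
    """Null population effect, 40 cells/arm x 50 steps, sigma_cell = sigma_step."""
    return SimConfig(
        design=Design(1, 1, 1, 1, cells_per_field=80, max_frames=50),
        sigma_cell=0.35, sigma_step=0.35, censor_on_exit=False, seed=seed,
    )


def calibration_replicate(seed: int) -> tuple[float, float]:
    """(mixed-model population p, step-pooled t-test p) for one null dataset."""
    ts, _ = simulate_experiment(null_calibration_config(seed))
    steps = compute_steps(ts)
    mixed = MotilityANOVA(random_effects=("cell",)).fit(steps)
    pops = sorted(steps["population"].unique())
    a = steps.loc[steps.population == pops[0], "speed"].to_numpy()
    b = steps.loc[steps.population == pops[1], "speed"].to_numpy()
    return mixed.result_.p_population, t_test(a, b).p_value


_COVERAGE_DYE = 0.10          # log-speed offset of the first dye level
_COVERAGE_INTERACTION = 0.08


def coverage_replicate(seed: int) -> tuple[bool, bool]:
    """Do the factorial 95% CIs cover the injected dye and interaction effects?

    Steps are independent here (no cell-level variance), so ordinary
    least-squares intervals on log speed are exact.
    """
    cfg = SimConfig(
        design=Design(1, 1, 1, 1, cells_per_field=60, max_frames=10),
        sigma_cell=0.0, sigma_step=0.3,
        dye_effect=_COVERAGE_DYE, interaction_effect=_COVERAGE_INTERACTION,
        censor_on_exit=False, seed=seed,
    )
    ts, _ = simulate_experiment(cfg)
    steps = compute_steps(ts)
    steps["log_speed"] = np.log(steps["speed"])
    est = MotilityANOVA(response="log_speed").fit(steps)
    tcrit = sps.t.ppf(0.975, est.df_residual_)

    def covers(term, truth):
        i = est.term_slices_[term].start
        half = tcrit * np.sqrt(est.cov_coef_[i, i])
        return bool(abs(est.coef_[i] - truth) <= half)

    # sorted levels put "KO" first, flipping the population contrast sign
    # relative to the simulator's (+ for "WT") convention; the dye contrast
    # keeps its sign ("CFSE" sorts first), so the interaction flips too.
    return (covers("dye", _COVERAGE_DYE),
            covers("interaction", -_COVERAGE_INTERACTION))


def censoring_config(seed: int, censor: bool = True) -> SimConfig:
    # 40 cells/arm: the censoring bias of the pooled mean (~1.4 um/min here)
    # must dominate the sampling noise of the cell-level mean (~0.5 um/min)
    # for the bias ordering to be visible in single replicates
    return SimConfig(
        design=Design(1, 1, 1, 1, cells_per_field=80, max_frames=40),
        baseline_log_speed=float(np.log(10.0)),
        sigma_cell=0.4, sigma_step=0.2, kappa=5.0,
        volume=(150.0, 150.0, 50.0), censor_on_exit=censor, seed=seed,
    )


def censoring_replicate(seed: int) -> dict:
    """Pooled, cell-mean and mixed-model speed estimates vs the true mean.

    Truth is the expected per-cell mean speed,
    exp(baseline + sigma_cell^2/2 + sigma_step^2/2).
    """
    cfg = censoring_config(seed)
    ts, _ = simulate_experiment(cfg)
    steps = compute_steps(ts)
    mixed = MotilityANOVA(fixed=("population",), random_effects=("cell",)).fit(steps)
    truth = float(np.exp(cfg.baseline_log_speed
                         + cfg.sigma_cell**2 / 2 + cfg.sigma_step**2 / 2))
    return {
        "pooled": float(steps["speed"].mean()),
        "cell_mean": float(cell_summaries(steps)["speed_mean"].mean()),
        "mixed": float(mixed.grand_mean_),
        "truth": truth,
    }


_REVERSAL = dict(population_effect=-0.075, dye_effect=-0.25,
                 interaction_effect=-0.15)


def reversal_replicate(seed: int) -> dict:
    """CARMA1-style confound: the knockout is truly faster, but it is mostly
    labelled with the slow dye, so the naive pooled comparison says slower."""
    cfg = SimConfig(
        design=Design(1, 1, 1, 1, cells_per_field=80, max_frames=10),
        sigma_cell=0.0, sigma_step=0.3,
        dye_weights={"WT": 0.2, "KO": 0.8},  # KO mostly on the slow dye
        censor_on_exit=False, seed=seed, **_REVERSAL,
    )
    ts, _ = simulate_experiment(cfg)
    steps = compute_steps(ts)
    steps["log_speed"] = np.log(steps["speed"])
    # truth: s_pop(KO) = -1, so the KO offset is -population_effect > 0
    true_ko = -cfg.population_effect
    naive = (steps.loc[steps.population == "KO", "log_speed"].mean()
             - steps.loc[steps.population == "WT", "log_speed"].mean())
    fact = MotilityANOVA(response="log_speed").fit(steps)
    mixed = MotilityANOVA(response="log_speed", random_effects=("cell",)).fit(steps)
    return {
        "naive_sign_correct": bool(np.sign(naive) == np.sign(true_ko)),
        "factorial_sign_correct": bool(
            np.sign(fact.population_effects_["KO"]) == np.sign(true_ko)),
        "mixed_sign_correct": bool(
            np.sign(mixed.population_effects_["KO"]) == np.sign(true_ko)),
    }
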