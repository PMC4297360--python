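"""Synthetic raters with the generative structure each experiment assumes.

No human data were deposited with the study these designs come from, so the
package ships generators that emulate the three data shapes:

* Experiment 1 — per-participant ordinal ratings of eleven stimulus values
  from one of four context distributions, generated from the latent-normal
  RFT model (a latent Normal(L + RFT·(U−L), s) discretised at half-integer
  cutpoints).
* Experiment 2 — nine percentile probes from a participant-specific
  log-normal belief (hyperpriors wide enough that believed medians span the
  roughly 9–40-day spread reported for real students), an own-provision
  value, and a 1–5 satisfaction rating drawn from a proportional-odds model
  whose linear predictor uses the true subjective rank (and optionally the
  own value).
* Experiment 3 — binary complain/not-complain responses to eleven printed
  provision values, driven by a mixture of a contextual-rank rule and an
  absolute rule.

All generators are deterministic given the seed; per-participant substreams
are spawned from the seed by counter, so enlarging ``n`` leaves earlier
participants' data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contexts import DOMAIN_ORIENTATIONS, exp1_context, exp3_context
from .elicitation import PROBE_PERCENTILES, map_probe_to_quantile
from .ordinal_model import CUTPOINTS
from .rft_core import Orientation, ParametricBelief, frequency_value, rft_value

__all__ = ["SimulationConfig", "gen_exp1", "gen_exp2", "gen_exp3"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the synthetic raters.

    Defaults emulate the study conditions: four conditions of ~38 raters in
    Experiment 1 (152 recruited), 170 in Experiment 2, ~42 per condition in
    Experiment 3 (85 recruited); a moderate range weight w = 0.5 and latent
    noise s = 0.5 on a 1–5 response scale; belief hyperpriors wide enough
    that the 10th/90th percentiles of believed medians sit near 9 and 40
    days; and a complaint rule that is mostly contextual (mixing 0.7) with an
    absolute component, matching the observed "absolute as well as relative"
    pattern.
    """

    seed: int = 0
    # Experiment 1
    n_exp1: int = 38  # per condition
    w: float = 0.5
    s: float = 0.5
    L: float = 1.0
    U: float = 5.0
    # Experiment 2
    n_exp2: int = 170
    belief_logmean_meanlog: float = 1.046  # log of ~2.85 => believed medians ~17 d
    belief_logmean_sdlog: float = 0.20
    belief_logsd_scale: float = 0.4  # half-normal scale of the log-SD
    belief_logsd_floor: float = 0.1
    probe_noise: float = 0.025  # multiplicative (log-scale SD); ~5% QC exclusions
    own_logmean: float = 2.4849  # log 12 days
    own_logsd: float = 0.5
    rank_coef: float = 3.2
    own_coef: float = 0.0
    satisfaction_cutpoints: tuple[float, ...] = (0.5, 1.3, 2.0, 2.8)
    # Experiment 3
    n_exp3: int = 42  # per condition
    mixing: float = 0.7  # weight on the contextual-rank rule
    complaint_mu: float = 0.55  # mean badness threshold
    complaint_sd: float = 0.12

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1 or not 0 <= self.mixing <= 1:
            raise ValueError("weights must lie in [0, 1]")
        if self.s <= 0 or self.probe_noise < 0:
            raise ValueError("noise parameters must be nonnegative (s > 0)")


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _discretize(latent: np.ndarray) -> np.ndarray:
    """Map latent response tendencies to 1–5 via the half-integer cutpoints."""
    return 1 + np.searchsorted(CUTPOINTS, latent)


def _endpoints(cfg: SimulationConfig, orientation: Orientation) -> tuple[float, float]:
    # Dissatisfaction rises with magnitude when higher is worse and falls
    # when higher is better (reversed endpoints, U < L).
    if orientation is Orientation.HIGHER_IS_WORSE:
        return cfg.L, cfg.U
    return cfg.U, cfg.L


def gen_exp1(
    config: SimulationConfig,
    domain_label: str = "feedback_time",
    conditions: Sequence[str] = ("unimodal", "bimodal", "neg_skew", "pos_skew"),
) -> pd.DataFrame:
    """Ordinal ratings in long format:
    participant_id, condition, domain, stimulus_value, response."""
    orientation = DOMAIN_ORIENTATIONS.get(domain_label, Orientation.HIGHER_IS_WORSE)
    L, U = _endpoints(config, orientation)
    rows = []
    for ci, condition in enumerate(conditions):
        context = exp1_context(condition, domain_label)
        means = np.array(
            [L + rft_value(v, context, config.w) * (U - L) for v in context.values]
        )
        for pi in range(config.n_exp1):
            rng = _rng(config, 1, ci, pi)
            latent = means + config.s * rng.standard_normal(len(means))
            responses = _discretize(latent)
            pid = f"e1_{condition}_{pi:03d}"
            for v, r in zip(context.values, responses):
                rows.append((pid, condition, domain_label, v, int(r)))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "domain", "stimulus_value", "response"],
    )


def _draw_satisfaction(rng: np.random.Generator, eta: float,
                       cutpoints: Sequence[float]) -> int:
    """Sample from the proportional-odds model P(Y<=k) = logistic(a_k - eta)."""
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(cutpoints) - eta)))
    u = rng.uniform()
    return int(1 + np.searchsorted(cum, u))


def gen_exp2(
    config: SimulationConfig,
    domain_label: str = "feedback_time",
    include_truth: bool = False,
) -> pd.DataFrame:
    """Elicitation records, one row per participant:
    participant_id, domain, p10..p90, own_value, satisfaction, gender, year.

    With ``include_truth`` the generating belief parameters and the true
    subjective rank are appended as ``true_*`` columns (ignored by the
    analysis pipeline).
    """
    orientation = DOMAIN_ORIENTATIONS.get(domain_label, Orientation.HIGHER_IS_WORSE)
    rows = []
    for pi in range(config.n_exp2):
        rng = _rng(config, 2, pi)
        logmean = float(np.exp(rng.normal(config.belief_logmean_meanlog,
                                          config.belief_logmean_sdlog)))
        logsd = float(config.belief_logsd_floor
                      + abs(rng.normal(0.0, config.belief_logsd_scale)))
        belief = ParametricBelief("lognormal", logmean, logsd)
        probes = {}
        for k in PROBE_PERCENTILES:
            q = map_probe_to_quantile(orientation, k)
            exact = belief.quantile(q)
            noise = np.exp(rng.normal(0.0, config.probe_noise)) if config.probe_noise else 1.0
            probes[k] = float(exact * noise)
        own = float(np.exp(rng.normal(config.own_logmean, config.own_logsd)))
        true_rank = float(belief.cdf(own))
        eta = config.rank_coef * true_rank + config.own_coef * own
        satisfaction = _draw_satisfaction(rng, eta, config.satisfaction_cutpoints)
        gender = "female" if rng.uniform() < 0.69 else "male"
        year = int(rng.integers(1, 4))
        row = {
            "participant_id": f"e2_{pi:03d}",
            "domain": domain_label,
            **{f"p{k}": probes[k] for k in PROBE_PERCENTILES},
            "own_value": own,
            "satisfaction": satisfaction,
            "gender": gender,
            "year": year,
        }
        if include_truth:
            row.update(
                true_logmean=logmean,
                true_logsd=logsd,
                true_rank=true_rank,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def gen_exp3(
    config: SimulationConfig,
    domain_label: str = "feedback_time",
    conditions: Sequence[str] = ("pos_skew", "neg_skew"),
) -> pd.DataFrame:
    """Complaint responses in long format:
    participant_id, condition, domain, provision_value, complain (yes/no).

    A participant complains at value v when
    ``mixing * contextual_badness_rank(v) + (1 - mixing) * absolute_badness(v)``
    exceeds a participant-specific Normal(complaint_mu, complaint_sd)
    threshold; badness is taken from the worse end of the scale per the
    domain's orientation, so responses are monotone in provision.
    """
    orientation = DOMAIN_ORIENTATIONS.get(domain_label, Orientation.HIGHER_IS_WORSE)
    rows = []
    for ci, condition in enumerate(conditions):
        context = exp3_context(condition, domain_label)
        lo = min(exp3_context(c, domain_label).min for c in conditions)
        hi = max(exp3_context(c, domain_label).max for c in conditions)
        for pi in range(config.n_exp3):
            rng = _rng(config, 3, ci, pi)
            theta = rng.normal(config.complaint_mu, config.complaint_sd)
            pid = f"e3_{condition}_{pi:03d}"
            for v in context.values:
                fv = frequency_value(v, context)
                av = (v - lo) / (hi - lo)
                if orientation is not Orientation.HIGHER_IS_WORSE:
                    fv, av = 1.0 - fv, 1.0 - av
                badness = config.mixing * fv + (1.0 - config.mixing) * av
                complain = "yes" if badness > theta else "no"
                rows.append((pid, condition, domain_label, v, complain))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "domain", "provision_value", "complain"],
    )
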