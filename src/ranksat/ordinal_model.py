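"""Latent-normal ordinal likelihood for context-based satisfaction ratings.

Each discrete 1–5 rating is modelled as a normally distributed latent
response tendency whose mean is the RFT value of the stimulus mapped onto
the response scale:

    m(x) = L + rft_value(x; w) * (U - L),      latent ~ Normal(m, s)

with fixed half-integer cutpoints {1.5, 2.5, 3.5, 4.5} partitioning the
latent scale into the five categories.  ``w`` (range weight), ``s`` (latent
noise SD) and the scale endpoints ``L``, ``U`` are free per participant.
Restricting ``w = 0`` gives a rank-only model and ``w = 1`` a range-only
model; comparing either against the full model with a likelihood-ratio test
(one constrained parameter per participant, summed over participants) tests
for range and rank effects respectively.

For higher-is-better domains (interestingness, contact ease) dissatisfaction
falls as provision rises; this is captured by letting ``U < L`` rather than
by transforming the stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .rft_core import ContextSet, frequency_value, range_value

__all__ = [
    "RFTOrdinalParams",
    "ParticipantRatings",
    "ParticipantFit",
    "NestedComparison",
    "CUTPOINTS",
    "category_probabilities",
    "fit_participant",
    "fit_variants",
    "nested_lr_test",
]

Variant = Literal["full", "rank_only", "range_only"]

#: Fixed latent-scale cutpoints between the five response categories.
CUTPOINTS = np.array([1.5, 2.5, 3.5, 4.5])

# Optimizer box constraints; the likelihood is multimodal in (L, U, s).
_BOUNDS = {"w": (0.0, 1.0), "s": (0.05, 5.0), "L": (-5.0, 11.0), "U": (-5.0, 11.0)}
_N_RESTARTS = 8


@dataclass(frozen=True)
class RFTOrdinalParams:
    """Per-participant judgement parameters."""

    w: float  # range weight in [0, 1]
    s: float  # latent noise SD, response-scale units
    L: float  # response-scale value at the contextual minimum
    U: float  # response-scale value at the contextual maximum

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not self.s > 0:
            raise ValueError("s must be positive")
        if self.U == self.L:
            raise ValueError("scale endpoints must differ")


@dataclass(frozen=True)
class ParticipantRatings:
    """One participant's ordinal ratings of the stimuli in their condition.

    Responses are coded 1–5 with higher numbers reflecting higher
    dissatisfaction.
    """

    participant_id: str
    condition: str
    domain_label: str
    stimuli: tuple[float, ...]
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.responses):
            raise ValueError("stimuli and responses must align")
        if any(r not in (1, 2, 3, 4, 5) for r in self.responses):
            raise ValueError("responses must lie in 1..5")


@dataclass(frozen=True)
class ParticipantFit:
    participant_id: str
    variant: Variant
    params: RFTOrdinalParams
    loglik: float
    converged: bool


@dataclass(frozen=True)
class NestedComparison:
    """Aggregated likelihood-ratio comparison of the full RFT model against a
    restricted (rank-only or range-only) variant, one constrained parameter
    per participant, df = number of participants."""

    chi2: float
    df: int
    p: float
    restricted: Literal["rank_only", "range_only"]

    def __post_init__(self) -> None:
        if self.chi2 < 0 or self.df < 1 or not 0 <= self.p <= 1:
            raise ValueError("invalid nested comparison")


def category_probabilities(
    x: float, context: ContextSet, params: RFTOrdinalParams
) -> np.ndarray:
    """Probabilities of the five response categories for stimulus ``x``."""
    rv = range_value(x, context)
    fv = frequency_value(x, context)
    m = params.L + (params.w * rv + (1 - params.w) * fv) * (params.U - params.L)
    z = (CUTPOINTS - m) / params.s
    cum = np.concatenate(([0.0], stats.norm.cdf(z), [1.0]))
    return np.diff(cum)


def _negloglik(
    theta: np.ndarray,
    rv: np.ndarray,
    fv: np.ndarray,
    resp_idx: np.ndarray,
    variant: Variant,
) -> float:
    if variant == "full":
        w, s, L, U = theta
    elif variant == "rank_only":
        w = 0.0
        s, L, U = theta
    else:
        w = 1.0
        s, L, U = theta
    m = L + (w * rv + (1 - w) * fv) * (U - L)
    upper = np.concatenate((CUTPOINTS, [np.inf]))
    lower = np.concatenate(([-np.inf], CUTPOINTS))
    p = ndtr((upper[resp_idx] - m) / s) - ndtr((lower[resp_idx] - m) / s)
    return -float(np.sum(np.log(np.maximum(p, 1e-300))))


def _starts(variant: Variant, responses: np.ndarray, fv: np.ndarray,
            rng: np.random.Generator, n_restarts: int) -> list[np.ndarray]:
    # Deterministic start: endpoints from a least-squares line of responses
    # on frequency value, noise from its residuals.
    slope, intercept = np.polyfit(fv, responses, 1) if np.ptp(fv) > 0 else (0.0, responses.mean())
    L0 = float(np.clip(intercept, *_BOUNDS["L"]))
    U0 = float(np.clip(intercept + slope, *_BOUNDS["U"]))
    if U0 == L0:
        U0 = L0 + 0.5
    resid = responses - (intercept + slope * fv)
    s0 = float(np.clip(np.std(resid) + 0.1, *_BOUNDS["s"]))
    base = [s0, L0, U0] if variant != "full" else [0.5, s0, L0, U0]
    starts = [np.array(base)]
    for _ in range(n_restarts - 1):
        if variant == "full":
            starts.append(np.array([
                rng.uniform(0, 1),
                rng.uniform(0.1, 2.0),
                rng.uniform(0, 6),
                rng.uniform(0, 6),
            ]))
        else:
            starts.append(np.array([
                rng.uniform(0.1, 2.0),
                rng.uniform(0, 6),
                rng.uniform(0, 6),
            ]))
    return starts


def fit_participant(
    ratings: ParticipantRatings,
    context: ContextSet,
    variant: Variant = "full",
    *,
    n_restarts: int = _N_RESTARTS,
    rng: np.random.Generator | int | None = 0,
    extra_starts: Sequence[Sequence[float]] = (),
) -> ParticipantFit:
    """Maximum-likelihood fit of one variant to one participant's ratings.

    Uses bounded quasi-Newton (L-BFGS-B) optimisation from one
    data-informed start plus random restarts; ``extra_starts`` allows
    warm-starting the full model from restricted optima so the nested
    log-likelihood ordering holds by construction.
    """
    if len(set(ratings.stimuli)) < 4:
        raise ValueError("need at least 4 distinct stimulus values to fit")
    rng = np.random.default_rng(rng)
    stim = np.asarray(ratings.stimuli, dtype=float)
    responses = np.asarray(ratings.responses, dtype=float)
    rv = np.array([range_value(v, context) for v in stim])
    fv = np.array([frequency_value(v, context) for v in stim])
    resp_idx = np.asarray(ratings.responses, dtype=int) - 1

    if variant == "full":
        bounds = [_BOUNDS["w"], _BOUNDS["s"], _BOUNDS["L"], _BOUNDS["U"]]
    else:
        bounds = [_BOUNDS["s"], _BOUNDS["L"], _BOUNDS["U"]]

    starts = _starts(variant, responses, fv, rng, n_restarts)
    starts += [np.asarray(s, dtype=float) for s in extra_starts]

    best = None
    converged = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _negloglik, x0, args=(rv, fv, resp_idx, variant),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    theta = best.x
    if variant == "full":
        w, s, L, U = theta
    elif variant == "rank_only":
        w, (s, L, U) = 0.0, theta
    else:
        w, (s, L, U) = 1.0, theta
    if U == L:  # degenerate flat scale; nudge within bounds for validity
        U = L + 1e-9
    params = RFTOrdinalParams(float(w), float(s), float(L), float(U))
    return ParticipantFit(
        participant_id=ratings.participant_id,
        variant=variant,
        params=params,
        loglik=-float(best.fun),
        converged=converged,
    )


def fit_variants(
    ratings: ParticipantRatings,
    context: ContextSet,
    *,
    n_restarts: int = _N_RESTARTS,
    rng: np.random.Generator | int | None = 0,
) -> dict[Variant, ParticipantFit]:
    """Fit full, rank-only and range-only variants to one participant.

    The full model is additionally warm-started from each restricted
    optimum, which guarantees LL_full >= LL_restricted up to optimizer
    tolerance.
    """
    rng = np.random.default_rng(rng)
    rank_fit = fit_participant(ratings, context, "rank_only",
                               n_restarts=n_restarts, rng=rng)
    range_fit = fit_participant(ratings, context, "range_only",
                                n_restarts=n_restarts, rng=rng)
    warm = [
        [0.0, rank_fit.params.s, rank_fit.params.L, rank_fit.params.U],
        [1.0, range_fit.params.s, range_fit.params.L, range_fit.params.U],
    ]
    full_fit = fit_participant(ratings, context, "full",
                               n_restarts=n_restarts, rng=rng, extra_starts=warm)
    # Symmetric polish: restart each restricted fit from the full optimum's
    # (s, L, U) so neither side of the nested comparison is under-optimized.
    polish = [[full_fit.params.s, full_fit.params.L, full_fit.params.U]]
    rank_polished = fit_participant(ratings, context, "rank_only",
                                    n_restarts=1, rng=rng, extra_starts=polish)
    if rank_polished.loglik > rank_fit.loglik:
        rank_fit = rank_polished
    range_polished = fit_participant(ratings, context, "range_only",
                                     n_restarts=1, rng=rng, extra_starts=polish)
    if range_polished.loglik > range_fit.loglik:
        range_fit = range_polished
    return {"full": full_fit, "rank_only": rank_fit, "range_only": range_fit}


def nested_lr_test(
    full_fits: Sequence[ParticipantFit],
    restricted_fits: Sequence[ParticipantFit],
    restricted: Literal["rank_only", "range_only"],
) -> NestedComparison:
    """Aggregated likelihood-ratio test of the full model against a
    restricted variant.

    chi2 = 2 * sum over participants of (LL_full - LL_restricted), with one
    degree of freedom per participant (df = participant count).  Tiny
    negative per-participant differences from optimizer tolerance are
    clamped to zero.
    """
    full_by_id = {f.participant_id: f for f in full_fits}
    restr_by_id = {f.participant_id: f for f in restricted_fits}
    if full_by_id.keys() != restr_by_id.keys():
        raise ValueError("full and restricted fits cover different participants")
    if not full_by_id:
        raise ValueError("no participants to compare")
    chi2 = 0.0
    for pid, full in full_by_id.items():
        diff = full.loglik - restr_by_id[pid].loglik
        chi2 += 2.0 * max(0.0, diff)
    df = len(full_by_id)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return NestedComparison(chi2=float(chi2), df=df, p=p, restricted=restricted)
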