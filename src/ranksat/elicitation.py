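"""Subjective-distribution elicitation from percentile probes.

Participants answer nine questions of the form "how quickly would a
university have to provide feedback to be faster than k out of 100
universities?" for k = 90, 80, ..., 10.  Each answer pins one quantile of the
participant's believed distribution of provision across institutions.  A
parametric cumulative distribution (log-normal or uniform/linear, whichever
fits best in least squares on the probability scale) is fitted to the nine
probes; from it we read off the *subjective mean* (mean of the believed
distribution) and the *subjective rank* of the participant's own provision
(the fitted CDF at their own value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import optimize, stats

from .rft_core import Orientation, ParametricBelief

__all__ = [
    "ExclusionError",
    "ElicitationRecord",
    "SubjectiveSummary",
    "PROBE_PERCENTILES",
    "map_probe_to_quantile",
    "fit_subjective_cdf",
    "subjective_mean",
    "subjective_rank",
    "summarize_record",
]

#: The k in "better than k out of 100 universities", as asked.
PROBE_PERCENTILES = (90, 80, 70, 60, 50, 40, 30, 20, 10)

#: Probes answered with a repair beyond this many values exclude the record.
DEFAULT_REPAIR_LIMIT = 2

#: Records with more missing probes than this are excluded.
MAX_MISSING_PROBES = 4


class ExclusionError(Exception):
    """A participant record that fails quality screening.

    ``reason`` is a short machine-readable tag (``missing_probes``,
    ``non_monotone``, ``degenerate``).
    """

    def __init__(self, reason: str, detail: str = "") -> None:
        super().__init__(detail or reason)
        self.reason = reason


@dataclass(frozen=True)
class ElicitationRecord:
    """Nine percentile probes plus own provision for one participant.

    ``probes`` maps the percentile k of the question wording ("better than k
    of 100") to the reported magnitude; missing answers are ``None`` or NaN.
    Satisfaction is 1–5, higher = more dissatisfaction.
    """

    participant_id: str
    domain_label: str
    probes: Mapping[int, float | None]
    own_provision: float
    satisfaction: int
    gender: str = ""
    year_of_study: int = 0

    def __post_init__(self) -> None:
        bad = set(self.probes) - set(PROBE_PERCENTILES)
        if bad:
            raise ValueError(f"unknown probe percentiles: {sorted(bad)}")
        if self.satisfaction not in (1, 2, 3, 4, 5):
            raise ValueError("satisfaction must lie in 1..5")


@dataclass(frozen=True)
class SubjectiveSummary:
    participant_id: str
    family_used: Literal["lognormal", "uniform"]
    fit_sse: float
    subjective_mean: float
    subjective_rank: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.subjective_rank <= 1.0:
            raise ValueError("subjective rank must lie in [0, 1]")
        if self.fit_sse < 0:
            raise ValueError("SSE must be nonnegative")


def map_probe_to_quantile(orientation: Orientation | str, k: int) -> float:
    """Quantile level of the magnitude distribution pinned by probe ``k``.

    For a higher-is-worse magnitude (feedback time), being "faster/better
    than k of 100" means only 100-k are quicker, so the answer is the
    (100-k)th percentile of the time distribution: k = 90 pins the 0.10
    quantile.  For higher-is-better magnitudes (interestingness %), beating
    k of 100 requires a high value, so the answer is the kth percentile.
    """
    if k not in PROBE_PERCENTILES:
        raise ValueError(f"k must be one of {PROBE_PERCENTILES}")
    orientation = Orientation(orientation)
    if orientation is Orientation.HIGHER_IS_WORSE:
        return (100 - k) / 100.0
    return k / 100.0


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: nondecreasing least-squares fit to y."""
    y = y.astype(float).copy()
    n = len(y)
    # blocks as (value, weight) lists
    vals: list[float] = []
    wts: list[float] = []
    for v in y:
        vals.append(v)
        wts.append(1.0)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2 = vals.pop(), wts.pop()
            v1, w1 = vals.pop(), wts.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
    out = np.empty(n)
    i = 0
    for v, w in zip(vals, wts):
        out[i : i + int(w)] = v
        i += int(w)
    return out


def _sse_lognormal(values: np.ndarray, q: np.ndarray) -> tuple[ParametricBelief, float]:
    z = stats.norm.ppf(q)
    logv = np.log(values)
    sigma0, mu0 = np.polyfit(z, logv, 1)
    sigma0 = max(sigma0, 1e-6)

    def resid(theta: np.ndarray) -> np.ndarray:
        mu, sigma = theta
        return stats.norm.cdf((logv - mu) / sigma) - q

    sol = optimize.least_squares(
        resid, x0=[mu0, sigma0], bounds=([-np.inf, 1e-9], [np.inf, np.inf])
    )
    belief = ParametricBelief("lognormal", float(sol.x[0]), float(sol.x[1]))
    return belief, float(np.sum(resid(sol.x) ** 2))


def _sse_uniform(values: np.ndarray, q: np.ndarray) -> tuple[ParametricBelief, float]:
    if np.ptp(values) <= 0:
        raise ExclusionError("degenerate", "all probe values identical")
    slope, intercept = np.polyfit(values, q, 1)
    if slope <= 0:
        raise ExclusionError("degenerate", "non-increasing linear CDF")
    lower = -intercept / slope
    upper = lower + 1.0 / slope
    belief = ParametricBelief("uniform", float(lower), float(upper))
    sse = float(np.sum((belief.cdf(values) - q) ** 2))
    return belief, sse


def fit_subjective_cdf(
    record: ElicitationRecord,
    orientation: Orientation | str = Orientation.HIGHER_IS_WORSE,
    repair_limit: int = DEFAULT_REPAIR_LIMIT,
) -> tuple[ParametricBelief, dict[str, float]]:
    """Fit a subjective CDF to one participant's percentile probes.

    Both candidate families (log-normal and uniform/linear CDF) are fitted by
    least squares on the probability scale, minimising
    ``sum_j (F(value_j) - p_j)^2``; the family with the smaller SSE wins
    (log-normal on ties).  Returns the winning belief and the per-family SSE.

    Screening mirrors the study's exclusions: more than four missing probes
    excludes the record, and probe sequences that are not weakly monotone in
    the quantile level are repaired by pool-adjacent-violators averaging —
    if more than ``repair_limit`` probes need repair, the record is excluded.
    """
    orientation = Orientation(orientation)
    pairs = []
    for k in PROBE_PERCENTILES:
        v = record.probes.get(k)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v <= 0:
            raise ExclusionError("degenerate", f"nonpositive probe value {v}")
        pairs.append((map_probe_to_quantile(orientation, k), float(v)))
    n_missing = len(PROBE_PERCENTILES) - len(pairs)
    if n_missing > MAX_MISSING_PROBES:
        raise ExclusionError("missing_probes", f"{n_missing} probes unanswered")

    pairs.sort()
    q = np.array([p for p, _ in pairs])
    values = np.array([v for _, v in pairs])
    repaired = _isotonic(values)
    n_repaired = int(np.sum(~np.isclose(repaired, values)))
    if n_repaired > repair_limit:
        raise ExclusionError("non_monotone", f"{n_repaired} probes repaired")
    values = repaired

    beliefs: dict[str, tuple[ParametricBelief, float]] = {}
    beliefs["lognormal"] = _sse_lognormal(values, q)
    beliefs["uniform"] = _sse_uniform(values, q)
    sse = {fam: s for fam, (_, s) in beliefs.items()}
    winner = "lognormal" if sse["lognormal"] <= sse["uniform"] else "uniform"
    return beliefs[winner][0], sse


def subjective_mean(belief: ParametricBelief) -> float:
    """Mean of the believed distribution (exp(mu + sigma^2/2) for the
    log-normal, midpoint for the uniform)."""
    return belief.mean


def subjective_rank(
    own: float,
    belief: ParametricBelief,
    orientation: Orientation | str = Orientation.HIGHER_IS_WORSE,
) -> float:
    """Relative ranked position of one's own provision in the belief: the
    fitted CDF at the own value.

    For a higher-is-worse magnitude this is the believed proportion of other
    institutions with *better* (smaller) provision than one's own — e.g. a
    student receiving feedback in 7 days under a belief with F(7) = .17
    thinks 17% of others are served more quickly.  For higher-is-better
    magnitudes the same CDF value reads as the proportion *worse* off; no
    tail flip is applied, the orientation only fixes the interpretation.
    """
    return float(np.clip(belief.cdf(own), 0.0, 1.0))


def summarize_record(
    record: ElicitationRecord,
    orientation: Orientation | str = Orientation.HIGHER_IS_WORSE,
    repair_limit: int = DEFAULT_REPAIR_LIMIT,
) -> SubjectiveSummary:
    """Full elicitation stage for one record: fit, then summary quantities."""
    belief, sse = fit_subjective_cdf(record, orientation, repair_limit)
    return SubjectiveSummary(
        participant_id=record.participant_id,
        family_used=belief.family,  # type: ignore[arg-type]
        fit_sse=sse[belief.family],
        subjective_mean=subjective_mean(belief),
        subjective_rank=subjective_rank(record.own_provision, belief, orientation),
    )
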