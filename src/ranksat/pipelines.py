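"""Experiment-level analysis stages: QC → derived quantities → inference.

Three pipelines mirror the three study designs:

* ``run_exp1`` — screen raters (signed Kendall coefficient and response
  range), fit the full / rank-only / range-only latent-normal RFT variants
  per participant, aggregate nested likelihood-ratio tests per condition,
  tabulate mean dissatisfaction per stimulus and at the shared critical
  points, and compare the skewed conditions' mean dissatisfaction.
* ``run_exp2`` — fit each participant's subjective CDF from the percentile
  probes, derive subjective mean and subjective rank, correlate
  dissatisfaction with own provision / rank / mean, then run the two
  proportional-odds regressions (rank + own value, then adding the mean).
* ``run_exp3`` — reduce each participant's 11 complain/not-complain
  responses to a complaint threshold, summarise per condition and compare
  the skew conditions.

All reports are plain JSON-serialisable dicts recording retained/excluded
counts with per-reason tallies; given the same input and configuration the
report is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .elicitation import (
    PROBE_PERCENTILES,
    ElicitationRecord,
    ExclusionError,
    SubjectiveSummary,
    summarize_record,
)
from .ordinal_model import ParticipantRatings, fit_variants, nested_lr_test
from .rft_core import ContextSet, Orientation, frequency_value
from .contexts import CRITICAL_POINTS, DOMAIN_ORIENTATIONS
from .stats_inference import (
    kendall_tau,
    pearson_r,
    proportional_odds_fit,
    two_sample_comparison,
)

__all__ = [
    "AnalysisConfig",
    "QCDecision",
    "ComplaintRecord",
    "ComplaintThreshold",
    "qc_exp1",
    "run_exp1",
    "run_exp2",
    "complaint_threshold",
    "run_exp3",
    "load_config",
    "write_report",
]

log = logging.getLogger("ranksat")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings (YAML-loadable).

    ``tau_cutoff`` and ``range_cutoff`` are the rater-screening rules:
    exclude when the appropriately signed Kendall coefficient between
    responses and stimuli falls below .5, or when the response range is 2 or
    less.  ``threshold_convention`` selects the complaint-threshold summary:
    the midpoint between the last tolerated and first complained-at value, or
    the first complained-at value itself.
    """

    tau_cutoff: float = 0.5
    range_cutoff: int = 2
    n_restarts: int = 8
    seed: int = 0
    repair_limit: int = 2
    threshold_convention: Literal["midpoint", "first"] = "midpoint"


def load_config(path: str | Path | None) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reason: str | None = None


def _expected_sign(orientation: Orientation) -> float:
    # Dissatisfaction should rise with magnitude when higher is worse.
    return 1.0 if orientation is Orientation.HIGHER_IS_WORSE else -1.0


def qc_exp1(
    ratings: ParticipantRatings,
    orientation: Orientation | str | None = None,
    tau_cutoff: float = 0.5,
    range_cutoff: int = 2,
) -> QCDecision:
    """Screen one rater: response range must exceed ``range_cutoff`` and the
    appropriately signed Kendall coefficient between responses and stimuli
    must reach ``tau_cutoff``."""
    if orientation is None:
        orientation = DOMAIN_ORIENTATIONS.get(
            ratings.domain_label, Orientation.HIGHER_IS_WORSE
        )
    orientation = Orientation(orientation)
    responses = np.asarray(ratings.responses)
    if responses.max() - responses.min() <= range_cutoff:
        return QCDecision(False, "range")
    tau = kendall_tau(ratings.stimuli, responses)
    if _expected_sign(orientation) * tau < tau_cutoff:
        return QCDecision(False, "tau")
    return QCDecision(True)


def _ratings_from_long(df: pd.DataFrame) -> list[ParticipantRatings]:
    out = []
    for (pid, cond, dom), grp in df.groupby(
        ["participant_id", "condition", "domain"], sort=True
    ):
        out.append(
            ParticipantRatings(
                participant_id=str(pid),
                condition=str(cond),
                domain_label=str(dom),
                stimuli=tuple(float(v) for v in grp["stimulus_value"]),
                responses=tuple(int(r) for r in grp["response"]),
            )
        )
    return out


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(x, nd))


def run_exp1(dataset: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Full Experiment-1 stage on a long-format ratings table.

    Returns a JSON-serialisable report: per (condition, domain) the rank and
    range likelihood-ratio tests, mean dissatisfaction per stimulus, the
    critical-point means (23/36/49 where present), exclusion accounting, and
    the positively vs negatively skewed mean-dissatisfaction comparison.
    """
    config = config or AnalysisConfig()
    all_ratings = _ratings_from_long(dataset)
    report: dict = {"conditions": {}, "exclusions": {}, "skew_comparison": {}}
    participant_means: dict[tuple[str, str], dict[str, float]] = {}

    for (cond, dom), group in _grouped(all_ratings):
        decisions = {
            r.participant_id: qc_exp1(r, tau_cutoff=config.tau_cutoff,
                                      range_cutoff=config.range_cutoff)
            for r in group
        }
        kept = [r for r in group if decisions[r.participant_id].keep]
        reasons: dict[str, int] = {}
        for d in decisions.values():
            if not d.keep:
                reasons[d.reason] = reasons.get(d.reason, 0) + 1
        log.info("exp1 %s/%s: retained %d of %d (%s)",
                 cond, dom, len(kept), len(group), reasons or "no exclusions")
        if len(kept) < 2:
            raise ValueError(f"fewer than 2 retained participants in {cond}/{dom}")

        orientation = DOMAIN_ORIENTATIONS.get(dom, Orientation.HIGHER_IS_WORSE)
        context = ContextSet(
            sorted({v for r in group for v in r.stimuli}),
            orientation=orientation, domain_label=dom,
        )
        fits = {}
        dropped_nonconv = 0
        for i, r in enumerate(sorted(kept, key=lambda r: r.participant_id)):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(11, i))
            )
            trio = fit_variants(r, context, n_restarts=config.n_restarts, rng=rng)
            if not all(f.converged for f in trio.values()):
                dropped_nonconv += 1
                continue
            fits[r.participant_id] = trio
        if dropped_nonconv:
            reasons["non_convergence"] = dropped_nonconv

        full = [t["full"] for t in fits.values()]
        effect_of_rank = nested_lr_test(
            full, [t["range_only"] for t in fits.values()], "range_only")
        effect_of_range = nested_lr_test(
            full, [t["rank_only"] for t in fits.values()], "rank_only")

        stim_means = {}
        for v in context.values:
            vals = [resp for r in kept
                    for sv, resp in zip(r.stimuli, r.responses) if sv == v]
            stim_means[str(v)] = _round(float(np.mean(vals)))
        critical = {
            str(v): stim_means[str(float(v))]
            for v in CRITICAL_POINTS if str(float(v)) in stim_means
        }
        for r in kept:
            participant_means.setdefault((cond, dom), {})[r.participant_id] = float(
                np.mean(r.responses)
            )

        report["conditions"][f"{cond}/{dom}"] = {
            "n_retained": len(kept),
            "n_fitted": len(fits),
            "mean_w": _round(float(np.mean([t["full"].params.w for t in fits.values()]))),
            "effect_of_rank": _comparison_dict(effect_of_rank),
            "effect_of_range": _comparison_dict(effect_of_range),
            "stimulus_means": stim_means,
            "critical_point_means": critical,
        }
        report["exclusions"][f"{cond}/{dom}"] = {
            "n_excluded": len(group) - len(kept),
            "reasons": reasons,
        }

    for dom in sorted({d for (_, d) in participant_means}):
        pos = participant_means.get(("pos_skew", dom))
        neg = participant_means.get(("neg_skew", dom))
        if pos and neg:
            cmp_ = two_sample_comparison(list(neg.values()), list(pos.values()))
            report["skew_comparison"][dom] = _group_comparison_dict(
                cmp_, label_a="neg_skew", label_b="pos_skew"
            )
    return report


def _grouped(ratings: Sequence[ParticipantRatings]):
    keys = sorted({(r.condition, r.domain_label) for r in ratings})
    for key in keys:
        yield key, [r for r in ratings
                    if (r.condition, r.domain_label) == key]


def _comparison_dict(c) -> dict:
    return {"chi2": _round(c.chi2, 3), "df": c.df, "p": _round(c.p, 6),
            "restricted": c.restricted}


def _group_comparison_dict(c, label_a: str, label_b: str) -> dict:
    return {
        "groups": [label_a, label_b],
        "means": [_round(c.mean_a), _round(c.mean_b)],
        "ses": [_round(c.se_a), _round(c.se_b)],
        "t": _round(c.t, 4),
        "df": c.df,
        "p": _round(c.p, 6),
        "cohens_d": _round(c.cohens_d, 4),
        "n": [c.n_a, c.n_b],
    }


# ---------------------------------------------------------------------------
# Experiment 2


def _records_from_wide(df: pd.DataFrame) -> list[ElicitationRecord]:
    records = []
    for _, row in df.iterrows():
        probes = {}
        for k in PROBE_PERCENTILES:
            v = row.get(f"p{k}")
            probes[k] = None if pd.isna(v) else float(v)
        records.append(
            ElicitationRecord(
                participant_id=str(row["participant_id"]),
                domain_label=str(row["domain"]),
                probes=probes,
                own_provision=float(row["own_value"]),
                satisfaction=int(row["satisfaction"]),
                gender=str(row.get("gender", "")),
                year_of_study=int(row.get("year", 0)),
            )
        )
    return records


def run_exp2(dataset: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Three-stage Experiment-2 analysis per domain.

    Stage 1 fits each participant's subjective CDF; stage 2 derives the
    subjective mean and the subjective rank of own provision; stage 3
    correlates dissatisfaction with own value / rank / mean (Pearson and
    Kendall) and fits two proportional-odds regressions: (1) own value +
    subjective rank + gender + year, (2) adding subjective mean.
    """
    config = config or AnalysisConfig()
    report: dict = {}
    for dom, sub in dataset.groupby("domain", sort=True):
        orientation = DOMAIN_ORIENTATIONS.get(str(dom), Orientation.HIGHER_IS_WORSE)
        records = _records_from_wide(sub)
        summaries: list[tuple[ElicitationRecord, SubjectiveSummary]] = []
        reasons: dict[str, int] = {}
        for rec in records:
            try:
                summaries.append(
                    (rec, summarize_record(rec, orientation, config.repair_limit))
                )
            except ExclusionError as exc:
                reasons[exc.reason] = reasons.get(exc.reason, 0) + 1
                log.info("exp2 %s: excluded %s (%s)", dom, rec.participant_id, exc.reason)
        if len(summaries) < 20:
            raise ValueError(f"fewer than 20 retained participants in domain {dom}")

        tab = pd.DataFrame(
            {
                "satisfaction": [r.satisfaction for r, _ in summaries],
                "own_value": [r.own_provision for r, _ in summaries],
                "subjective_rank": [s.subjective_rank for _, s in summaries],
                "subjective_mean": [s.subjective_mean for _, s in summaries],
                "gender": [1.0 if r.gender == "female" else 0.0 for r, _ in summaries],
                "year": [float(r.year_of_study) for r, _ in summaries],
            },
            index=[r.participant_id for r, _ in summaries],
        )
        correlations = {}
        for pred in ("own_value", "subjective_rank", "subjective_mean"):
            correlations[pred] = {
                "pearson_r": _round(pearson_r(tab[pred], tab["satisfaction"]), 4),
                "kendall_tau": _round(kendall_tau(tab[pred], tab["satisfaction"]), 4),
            }

        covariates = [c for c in ("gender", "year") if tab[c].nunique() > 1]
        reg1 = proportional_odds_fit(
            tab["satisfaction"], tab[["own_value", "subjective_rank", *covariates]]
        )
        reg2 = proportional_odds_fit(
            tab["satisfaction"],
            tab[["own_value", "subjective_rank", "subjective_mean", *covariates]],
        )
        report[str(dom)] = {
            "n_retained": len(summaries),
            "n_excluded": len(records) - len(summaries),
            "exclusion_reasons": reasons,
            "family_counts": {
                str(k): int(v)
                for k, v in pd.Series(
                    [s.family_used for _, s in summaries]
                ).value_counts().items()
            },
            "correlations": correlations,
            "regression_1": _regression_dict(reg1),
            "regression_2": _regression_dict(reg2),
        }
    return report


def _regression_dict(res) -> dict:
    rows = {}
    for name, row in res.table.iterrows():
        rows[str(name)] = {
            "coef": _round(row["coef"], 4),
            "se": _round(row["se"], 4),
            "wald": _round(row["wald"], 4),
            "p": _round(row["p"], 6),
        }
    return {
        "coefficients": rows,
        "ll_model": _round(res.ll_model, 4),
        "ll_null": _round(res.ll_null, 4),
        "nagelkerke_r2": _round(res.nagelkerke_r2, 4),
        "n": res.n,
    }


# ---------------------------------------------------------------------------
# Experiment 3


@dataclass(frozen=True)
class ComplaintRecord:
    """One participant's complain/not-complain responses to 11 values."""

    participant_id: str
    condition: str
    domain_label: str
    values: tuple[float, ...]
    complain: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.complain):
            raise ValueError("values and responses must align")
        if len(self.values) != 11:
            raise ValueError("a complaint record holds exactly 11 value-response pairs")


@dataclass(frozen=True)
class ComplaintThreshold:
    participant_id: str
    threshold: float
    threshold_rank: float


def complaint_threshold(
    record: ComplaintRecord,
    context: ContextSet,
    convention: Literal["midpoint", "first"] = "midpoint",
) -> ComplaintThreshold:
    """Reduce one participant's responses to a complaint threshold.

    Values are ordered from best to worst provision (per the domain's
    orientation).  Participants who would never complain, always complain, or
    complain at better provision than a level they tolerate are excluded.
    The threshold is either the midpoint between the worst tolerated value
    and the best complained-at value, or the first complained-at value
    itself; ``threshold_rank`` is the frequency value of the first
    complained-at value within the condition's context.
    """
    worse_is_larger = context.orientation is Orientation.HIGHER_IS_WORSE
    order = np.argsort(record.values)
    if not worse_is_larger:
        order = order[::-1]
    vals = np.asarray(record.values)[order]
    resp = np.asarray(record.complain)[order]
    if resp.all():
        raise ExclusionError("all_complain", "complains at every level")
    if not resp.any():
        raise ExclusionError("never_complain", "complains at no level")
    first_yes = int(np.argmax(resp))
    if not resp[first_yes:].all():
        raise ExclusionError("non_monotone",
                             "complains at better provision than a tolerated level")
    first_value = float(vals[first_yes])
    if convention == "first":
        threshold = first_value
    else:
        threshold = (float(vals[first_yes - 1]) + first_value) / 2.0
    return ComplaintThreshold(
        participant_id=record.participant_id,
        threshold=threshold,
        threshold_rank=frequency_value(first_value, context),
    )


def _complaints_from_long(df: pd.DataFrame) -> list[ComplaintRecord]:
    out = []
    for (pid, cond, dom), grp in df.groupby(
        ["participant_id", "condition", "domain"], sort=True
    ):
        raw = grp["complain"]
        flags = tuple(
            str(v).strip().lower() in ("yes", "true", "1") for v in raw
        )
        out.append(
            ComplaintRecord(
                participant_id=str(pid),
                condition=str(cond),
                domain_label=str(dom),
                values=tuple(float(v) for v in grp["provision_value"]),
                complain=flags,
            )
        )
    return out


def run_exp3(dataset: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Experiment-3 stage: thresholds per condition and the skew contrast."""
    config = config or AnalysisConfig()
    records = _complaints_from_long(dataset)
    report: dict = {"conditions": {}, "skew_comparison": {}}
    thresholds: dict[tuple[str, str], list[ComplaintThreshold]] = {}
    for (cond, dom) in sorted({(r.condition, r.domain_label) for r in records}):
        group = [r for r in records
                 if (r.condition, r.domain_label) == (cond, dom)]
        orientation = DOMAIN_ORIENTATIONS.get(dom, Orientation.HIGHER_IS_WORSE)
        context = ContextSet(sorted({v for r in group for v in r.values}),
                             orientation=orientation, domain_label=dom)
        kept: list[ComplaintThreshold] = []
        reasons: dict[str, int] = {}
        for r in group:
            try:
                kept.append(complaint_threshold(r, context, config.threshold_convention))
            except ExclusionError as exc:
                reasons[exc.reason] = reasons.get(exc.reason, 0) + 1
        log.info("exp3 %s/%s: retained %d of %d (%s)",
                 cond, dom, len(kept), len(group), reasons or "no exclusions")
        if len(kept) < 2:
            raise ValueError(f"fewer than 2 retained participants in {cond}/{dom}")
        thresholds[(cond, dom)] = kept
        tvals = np.array([k.threshold for k in kept])
        report["conditions"][f"{cond}/{dom}"] = {
            "n_retained": len(kept),
            "n_excluded": len(group) - len(kept),
            "exclusion_reasons": reasons,
            "mean_threshold": _round(float(tvals.mean()), 4),
            "se_threshold": _round(float(tvals.std(ddof=1) / np.sqrt(len(tvals))), 4),
            "mean_threshold_rank": _round(
                float(np.mean([k.threshold_rank for k in kept])), 4
            ),
        }
    for dom in sorted({d for (_, d) in thresholds}):
        neg = thresholds.get(("neg_skew", dom))
        pos = thresholds.get(("pos_skew", dom))
        if neg and pos:
            cmp_ = two_sample_comparison(
                [k.threshold for k in neg], [k.threshold for k in pos]
            )
            report["skew_comparison"][dom] = _group_comparison_dict(
                cmp_, label_a="neg_skew", label_b="pos_skew"
            )
    return report


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize a report deterministically (sorted keys, fixed separators)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def report_markdown(report: Mapping, title: str) -> str:
    """Plain markdown rendering of a report, with per-stimulus mean tables."""
    lines = [f"# {title}", ""]

    def walk(node, depth=2):
        for key, val in node.items():
            if isinstance(val, Mapping) and key == "stimulus_means":
                lines.append(f"{'#' * depth} mean dissatisfaction per stimulus\n")
                lines.append("| stimulus | mean rating |")
                lines.append("| --- | --- |")
                for k, v in val.items():
                    lines.append(f"| {k} | {v} |")
                lines.append("")
            elif isinstance(val, Mapping):
                lines.append(f"{'#' * depth} {key}\n")
                walk(val, min(depth + 1, 6))
            else:
                lines.append(f"- **{key}**: {val}")
        lines.append("")

    walk(dict(report))
    return "\n".join(lines)
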