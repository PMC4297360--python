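"""Packaged stimulus sets used in the judgement experiments.

Experiment 1 used four between-subject distributions of eleven provision
magnitudes (unimodal, bimodal, negatively skewed, positively skewed); the
unimodal and bimodal sets share the critical points 23 and 49, which differ
in rank but not in range position, so rating differences at those points
isolate pure rank effects.  The two skewed sets share their mean (46.5), so
judgement differences between them isolate range/skew effects.  Experiment 3
used its own positively and negatively skewed eleven-value sets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rft_core import ContextSet, Orientation

__all__ = [
    "exp1_stimulus_table",
    "exp3_stimulus_table",
    "exp1_context",
    "exp3_context",
    "EXP1_CONDITIONS",
    "EXP3_CONDITIONS",
    "CRITICAL_POINTS",
    "DOMAIN_ORIENTATIONS",
]

EXP1_CONDITIONS = ("unimodal", "bimodal", "neg_skew", "pos_skew")
EXP3_CONDITIONS = ("pos_skew", "neg_skew")

#: Values shared between the unimodal and bimodal sets; 23 and 49 differ in
#: rank across the two sets (2 vs 5 and 10 vs 7), 36 is a common midpoint.
CRITICAL_POINTS = (23.0, 36.0, 49.0)

DOMAIN_ORIENTATIONS = {
    "feedback_time": Orientation.HIGHER_IS_WORSE,
    "interestingness": Orientation.HIGHER_IS_BETTER,
    "contact_ease": Orientation.HIGHER_IS_BETTER,
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("ranksat.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def exp1_stimulus_table() -> pd.DataFrame:
    """The four Experiment-1 stimulus columns, one condition per column."""
    return _load("exp1_stimulus_sets.csv")


def exp3_stimulus_table() -> pd.DataFrame:
    """The two Experiment-3 stimulus columns."""
    return _load("exp3_stimulus_sets.csv")


def exp1_context(condition: str, domain_label: str = "feedback_time") -> ContextSet:
    """ContextSet for an Experiment-1 condition."""
    tab = exp1_stimulus_table()
    if condition not in tab.columns:
        raise KeyError(f"unknown condition {condition!r}; choose from {EXP1_CONDITIONS}")
    return ContextSet(
        tab[condition].tolist(),
        orientation=DOMAIN_ORIENTATIONS.get(domain_label, Orientation.HIGHER_IS_WORSE),
        domain_label=domain_label,
    )


def exp3_context(condition: str, domain_label: str = "feedback_time") -> ContextSet:
    """ContextSet for an Experiment-3 condition."""
    tab = exp3_stimulus_table()
    if condition not in tab.columns:
        raise KeyError(f"unknown condition {condition!r}; choose from {EXP3_CONDITIONS}")
    return ContextSet(
        tab[condition].tolist(),
        orientation=DOMAIN_ORIENTATIONS.get(domain_label, Orientation.HIGHER_IS_WORSE),
        domain_label=domain_label,
    )
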