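"""Condition binning, exclusions, one-sample tests, and the 2x3 RM-ANOVA.

Memory scores are analyzed in six within-subject cells: subjective
congruency (incongruent = ratings 1-2, congruent = 4-5; a rating of 3
marks indifference and drops the trial) crossed with the 3-level
reactivation report given during AC-encoding.  Per-participant cell means
feed one-sample t-tests against the analytic guessing chance level and a
2 x 3 repeated-measures ANOVA (congruency x reactivation) with partial
eta-squared effect sizes.  The same ANOVA is reused on decoded scene
probabilities by :mod:`reinstate.mvpa`.

The ANOVA is the standard fully-within two-way decomposition: each effect
is tested against its own effect-by-subject interaction (no sphericity
correction by default, matching common practice for a 3-level factor when
none is reported; Greenhouse-Geisser is available via a flag).
Participants missing any cell are dropped listwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ScoredTrial, ValidationError

__all__ = [
    "CONGRUENCY_BINS",
    "REACTIVATION_LEVELS",
    "ConditionTable",
    "AnovaEffect",
    "AnovaResult",
    "OneSampleResult",
    "ExclusionReport",
    "bin_congruency",
    "attach_bins",
    "condition_summary",
    "apply_exclusions",
    "one_sample_test",
    "rm_anova_2x3",
]

CONGRUENCY_BINS = ("incongruent", "congruent")
REACTIVATION_LEVELS = (1, 2, 3)
_CELLS = [(b, r) for b in CONGRUENCY_BINS for r in REACTIVATION_LEVELS]


def bin_congruency(rating: int) -> str:
    """Map a 1-5 subjective congruency rating to its analysis bin.

    1-2 -> "incongruent", 3 -> "excluded" (indifferent; trial dropped from
    condition analyses), 4-5 -> "congruent".
    """
    if rating not in (1, 2, 3, 4, 5):
        raise ValidationError(f"congruency rating must be in 1..5, got {rating!r}")
    if rating <= 2:
        return "incongruent"
    if rating == 3:
        return "excluded"
    return "congruent"


def attach_bins(scored: Iterable[ScoredTrial], ratings, encoding) -> list[ScoredTrial]:
    """Attach congruency bins (from ratings) and reactivation levels (from
    encoding trials) to scored trials by (participant, triad)."""
    from dataclasses import replace

    bin_map = {(r.participant_id, r.triad_id): bin_congruency(r.rating) for r in ratings}
    react_map = {
        (e.participant_id, e.triad_id): e.reactivation_response for e in encoding
    }
    out = []
    for s in scored:
        key = (s.participant_id, s.triad_id)
        out.append(
            replace(s, congruency_bin=bin_map.get(key), reactivation_level=react_map.get(key))
        )
    return out


@dataclass
class ConditionTable:
    """Per-participant cell means and counts for the 2 x 3 design.

    ``means`` and ``counts`` are participant x cell DataFrames with a
    (congruency_bin, reactivation_level) column MultiIndex.  A cell with no
    trials has count 0 and mean NaN (missing, never silently 0).
    """

    means: pd.DataFrame
    counts: pd.DataFrame
    value: str = "memory_score"

    @property
    def participants(self) -> list:
        return list(self.means.index)

    def marginal_means(self, factor: str) -> pd.DataFrame:
        """Participant-level marginal means over one factor
        ("congruency_bin" or "reactivation_level")."""
        return self.means.T.groupby(level=factor).mean().T


def condition_summary(
    scored: Sequence[ScoredTrial],
    value: str = "memory_score",
    values: Optional[Sequence[float]] = None,
) -> ConditionTable:
    """Per-participant (congruency x reactivation) cell means of a score.

    Trials with an excluded congruency bin, no bin, or a missing
    reactivation response are dropped.  ``values`` may override the scored
    value per trial (aligned with ``scored``), e.g. decoded probabilities.
    """
    rows = []
    for i, s in enumerate(scored):
        if s.congruency_bin not in CONGRUENCY_BINS or s.reactivation_level is None:
            continue
        v = values[i] if values is not None else getattr(s, value)
        rows.append(
            {
                "participant_id": s.participant_id,
                "congruency_bin": s.congruency_bin,
                "reactivation_level": s.reactivation_level,
                "value": v,
            }
        )
    columns = pd.MultiIndex.from_tuples(_CELLS, names=["congruency_bin", "reactivation_level"])
    if not rows:
        empty = pd.DataFrame(columns=columns)
        return ConditionTable(means=empty, counts=empty.copy(), value=value)
    frame = pd.DataFrame(rows)
    grouped = frame.groupby(["participant_id", "congruency_bin", "reactivation_level"])["value"]
    means = grouped.mean().unstack(["congruency_bin", "reactivation_level"])
    counts = grouped.size().unstack(["congruency_bin", "reactivation_level"])
    means = means.reindex(columns=columns)
    counts = counts.reindex(columns=columns).fillna(0).astype(int)
    return ConditionTable(means=means, counts=counts, value=value)


@dataclass(frozen=True)
class ExclusionReport:
    included: list
    excluded: list
    offending_cells: dict  # participant -> list of (bin, level, count)


def apply_exclusions(
    table: ConditionTable, min_trials: int = 10, on: str = "margins"
) -> ExclusionReport:
    """Exclude participants with fewer than ``min_trials`` trials in an
    analyzed condition (default threshold: below 10 excludes).

    With ``on="margins"`` (default) the analyzed conditions are the two
    congruency bins and the three reactivation levels — participants can
    still have sparse or empty crossed cells, which the ANOVA then handles
    by listwise deletion.  ``on="cells"`` applies the threshold to all six
    crossed cells instead.
    """
    if on not in ("margins", "cells"):
        raise ValidationError(f"on must be 'margins' or 'cells', got {on!r}")
    included, excluded, offending = [], [], {}
    for pid in table.participants:
        if on == "cells":
            conditions = [
                ((b, r), int(table.counts.loc[pid, (b, r)])) for (b, r) in _CELLS
            ]
        else:
            row = table.counts.loc[pid]
            conditions = [
                ((b,), int(row[b].sum())) for b in CONGRUENCY_BINS
            ] + [
                ((r,), int(row.xs(r, level="reactivation_level").sum()))
                for r in REACTIVATION_LEVELS
            ]
        low = [c + (n,) for (c, n) in conditions if n < min_trials]
        if low:
            excluded.append(pid)
            offending[pid] = low
        else:
            included.append(pid)
    return ExclusionReport(included=included, excluded=excluded, offending_cells=offending)


@dataclass(frozen=True)
class OneSampleResult:
    t: float
    df: int
    p: float
    cohens_d: float  # (mean - null) / sd, the standard one-sample d
    d_vs_zero: float  # mean / sd, the ratio the printed effect sizes follow
    mean: float
    sd: float
    n: int
    null: float


def one_sample_test(values: Sequence[float], null: float) -> OneSampleResult:
    """Two-tailed one-sample t-test of per-participant means against a
    fixed chance level, with both Cohen's d conventions."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    n = arr.size
    if n < 2:
        raise ValidationError(f"one_sample_test needs n >= 2, got {n}")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("zero variance: t statistic undefined")
    mean = float(arr.mean())
    res = sps.ttest_1samp(arr, popmean=null)
    return OneSampleResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        cohens_d=(mean - null) / sd,
        d_vs_zero=mean / sd,
        mean=mean,
        sd=sd,
        n=n,
    null=float(null),
    )


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    gg_epsilon: Optional[float] = None


@dataclass(frozen=True)
class AnovaResult:
    congruency: AnovaEffect
    reactivation: AnovaEffect
    interaction: AnovaEffect
    n_complete: int

    @property
    def effects(self) -> dict:
        return {
            "congruency": self.congruency,
            "reactivation": self.reactivation,
            "interaction": self.interaction,
        }


def rm_anova_2x3(
    table: ConditionTable, gg_correction: bool = False
) -> AnovaResult:
    """Two-way fully-within ANOVA on the 2 x 3 cell means.

    Each effect's error term is its interaction with subjects; partial
    eta-squared is SS_effect / (SS_effect + SS_error).  Participants with
    any missing cell are dropped listwise.  ``gg_correction`` applies
    Greenhouse-Geisser epsilon to the reactivation and interaction terms
    (the congruency factor has 2 levels and needs none).
    """
    means = table.means.dropna(axis=0, how="any")
    n = len(means)
    if n < 3:
        raise ValidationError(f"rm_anova_2x3 needs >= 3 complete cases, got {n}")
    a, b = len(CONGRUENCY_BINS), len(REACTIVATION_LEVELS)
    # y[s, i, j]: subject x congruency x reactivation
    y = means.to_numpy().reshape(n, a, b)

    gm = y.mean()
    subj = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - subj[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - subj[:, None] - m_b[None, :] + gm) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + subj[:, None, None]
        - gm
    )
    ss_abs = np.sum(resid**2)

    # guard against spurious F from 1-ulp rounding residues on constant data
    ss_scale = np.sum((y - gm) ** 2)
    tol = 1e-12 * max(1.0, ss_scale)

    def effect(name, ss_eff, df_eff, ss_err, df_err, eps=None):
        if eps is not None:
            df_eff, df_err = df_eff * eps, df_err * eps
        if ss_err <= tol:
            f = 0.0 if ss_eff <= tol else np.inf
        else:
            f = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaEffect(
            name=name, F=float(f), df_num=float(df_eff), df_den=float(df_err),
            p=p, partial_eta_sq=float(peta), ss_effect=float(ss_eff),
            ss_error=float(ss_err), gg_epsilon=eps,
        )

    eps_b = eps_ab = None
    if gg_correction:
        eps_b = _gg_epsilon(m_sb)
        # interaction contrast scores: subject x (a*b) cell deviations
        inter = (y - m_sa[:, :, None] - m_sb[:, None, :] + subj[:, None, None]).reshape(n, a * b)
        eps_ab = _gg_epsilon_from_cov(np.cov(inter.T), df=(a - 1) * (b - 1))

    return AnovaResult(
        congruency=effect("congruency", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        reactivation=effect("reactivation", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b),
        interaction=effect(
            "interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), eps_ab
        ),
        n_complete=n,
    )


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level scores."""
    cov = np.cov(scores.T)
    return _gg_epsilon_from_cov(cov, df=scores.shape[1] - 1)


def _gg_epsilon_from_cov(cov: np.ndarray, df: int) -> float:
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    grand = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / df, 1.0))
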