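"""The four session scores and the mixed-trial convergence analysis.

Scores
------
original
    %primed over non-mixed rivalry trials only:
    ``(n_BB + n_RR) / (n_BB + n_RR + n_BR + n_RB)``.
improved
    %primed with mixed trials half-weighted in the numerator and fully
    weighted in the denominator:
    ``(n_BB + n_RR + 0.5 n_BM + 0.5 n_RM) / N`` with ``N`` all rivalry
    trials.  Mixed trials pull the score toward 0.5 (the calibrated
    no-priming baseline) but can never push it across 0.5, and with zero
    mixed trials the two scores coincide exactly.
stability
    Proportion of successive rivalry-trial pairs (both responses non-mixed)
    whose dominant percept repeats — serial dependence of the percept, the
    bias hypothesized to replace imagery priming in aphantasia.
difference
    improved − stability.  Oriented so that larger values go with more
    vivid imagery (positive regression slope on VVIQ); aphantasics, being
    stability-dominant, fall at the negative end.

Undefined scores are ``None`` — never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .trial_data import (
    OutcomeCounts,
    Response,
    Session,
    count_outcomes,
    validate_session,
)

__all__ = [
    "ScoreBundle",
    "ScoringConfig",
    "original_priming_score",
    "improved_priming_score",
    "perceptual_stability",
    "difference_score",
    "convergence_curve",
    "score_session",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring options.

    break_at_mock
        If true, a mock trial breaks the adjacency chain for the stability
        score; by default mocks are skipped over, so the pair formed by the
        rivalry trials on either side still counts.
    """

    break_at_mock: bool = False


@dataclass(frozen=True)
class ScoreBundle:
    participant_id: str
    original: Optional[float]
    improved: Optional[float]
    stability: Optional[float]
    difference: Optional[float]
    mixed_proportion: float
    n_nonmixed: int


def original_priming_score(counts: OutcomeCounts) -> Optional[float]:
    """Proportion of non-mixed rivalry trials whose percept matched the cue.

    Undefined (``None``) when every rivalry trial was mixed, since the
    denominator excludes mixed trials entirely.
    """
    denom = counts.n_congruent + counts.n_incongruent
    if denom == 0:
        return None
    return counts.n_congruent / denom


def improved_priming_score(counts: OutcomeCounts) -> Optional[float]:
    """Mixed-weighted priming score; undefined only with zero rivalry trials."""
    denom = counts.total
    if denom == 0:
        return None
    return (counts.n_congruent + 0.5 * counts.n_mixed) / denom


def perceptual_stability(
    session: Session, config: ScoringConfig = ScoringConfig()
) -> Optional[float]:
    """Proportion of successive non-mixed rivalry responses that repeat.

    Pairs with a mixed response on either side are dropped from numerator and
    denominator.  Undefined when no eligible pair exists (fewer than two
    rivalry trials, or mixed percepts break every pair).
    """
    if config.break_at_mock:
        runs: list[list[Response]] = [[]]
        for t in session.trials:
            if t.is_rivalry:
                runs[-1].append(t.response)
            elif runs[-1]:
                runs.append([])
    else:
        runs = [[t.response for t in session.rivalry_trials]]

    matches = eligible = 0
    for run in runs:
        for a, b in zip(run, run[1:]):
            if a is Response.MIXED or b is Response.MIXED:
                continue
            eligible += 1
            matches += a is b
    if eligible == 0:
        return None
    return matches / eligible


def difference_score(
    improved: Optional[float], stability: Optional[float]
) -> Optional[float]:
    """improved − stability; ``None`` propagates from either input."""
    if improved is None or stability is None:
        return None
    return improved - stability


def convergence_curve(
    n_congruent: int, n_incongruent: int, mixed_counts: Sequence[int]
) -> list[Optional[float]]:
    """Improved score as a function of the mixed-trial count.

    With congruent and incongruent tallies fixed, the improved score moves
    monotonically toward 0.5 as mixed trials accumulate — flat at exactly 0.5
    when the non-mixed tallies are equal, and flatter overall the more
    non-mixed trials there are.
    """
    if n_congruent < 0 or n_incongruent < 0 or any(m < 0 for m in mixed_counts):
        raise ValueError("counts must be non-negative")
    curve: list[Optional[float]] = []
    for m in mixed_counts:
        total = n_congruent + n_incongruent + m
        curve.append(None if total == 0 else (n_congruent + 0.5 * m) / total)
    return curve


def score_session(session: Session, config: ScoringConfig = ScoringConfig()) -> ScoreBundle:
    """Compute all four scores plus quality metrics for one session."""
    if not session.trials:
        raise ValueError(f"empty session for participant {session.participant_id!r}")
    counts = count_outcomes(session)
    report = validate_session(session)
    improved = improved_priming_score(counts)
    stability = perceptual_stability(session, config)
    return ScoreBundle(
        participant_id=session.participant_id,
        original=original_priming_score(counts),
        improved=improved,
        stability=stability,
        difference=difference_score(improved, stability),
        mixed_proportion=report.mixed_proportion,
        n_nonmixed=counts.n_congruent + counts.n_incongruent,
    )
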