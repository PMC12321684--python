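"""Domain types, session-log I/O, and validity/exclusion rules.

A *session* is the ordered list of trials one participant produced in the
binocular rivalry imagery-priming task: on each trial the participant first
imagines a cued Gabor pattern (red-horizontal, cue ``R``, or blue-vertical,
cue ``B``), then views a brief rivalry display and reports which pattern
dominated (``red``, ``blue``, or ``mixed``).  Interleaved *mock* trials show
a single unambiguous color and act as catch trials: a compliant observer
answers them with the displayed color.

Logs are delimited text with a mandatory header row naming the five trial
columns ``participant_id, trial_index, trial_type, cue, response``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TrialKind",
    "Cue",
    "Response",
    "Group",
    "Trial",
    "Session",
    "OutcomeCounts",
    "ValidationPolicy",
    "ValidationReport",
    "FormatError",
    "IntegrityError",
    "Dialect",
    "read_sessions",
    "write_sessions",
    "read_vviq",
    "validate_session",
    "count_outcomes",
    "mock_bias",
]


class FormatError(ValueError):
    """The file does not conform to the trial-log schema (e.g. missing column)."""


class IntegrityError(ValueError):
    """The file parses but its content violates a domain rule."""


class TrialKind(str, enum.Enum):
    RIVALRY = "rivalry"
    MOCK_RED = "mock_red"
    MOCK_BLUE = "mock_blue"


class Cue(str, enum.Enum):
    R = "R"
    B = "B"


class Response(str, enum.Enum):
    RED = "red"
    BLUE = "blue"
    MIXED = "mixed"


class Group(str, enum.Enum):
    APHANTASIC = "aphantasic"
    CONTROL = "control"
    UNKNOWN = "unknown"


#: Color shown on a mock trial, keyed by trial kind.
MOCK_DISPLAY = {TrialKind.MOCK_RED: Response.RED, TrialKind.MOCK_BLUE: Response.BLUE}

#: Response color a cue corresponds to (cue R = red pattern, cue B = blue pattern).
CUE_COLOR = {Cue.R: Response.RED, Cue.B: Response.BLUE}


@dataclass(frozen=True)
class Trial:
    """One cue→response event.

    ``index`` is the 1-based presentation order within the session.
    """

    index: int
    kind: TrialKind
    cue: Cue
    response: Response

    def __post_init__(self) -> None:
        if self.index < 1:
            raise IntegrityError(f"trial index must be positive, got {self.index}")
        # coerce raw strings so Trial(1, "rivalry", "R", "red") works
        object.__setattr__(self, "kind", TrialKind(self.kind))
        object.__setattr__(self, "cue", Cue(self.cue))
        object.__setattr__(self, "response", Response(self.response))

    @property
    def is_rivalry(self) -> bool:
        return self.kind is TrialKind.RIVALRY

    @property
    def is_mock(self) -> bool:
        return self.kind is not TrialKind.RIVALRY


@dataclass(frozen=True)
class Session:
    """Ordered trials for one participant, plus optional VVIQ self-report.

    The constructor enforces strictly increasing, unique trial indices and
    valid enum domains.  Design-level expectations (cue balance, at least one
    rivalry trial) are *reported*, not enforced, by :func:`validate_session`,
    so degenerate sessions remain representable.
    """

    participant_id: str
    trials: tuple[Trial, ...]
    vviq: Optional[int] = None
    group: Group = Group.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        indices = [t.index for t in self.trials]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise IntegrityError(
                f"participant {self.participant_id!r}: trial indices must be "
                "unique and strictly increasing"
            )
        if self.vviq is not None and not (16 <= self.vviq <= 80):
            raise IntegrityError(f"VVIQ must lie in [16, 80], got {self.vviq}")
        object.__setattr__(self, "group", Group(self.group))

    @property
    def rivalry_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.is_rivalry)

    @property
    def mock_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.is_mock)

    def with_vviq(self, vviq: Optional[int]) -> "Session":
        return replace(self, vviq=vviq)


@dataclass(frozen=True)
class OutcomeCounts:
    """The six cells of the rivalry cross table.

    First subscript is the cue, second the response; ``M`` marks a mixed
    percept.  Only rivalry trials are tallied here — mock trials never enter
    any score.
    """

    n_BB: int = 0
    n_RR: int = 0
    n_BR: int = 0
    n_RB: int = 0
    n_BM: int = 0
    n_RM: int = 0

    def __post_init__(self) -> None:
        for name in ("n_BB", "n_RR", "n_BR", "n_RB", "n_BM", "n_RM"):
            if getattr(self, name) < 0:
                raise IntegrityError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_BB + self.n_RR + self.n_BR + self.n_RB + self.n_BM + self.n_RM

    @property
    def n_congruent(self) -> int:
        return self.n_BB + self.n_RR

    @property
    def n_incongruent(self) -> int:
        return self.n_BR + self.n_RB

    @property
    def n_mixed(self) -> int:
        return self.n_BM + self.n_RM


@dataclass(frozen=True)
class ValidationPolicy:
    """Data-cleaning policy.

    ``max_mock_errors`` reproduces the compliance gate (at most one wrongly
    answered mock trial keeps a participant in the dataset).  The mixed
    threshold only *flags* by default: under the improved priming score there
    is no need to exclude high-mixed participants, but the legacy behavior is
    available to callers that set ``exclude_over_mixed_threshold``.
    """

    max_mock_errors: int = 1
    mixed_threshold: float = 0.20
    exclude_over_mixed_threshold: bool = False


@dataclass(frozen=True)
class ValidationReport:
    participant_id: str
    n_nonmock: int
    n_mock: int
    mock_errors: int
    mixed_proportion: float
    cue_imbalance: int
    passes_mock_gate: bool
    exceeds_mixed_threshold: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("participant_id", "trial_index", "trial_type", "cue", "response")


@dataclass(frozen=True)
class Dialect:
    """Log-format options.

    ``case_insensitive`` lowercases/uppercases enum tokens before matching
    (so ``Mixed`` or ``mock_Red`` are accepted); off by default because the
    canonical spellings are fixed.
    """

    delimiter: str = ","
    case_insensitive: bool = False


def _normalize_token(token: str, domain: type[enum.Enum], dialect: Dialect, column: str) -> enum.Enum:
    raw = str(token).strip()
    candidate = raw
    if dialect.case_insensitive:
        candidate = raw.upper() if domain is Cue else raw.lower()
    try:
        return domain(candidate)
    except ValueError:
        allowed = ", ".join(m.value for m in domain)
        raise IntegrityError(
            f"invalid {column} token {raw!r}; allowed: {allowed}"
        ) from None


def read_sessions(
    path,
    dialect: Dialect = Dialect(),
    vviq: Optional[Mapping[str, int]] = None,
) -> list[Session]:
    """Read a trial log into one :class:`Session` per participant.

    Trials are sorted by ``trial_index`` within each participant.  ``vviq``
    optionally maps participant ids to VVIQ totals to attach.

    Raises
    ------
    FormatError
        if a required column is missing.
    IntegrityError
        on unknown enum tokens or duplicate (participant, trial_index) pairs.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    sessions: list[Session] = []
    for pid, sub in df.groupby("participant_id", sort=True):
        try:
            idx = sub["trial_index"].astype(int)
        except ValueError as exc:
            raise FormatError(f"non-integer trial_index for participant {pid!r}") from exc
        if idx.duplicated().any():
            dup = int(idx[idx.duplicated()].iloc[0])
            raise IntegrityError(
                f"duplicate (participant, trial_index) = ({pid!r}, {dup})"
            )
        sub = sub.assign(sort_index=idx).sort_values("sort_index")
        trials = tuple(
            Trial(
                index=int(row.sort_index),
                kind=_normalize_token(row.trial_type, TrialKind, dialect, "trial_type"),
                cue=_normalize_token(row.cue, Cue, dialect, "cue"),
                response=_normalize_token(row.response, Response, dialect, "response"),
            )
            for row in sub.itertuples()
        )
        v = None if vviq is None else vviq.get(str(pid))
        sessions.append(Session(participant_id=str(pid), trials=trials, vviq=v))
    return sessions


def write_sessions(sessions: Iterable[Session], path, dialect: Dialect = Dialect()) -> None:
    """Write sessions back to the canonical five-column log format."""
    rows = [
        {
            "participant_id": s.participant_id,
            "trial_index": t.index,
            "trial_type": t.kind.value,
            "cue": t.cue.value,
            "response": t.response.value,
        }
        for s in sessions
        for t in s.trials
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep=dialect.delimiter, index=False
    )


def read_vviq(path, dialect: Dialect = Dialect()) -> dict[str, int]:
    """Read a two-column ``participant_id, vviq`` table into a dict."""
    df = pd.read_csv(path, sep=dialect.delimiter, dtype={"participant_id": str}, comment="#")
    for col in ("participant_id", "vviq"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    return {str(r.participant_id): int(r.vviq) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Validation and tallies


def count_outcomes(session: Session) -> OutcomeCounts:
    """Tally the six-cell cross table over rivalry trials only."""
    cells = dict(n_BB=0, n_RR=0, n_BR=0, n_RB=0, n_BM=0, n_RM=0)
    for t in session.rivalry_trials:
        c = "B" if t.cue is Cue.B else "R"
        r = {"red": "R", "blue": "B", "mixed": "M"}[t.response.value]
        cells[f"n_{c}{r}"] += 1
    return OutcomeCounts(**cells)


def validate_session(session: Session, policy: ValidationPolicy = ValidationPolicy()) -> ValidationReport:
    """Apply the compliance gate and data-quality flags to one session.

    A mock trial is answered correctly when the response color matches the
    displayed mock color; a ``mixed`` response to a mock is an error.  A
    session with no mock trials passes the gate vacuously but carries a
    warning, because compliance cannot be checked.
    """
    rivalry = session.rivalry_trials
    mocks = session.mock_trials
    mock_errors = sum(1 for t in mocks if t.response is not MOCK_DISPLAY[t.kind])

    n_riv = len(rivalry)
    n_mixed = sum(1 for t in rivalry if t.response is Response.MIXED)
    mixed_proportion = n_mixed / n_riv if n_riv else 0.0
    n_cue_r = sum(1 for t in rivalry if t.cue is Cue.R)
    cue_imbalance = abs(n_cue_r - (n_riv - n_cue_r))

    warnings: list[str] = []
    if not mocks:
        warnings.append("no mock trials: compliance gate passed vacuously")
    if not rivalry:
        warnings.append("no rivalry trials: scores will be undefined")
    if cue_imbalance > 1:
        warnings.append(f"cue imbalance of {cue_imbalance} exceeds the balanced design")

    return ValidationReport(
        participant_id=session.participant_id,
        n_nonmock=n_riv,
        n_mock=len(mocks),
        mock_errors=mock_errors,
        mixed_proportion=mixed_proportion,
        cue_imbalance=cue_imbalance,
        passes_mock_gate=mock_errors <= policy.max_mock_errors,
        exceeds_mixed_threshold=mixed_proportion > policy.mixed_threshold,
        warnings=tuple(warnings),
    )


def mock_bias(session: Session) -> Optional[float]:
    """Per-participant imagery-consistency bias on mock trials.

    Defined as the proportion of mock trials answered with the *cued* color
    minus the proportion of mock trials whose *displayed* color equals the
    cued color.  Zero means responses track the display with no pull toward
    the imagined pattern; the cohort-level one-sample test lives in
    :mod:`rivalscore.stats`.

    Returns ``None`` (undefined) for a session without mock trials —
    distinct from a measured bias of 0.
    """
    mocks = session.mock_trials
    if not mocks:
        return None
    answered_cued = sum(1 for t in mocks if t.response is CUE_COLOR[t.cue])
    display_cued = sum(1 for t in mocks if MOCK_DISPLAY[t.kind] is CUE_COLOR[t.cue])
    return (answered_cued - display_cued) / len(mocks)
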