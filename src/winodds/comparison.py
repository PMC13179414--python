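"""Outcome representation and the pairwise win/loss/tie engine.

A subject's composite outcome is the censored pair (time to death, time to
first nonfatal event) together with the corresponding event indicators.
Two subjects are compared hierarchically: death decides first, and only
within the follow-up window the two subjects share; nonfatal events break
the tie on the same shared window.  The result of comparing every ordered
pair is collected into an antisymmetric score matrix with entries in
{0, 1/2, 1}, the "pseudo-observations" that all estimators downstream
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "TrialArrays",
    "ComparisonRule",
    "PairwiseScores",
    "compare_hierarchical",
    "score_matrix",
    "InvalidOutcomeError",
    "RuleConsistencyError",
]


class InvalidOutcomeError(ValueError):
    """An outcome violates the structural invariants (negative times,
    nonfatal time exceeding terminal time, bad indicator values)."""


class RuleConsistencyError(ValueError):
    """A user-supplied comparison rule violated antisymmetry or
    irreflexivity on an evaluated pair."""


#: A comparison rule maps an ordered pair of subject outcomes to a verdict:
#: +1 if the second subject wins, -1 if the first subject wins, 0 for a tie.
#: It must be antisymmetric (rule(a, b) == -rule(b, a)) and irreflexive
#: (rule(a, a) == 0).
ComparisonRule = Callable[["SubjectRecord", "SubjectRecord"], int]


@dataclass
class SubjectRecord:
    """One subject's treatment arm, baseline covariates, and censored
    hierarchical composite outcome.

    Parameters
    ----------
    subject_id
        Opaque identifier, kept only for error messages and output.
    arm
        Binary treatment indicator (1 = treatment, 0 = control).
    covariates
        Baseline covariate vector (length p, possibly empty).  Must be
        measured before randomization for adjustment to be valid.
    terminal_time
        min(time to death, censoring time).
    terminal_event
        1 if ``terminal_time`` is a death, 0 if censoring.
    nonfatal_time
        Time to the first nonfatal event if one was observed, otherwise
        equal to ``terminal_time`` (no information beyond end of follow-up).
    nonfatal_event
        1 if a nonfatal event was observed strictly before death/censoring.
    """

    subject_id: object
    arm: int
    covariates: np.ndarray
    terminal_time: float
    terminal_event: int
    nonfatal_time: float
    nonfatal_event: int

    def __post_init__(self) -> None:
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        self.validate()

    def validate(self) -> None:
        sid = self.subject_id
        if self.arm not in (0, 1):
            raise InvalidOutcomeError(f"subject {sid!r}: arm must be 0 or 1, got {self.arm!r}")
        if self.terminal_event not in (0, 1) or self.nonfatal_event not in (0, 1):
            raise InvalidOutcomeError(f"subject {sid!r}: event indicators must be 0 or 1")
        if not self.terminal_time > 0:
            raise InvalidOutcomeError(
                f"subject {sid!r}: terminal_time must be positive, got {self.terminal_time}"
            )
        if not self.nonfatal_time > 0:
            raise InvalidOutcomeError(
                f"subject {sid!r}: nonfatal_time must be positive, got {self.nonfatal_time}"
            )
        if self.nonfatal_time > self.terminal_time:
            raise InvalidOutcomeError(
                f"subject {sid!r}: nonfatal_time ({self.nonfatal_time}) exceeds "
                f"terminal_time ({self.terminal_time})"
            )
        if self.nonfatal_event == 0 and self.nonfatal_time != self.terminal_time:
            raise InvalidOutcomeError(
                f"subject {sid!r}: without an observed nonfatal event, nonfatal_time "
                f"must equal terminal_time"
            )
        if not np.all(np.isfinite(self.covariates)):
            raise InvalidOutcomeError(f"subject {sid!r}: covariates must be finite")


@dataclass
class TrialArrays:
    """Column-oriented view of a trial used by the vectorized kernels.

    Holds the same information as a list of :class:`SubjectRecord` but as
    flat numpy arrays, which is what the O(n^2) pairwise computations and
    the Fisher-scoring fit operate on.
    """

    arm: np.ndarray          # (n,) int, 0/1
    terminal_time: np.ndarray
    terminal_event: np.ndarray
    nonfatal_time: np.ndarray
    nonfatal_event: np.ndarray
    covariates: np.ndarray   # (n, p) float, p >= 0
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.terminal_time = np.asarray(self.terminal_time, dtype=float)
        self.terminal_event = np.asarray(self.terminal_event, dtype=np.int64)
        self.nonfatal_time = np.asarray(self.nonfatal_time, dtype=float)
        self.nonfatal_event = np.asarray(self.nonfatal_event, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.n and self.covariates.size == 0:
            self.covariates = np.empty((self.n, 0))
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.n)

    @property
    def n(self) -> int:
        return self.arm.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def from_records(cls, records: Sequence[SubjectRecord]) -> "TrialArrays":
        if len(records) < 2:
            raise ValueError("need at least two subjects")
        p = len(records[0].covariates)
        X = np.empty((len(records), p))
        for k, r in enumerate(records):
            if len(r.covariates) != p:
                raise InvalidOutcomeError(
                    f"subject {r.subject_id!r}: covariate length {len(r.covariates)} != {p}"
                )
            X[k] = r.covariates
        return cls(
            arm=np.array([r.arm for r in records]),
            terminal_time=np.array([r.terminal_time for r in records]),
            terminal_event=np.array([r.terminal_event for r in records]),
            nonfatal_time=np.array([r.nonfatal_time for r in records]),
            nonfatal_event=np.array([r.nonfatal_event for r in records]),
            covariates=X,
            subject_ids=np.array([r.subject_id for r in records], dtype=object),
        )

    def to_records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(
                subject_id=self.subject_ids[k],
                arm=int(self.arm[k]),
                covariates=self.covariates[k].copy(),
                terminal_time=float(self.terminal_time[k]),
                terminal_event=int(self.terminal_event[k]),
                nonfatal_time=float(self.nonfatal_time[k]),
                nonfatal_event=int(self.nonfatal_event[k]),
            )
            for k in range(self.n)
        ]

    def subset(self, idx: np.ndarray) -> "TrialArrays":
        return TrialArrays(
            arm=self.arm[idx],
            terminal_time=self.terminal_time[idx],
            terminal_event=self.terminal_event[idx],
            nonfatal_time=self.nonfatal_time[idx],
            nonfatal_event=self.nonfatal_event[idx],
            covariates=self.covariates[idx],
            subject_ids=self.subject_ids[idx],
        )


@dataclass
class PairwiseScores:
    """Antisymmetric n x n score matrix.

    ``scores[i, j]`` is 1 if subject j beats subject i, 0 if i beats j and
    1/2 on a tie, so that ``scores[i, j] + scores[j, i] == 1`` off the
    diagonal.  The diagonal is set to 1/2 by convention but is excluded
    from every estimator sum.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.scores.shape[0]
        if self.scores.shape != (n, n):
            raise ValueError("scores must be a square matrix")

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def compare_hierarchical(a: SubjectRecord, b: SubjectRecord) -> int:
    """Two-layer death-then-nonfatal comparison of two composite outcomes.

    Layer 1 (death): the subject whose death occurs later — or who is known
    to still be at risk when the other dies — wins.  A death is decidable
    only against follow-up extending strictly beyond it, so a death after
    the other subject's censoring time falls through, as do equal death
    times.

    Layer 2 (nonfatal events), entered when layer 1 is undecided: over the
    shared window tau = min of the two terminal times, the subject whose
    first nonfatal event occurs later (or never, within tau) wins.  Equal
    event times tie.

    Returns +1 if ``b`` wins, -1 if ``a`` wins, 0 for a tie.
    """
    a.validate()
    b.validate()
    # layer 1: deaths
    if a.terminal_event == 1 and a.terminal_time < b.terminal_time:
        return 1
    if b.terminal_event == 1 and b.terminal_time < a.terminal_time:
        return -1
    # layer 2: nonfatal events on the shared follow-up window
    tau = min(a.terminal_time, b.terminal_time)
    a_has = a.nonfatal_event == 1 and a.nonfatal_time < tau
    b_has = b.nonfatal_event == 1 and b.nonfatal_time < tau
    if a_has and not (b_has and b.nonfatal_time <= a.nonfatal_time):
        return 1
    if b_has and not (a_has and a.nonfatal_time <= b.nonfatal_time):
        return -1
    return 0


def _hierarchical_scores(data: TrialArrays) -> np.ndarray:
    """Vectorized score matrix for the built-in hierarchical rule.

    Broadcasts the layer-1/layer-2 logic of :func:`compare_hierarchical`
    over all pairs at once; O(n^2) memory.
    """
    t1 = data.terminal_time
    d1 = data.terminal_event.astype(bool)
    t2 = data.nonfatal_time
    d2 = data.nonfatal_event.astype(bool)

    t1_i = t1[:, None]
    t1_j = t1[None, :]
    # layer 1: j wins against i iff i died while j was still under observation
    j_wins = d1[:, None] & (t1_i < t1_j)
    i_wins = d1[None, :] & (t1_j < t1_i)

    undecided = ~(j_wins | i_wins)
    tau = np.minimum(t1_i, t1_j)
    has_i = d2[:, None] & (t2[:, None] < tau)   # i's nonfatal inside shared window
    has_j = d2[None, :] & (t2[None, :] < tau)
    earlier_j = has_j & (t2[None, :] <= t2[:, None])
    earlier_i = has_i & (t2[:, None] <= t2[None, :])
    j_wins |= undecided & has_i & ~earlier_j
    i_wins |= undecided & has_j & ~earlier_i

    scores = np.full((data.n, data.n), 0.5)
    scores[j_wins] = 1.0
    scores[i_wins] = 0.0
    np.fill_diagonal(scores, 0.5)
    return scores


def score_matrix(
    records: Sequence[SubjectRecord] | TrialArrays,
    rule: ComparisonRule = compare_hierarchical,
) -> PairwiseScores:
    """Evaluate ``rule`` on every pair of subjects.

    For the built-in hierarchical rule the matrix is computed with
    vectorized numpy operations; any other rule is evaluated pairwise, in
    both orders, and a :class:`RuleConsistencyError` is raised if the rule
    is not antisymmetric or gives a nonzero self-comparison.
    """
    if isinstance(records, TrialArrays):
        data = records
        recs = None
    else:
        recs = list(records)
        if len(recs) < 2:
            raise ValueError("need at least two subjects")
        data = None

    if rule is compare_hierarchical:
        if data is None:
            data = TrialArrays.from_records(recs)
        return PairwiseScores(_hierarchical_scores(data))

    if recs is None:
        recs = records.to_records()
    n = len(recs)
    scores = np.full((n, n), 0.5)
    for i in range(n):
        if rule(recs[i], recs[i]) != 0:
            raise RuleConsistencyError(
                f"rule(a, a) != 0 for subject {recs[i].subject_id!r}"
            )
        for j in range(i + 1, n):
            v = rule(recs[i], recs[j])
            v_rev = rule(recs[j], recs[i])
            if v not in (-1, 0, 1):
                raise RuleConsistencyError(f"rule returned {v!r}, expected -1, 0, or +1")
            if v_rev != -v:
                raise RuleConsistencyError(
                    f"rule not antisymmetric on subjects "
                    f"({recs[i].subject_id!r}, {recs[j].subject_id!r}): "
                    f"{v} vs {v_rev}"
                )
            scores[i, j] = 0.5 * (1 + v)
            scores[j, i] = 0.5 * (1 - v)
    return PairwiseScores(scores)
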