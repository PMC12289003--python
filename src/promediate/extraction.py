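"""Parse transcripts back into the (X, Z, M, Y) analysis table.

The parser sees only transcript text plus trial-side metadata (subject ID and
arm); it never consults ground truth. Each severity value is the single
numeric token in the user turn that immediately follows the corresponding
router node; the fatigue branch is inferred from which stress node appears
and cross-checked against the yes/no answer text. The policy is fail-fast: a
malformed transcript aborts the cohort with its subject ID in the error,
because silently dropping subjects would bias any downstream analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dialogue as dlg
from .dialogue import Transcript
from .errors import (
    AmbiguousAnswerError,
    AnswerParseError,
    IncompleteTranscriptError,
    IntegrityError,
    TranscriptError,
)

__all__ = ["ExtractedRecord", "AnalysisTable", "parse_transcript", "extract_cohort"]

_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")


@dataclass(frozen=True)
class ExtractedRecord:
    """One parsed subject row; ``branch`` records the fatigue arm taken."""

    subject_id: str
    x: int
    y: float
    z: float
    m: float
    branch: str  # "yes" | "no"


@dataclass(frozen=True)
class AnalysisTable:
    """The parsed cohort, one row per subject, subject IDs unique."""

    rows: tuple[ExtractedRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate subject_id(s): {', '.join(dupes)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.rows],
                "x": np.array([r.x for r in self.rows], dtype=np.int64),
                "z": np.array([r.z for r in self.rows], dtype=float),
                "m": np.array([r.m for r in self.rows], dtype=float),
                "y": np.array([r.y for r in self.rows], dtype=float),
                "branch": [r.branch for r in self.rows],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnalysisTable":
        required = {"subject_id", "x", "z", "m", "y"}
        missing = sorted(required - set(frame.columns))
        if missing:
            raise IntegrityError(f"analysis table missing column(s): {', '.join(missing)}")
        has_branch = "branch" in frame.columns
        rows = tuple(
            ExtractedRecord(
                subject_id=str(r.subject_id), x=int(r.x), y=float(r.y),
                z=float(r.z), m=float(r.m),
                branch=str(r.branch) if has_branch else "",
            )
            for r in frame.itertuples(index=False)
        )
        return cls(rows=rows)

    @classmethod
    def from_ground_truth(
        cls, records: list[dlg.GroundTruthRecord], fatigue_threshold: float = 3.0
    ) -> "AnalysisTable":
        """Fast-path table straight from ground truth (no rendering round trip)."""
        rows = tuple(
            ExtractedRecord(
                subject_id=r.subject_id, x=r.x, y=r.y, z=r.z, m=r.m,
                branch="yes" if r.y >= fatigue_threshold else "no",
            )
            for r in records
        )
        return cls(rows=rows)


def _single_number(text: str, node_id: str, subject_id: str) -> float:
    tokens = _NUMBER_RE.findall(text)
    if len(tokens) == 0:
        raise AnswerParseError(
            f"subject {subject_id}: no numeric severity in answer to {node_id}: {text!r}"
        )
    if len(tokens) > 1:
        raise AmbiguousAnswerError(
            f"subject {subject_id}: {len(tokens)} numbers in answer to {node_id}: {text!r}"
        )
    return float(tokens[0])


def parse_transcript(transcript: Transcript) -> ExtractedRecord:
    """Extract (x, y, z, m, branch) from a single transcript.

    Raises :class:`IncompleteTranscriptError` (missing/duplicated router
    node, broken alternation), :class:`AmbiguousAnswerError` (several numeric
    tokens in a severity answer) or :class:`AnswerParseError` (none).
    """
    sid = transcript.subject_id
    turns = transcript.turns
    if not turns:
        raise IncompleteTranscriptError(f"subject {sid}: empty transcript")
    for i, turn in enumerate(turns):
        expected = "agent" if i % 2 == 0 else "user"
        if turn.role != expected:
            raise IncompleteTranscriptError(
                f"subject {sid}: turn {i} has role {turn.role!r}, expected {expected!r}"
            )

    # Answer to each agent node = the user turn right after it.
    answers: dict[str, list[str]] = {}
    for i in range(0, len(turns) - 1, 2):
        answers.setdefault(turns[i].node_id, []).append(turns[i + 1].text)

    values: dict[str, float] = {}
    for node_id, var in dlg.SEVERITY_NODES.items():
        got = answers.get(node_id, [])
        if len(got) == 0:
            raise IncompleteTranscriptError(
                f"subject {sid}: transcript is missing required node {node_id}"
            )
        if len(got) > 1:
            raise IncompleteTranscriptError(
                f"subject {sid}: node {node_id} appears {len(got)} times, expected once"
            )
        values[var] = _single_number(got[0], node_id, sid)

    has_cause = dlg.STRESS_FATIGUE_CAUSE in answers
    has_general = dlg.STRESS_GENERAL in answers
    if has_cause == has_general:
        raise IncompleteTranscriptError(
            f"subject {sid}: expected exactly one stress probe, "
            f"found cause={has_cause}, general={has_general}"
        )
    branch = "yes" if has_cause else "no"

    yn = answers.get(dlg.FATIGUE_YN)
    if yn is None:
        raise IncompleteTranscriptError(
            f"subject {sid}: transcript is missing required node {dlg.FATIGUE_YN}"
        )
    said_yes = yn[0].strip().lower().startswith("yes")
    if said_yes != (branch == "yes"):
        raise IncompleteTranscriptError(
            f"subject {sid}: fatigue answer {yn[0]!r} inconsistent with {branch!r} branch"
        )

    return ExtractedRecord(
        subject_id=sid, x=int(transcript.arm),
        y=values["y"], z=values["z"], m=values["m"], branch=branch,
    )


def extract_cohort(transcripts: list[Transcript]) -> AnalysisTable:
    """Parse a whole cohort, order preserved, failing fast on the first bad one."""
    if not transcripts:
        raise IntegrityError("cannot extract an empty list of transcripts")
    rows = []
    for t in transcripts:
        try:
            rows.append(parse_transcript(t))
        except TranscriptError:
            raise  # already carries the subject_id
    return AnalysisTable(rows=tuple(rows))
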