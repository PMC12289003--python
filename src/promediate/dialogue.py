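"""Synthetic patient-chatbot dialogues from a known mediation process.

A cohort is simulated in two stages. First, per-subject ground truth is drawn
from the linear-Gaussian mediation model: treatment X by 1:1 randomization,
stress Z ~ Normal(z_mean, z_sd^2), mediator M = i_m + a*X + eps_m, outcome
Y = i_y + c'*X + d*Z + b*M + eps_y. Nothing is clipped or rounded, so the
regression equations stay exactly linear-Gaussian.

Second, each record is rendered as a multi-turn transcript that follows the
chatbot's branching router: greeting, a yes/no fatigue probe ("Yes" iff
Y >= fatigue_threshold), a branch-specific stress question, and a side-effect
question. Both branches additionally elicit numeric zero-anchored severities
for fatigue, stress and side effects, embedding Y, Z and M rounded to
``render_precision`` decimals — the only information loss in the pipeline.
Surface wording is drawn deterministically from a small template bank per
router node, standing in for free-form LLM role-play: downstream stages
consume the numbers, not the prose.

Seed discipline: arm allocation uses SeedSequence(seed, spawn_key=(0,)); the
subject at position ``i`` uses SeedSequence(seed, spawn_key=(1, i)), so
enlarging a cohort never perturbs earlier subjects. Template choice hashes
(seed, subject_id, node_id) and consumes no RNG stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .params import CohortConfig

__all__ = [
    "GroundTruthRecord",
    "TranscriptTurn",
    "Transcript",
    "randomize_cohort",
    "simulate_ground_truth",
    "render_transcript",
    "simulate_cohort",
    "SEVERITY_NODES",
    "YES_PATH",
    "NO_PATH",
]


@dataclass(frozen=True)
class GroundTruthRecord:
    """True latent values for one subject: the reference for everything downstream."""

    subject_id: str
    x: int  # treatment indicator, 0 = placebo, 1 = active
    z: float  # stress severity
    m: float  # adverse-event severity (mediator)
    y: float  # fatigue severity (outcome)

    def __post_init__(self) -> None:
        if self.x not in (0, 1):
            raise ConfigError(f"x must be 0 or 1, got {self.x!r}")
        if not all(np.isfinite([self.z, self.m, self.y])):
            raise ConfigError(f"non-finite value in record {self.subject_id}")


@dataclass(frozen=True)
class TranscriptTurn:
    role: str  # "agent" | "user"
    node_id: str
    text: str


@dataclass(frozen=True)
class Transcript:
    """An ordered agent/user dialogue plus trial-side metadata.

    The treatment arm is metadata known to the trial system, never uttered.
    """

    subject_id: str
    arm: int
    turns: tuple[TranscriptTurn, ...]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "arm": self.arm,
            "turns": [
                {"role": t.role, "node_id": t.node_id, "text": t.text}
                for t in self.turns
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transcript":
        return cls(
            subject_id=d["subject_id"],
            arm=int(d["arm"]),
            turns=tuple(
                TranscriptTurn(role=t["role"], node_id=t["node_id"], text=t["text"])
                for t in d["turns"]
            ),
        )


# --------------------------------------------------------------------------
# Router definition
# --------------------------------------------------------------------------

GREETING = "GREETING"
FATIGUE_YN = "FATIGUE_YN"
FATIGUE_SEVERITY = "FATIGUE_SEVERITY"
STRESS_FATIGUE_CAUSE = "STRESS_FATIGUE_CAUSE"  # "Yes" branch stress probe
STRESS_GENERAL = "STRESS_GENERAL"  # "No" branch stress probe
STRESS_SEVERITY = "STRESS_SEVERITY"
SIDE_EFFECTS = "SIDE_EFFECTS"
SIDE_EFFECT_SEVERITY = "SIDE_EFFECT_SEVERITY"
CLOSING = "CLOSING"

#: Maps each numeric-elicitation node to the ground-truth field it captures.
SEVERITY_NODES = {
    FATIGUE_SEVERITY: "y",
    STRESS_SEVERITY: "z",
    SIDE_EFFECT_SEVERITY: "m",
}

#: Agent node order when the subject reports fatigue: the fatigue follow-ups
#: come first, then the stress-as-cause probe, then side effects.
YES_PATH = (
    GREETING,
    FATIGUE_YN,
    FATIGUE_SEVERITY,
    STRESS_FATIGUE_CAUSE,
    STRESS_SEVERITY,
    SIDE_EFFECTS,
    SIDE_EFFECT_SEVERITY,
    CLOSING,
)

#: Agent node order when fatigue is denied: stress precedes side effects, and
#: the (mild) fatigue severity is still elicited at the end so every subject
#: contributes a complete (Y, Z, M) triple.
NO_PATH = (
    GREETING,
    FATIGUE_YN,
    STRESS_GENERAL,
    STRESS_SEVERITY,
    SIDE_EFFECTS,
    SIDE_EFFECT_SEVERITY,
    FATIGUE_SEVERITY,
    CLOSING,
)

# Agent prompt bank: >= 3 surface variants per node. Severity prompts anchor
# the scale at zero in words only — user answers must carry the sole numeral.
_AGENT_TEMPLATES: dict[str, list[str]] = {
    GREETING: [
        "Hello! How are you feeling today?",
        "Hi there, thanks for checking in. How have you been feeling?",
        "Good day! Could you tell me how you are doing today?",
    ],
    FATIGUE_YN: [
        "Have you experienced any fatigue recently?",
        "Have you been feeling unusually tired or fatigued?",
        "Would you say you have had fatigue since your last visit?",
    ],
    FATIGUE_SEVERITY: [
        "On a scale from zero to ten, how severe is your fatigue right now?",
        "Please rate your fatigue on a zero-to-ten scale, where zero means none at all.",
        "How would you score your fatigue, from zero (none) up to ten (worst imaginable)?",
    ],
    STRESS_FATIGUE_CAUSE: [
        "Could social or cultural pressures be contributing to your fatigue?",
        "Do you think stress at home or in your community might explain some of this fatigue?",
        "Are there social or cultural sources of stress that could be behind the tiredness?",
    ],
    STRESS_GENERAL: [
        "Have you been under any social or cultural stress lately?",
        "How about stress — anything at home, work or in your community weighing on you?",
        "Are you experiencing stress from social or cultural circumstances at the moment?",
    ],
    STRESS_SEVERITY: [
        "On a zero-to-ten scale, how severe is that stress?",
        "Please rate your stress from zero (none) to ten (overwhelming).",
        "How would you score your stress level, zero to ten?",
    ],
    SIDE_EFFECTS: [
        "Have you noticed any side effects of the treatment?",
        "Has the treatment caused any adverse effects you are aware of?",
        "Do you think you have had any side effects from the study medication?",
    ],
    SIDE_EFFECT_SEVERITY: [
        "On a zero-to-ten scale, how severe are those side effects?",
        "Please rate the severity of any side effects from zero to ten.",
        "How would you score the side effects overall, zero (none) to ten (severe)?",
    ],
    CLOSING: [
        "Thank you for sharing. Your care team will review this. Take care!",
        "Thanks, that is everything I needed today. Be well!",
        "That completes today's check-in. Thank you, and take care of yourself!",
    ],
}

# User reply bank. Severity answers carry exactly one numeral ({v}); every
# other reply is digit-free so the one-number invariant holds per answer turn.
_USER_SEVERITY_TEMPLATES = [
    "On that scale I would put it at {v}.",
    "I'd say about {v} right now.",
    "Probably around {v}, to be honest.",
]

_USER_TEMPLATES: dict[str, list[str]] = {
    GREETING: [
        "Hello, doing my best today.",
        "Hi, I'm hanging in there.",
        "Hello! A bit of a mixed day, honestly.",
    ],
    "FATIGUE_YES": [
        "Yes, I have been feeling quite a lot of fatigue.",
        "Yes, the fatigue has been noticeable lately.",
        "Yes — I've felt fatigued most days this week.",
    ],
    "FATIGUE_NO": [
        "No, no real fatigue to speak of.",
        "No, I haven't felt fatigued lately.",
        "No — my energy has been fine, no fatigue.",
    ],
    STRESS_FATIGUE_CAUSE: [
        "Yes, there has been a lot of domestic stress at home lately.",
        "Possibly — family stress has been weighing on me.",
        "I think so; there's been stress with relatives and money at home.",
    ],
    STRESS_GENERAL: [
        "There is some stress at home, yes.",
        "A little stress from family matters, nothing dramatic.",
        "Some social stress, mostly around home life.",
    ],
    "SIDE_EFFECTS_PRESENT": [
        "Yes, I believe I've had an adverse event — some nausea since the last dose.",
        "I think so: an adverse event, mostly stomach upset after taking it.",
        "Yes, there's been an adverse event — headaches that started with the treatment.",
    ],
    "SIDE_EFFECTS_ABSENT": [
        "Nothing I would call an adverse event, no.",
        "No side effects that I've noticed.",
        "Not really — no adverse event so far.",
    ],
    CLOSING: [
        "Thanks, goodbye!",
        "Thank you, talk soon.",
        "Thanks for checking in on me.",
    ],
}


def _pick(bank: list[str], seed: int, subject_id: str, node_id: str) -> str:
    """Deterministic template choice keyed by (seed, subject, node)."""
    key = f"{seed}:{subject_id}:{node_id}".encode()
    return bank[zlib.crc32(key) % len(bank)]


# --------------------------------------------------------------------------
# Ground-truth simulation
# --------------------------------------------------------------------------

def randomize_cohort(n_subjects: int, seed: int) -> np.ndarray:
    """1:1 randomization: a permuted vector of ceil(n/2) ones, floor(n/2) zeros.

    The active arm receives the extra subject when n is odd. Deterministic
    given the seed.
    """
    if n_subjects < 4:
        raise ConfigError(
            f"n_subjects must be >= 4 for a two-arm cohort, got {n_subjects}"
        )
    n_active = (n_subjects + 1) // 2
    x = np.zeros(n_subjects, dtype=np.int64)
    x[:n_active] = 1
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    rng.shuffle(x)
    return x


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, index)))


def simulate_ground_truth(config: CohortConfig) -> list[GroundTruthRecord]:
    """Draw one cohort of (X, Z, M, Y) records from the mediation model."""
    p = config.params
    x = randomize_cohort(config.n_subjects, config.seed)
    records = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        z = config.z_mean + config.z_sd * rng.standard_normal()
        m = p.i_m + p.a * x[i] + p.sigma_m * rng.standard_normal()
        y = p.i_y + p.c_prime * x[i] + p.d * z + p.b * m + p.sigma_y * rng.standard_normal()
        records.append(
            GroundTruthRecord(
                subject_id=f"S{i + 1:04d}", x=int(x[i]), z=float(z),
                m=float(m), y=float(y),
            )
        )
    return records


# --------------------------------------------------------------------------
# Transcript rendering
# --------------------------------------------------------------------------

def render_transcript(record: GroundTruthRecord, config: CohortConfig) -> Transcript:
    """Render one record as a router-conformant transcript.

    Pure function of (record, config): the fatigue branch is "Yes" iff
    record.y >= config.fatigue_threshold; severities are embedded rounded to
    config.render_precision decimals.
    """
    fatigued = record.y >= config.fatigue_threshold
    path = YES_PATH if fatigued else NO_PATH
    prec = config.render_precision
    seed = config.seed
    sid = record.subject_id

    def fmt(value: float) -> str:
        return f"{value:.{prec}f}"

    turns: list[TranscriptTurn] = []
    for node in path:
        agent_text = _pick(_AGENT_TEMPLATES[node], seed, sid, node)
        turns.append(TranscriptTurn(role="agent", node_id=node, text=agent_text))
        if node == FATIGUE_YN:
            bank = _USER_TEMPLATES["FATIGUE_YES" if fatigued else "FATIGUE_NO"]
            user_text = _pick(bank, seed, sid, node)
        elif node == SIDE_EFFECTS:
            bank = _USER_TEMPLATES[
                "SIDE_EFFECTS_PRESENT" if record.m > 0 else "SIDE_EFFECTS_ABSENT"
            ]
            user_text = _pick(bank, seed, sid, node)
        elif node in SEVERITY_NODES:
            value = getattr(record, SEVERITY_NODES[node])
            template = _pick(_USER_SEVERITY_TEMPLATES, seed, sid, node)
            user_text = template.format(v=fmt(value))
        else:
            user_text = _pick(_USER_TEMPLATES[node], seed, sid, node)
        turns.append(TranscriptTurn(role="user", node_id=node, text=user_text))
    return Transcript(subject_id=sid, arm=record.x, turns=tuple(turns))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[Transcript], list[GroundTruthRecord]]:
    """Simulate ground truth and render every subject's transcript.

    Returns index-aligned (transcripts, records); deterministic given config.
    """
    records = simulate_ground_truth(config)
    transcripts = [render_transcript(r, config) for r in records]
    return transcripts, records


def iter_agent_nodes(transcript: Transcript) -> Iterator[str]:
    """Node IDs of the agent turns, in order (the path taken through the router)."""
    for t in transcript.turns:
        if t.role == "agent":
            yield t.node_id
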