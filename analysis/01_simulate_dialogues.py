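#!/usr/bin/env python
"""Simulate one trial cohort of patient-chatbot dialogues.

Draws 75 subjects (randomized 1:1) from the default mediation process, renders
each as a multi-turn transcript following the chatbot router, and writes the
transcript JSONL plus the ground-truth table under results/cohort/.
"""

from pathlib import Path

from promediate import StudyConfig, simulate_cohort
from promediate.io import write_ground_truth, write_manifest, write_transcripts

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = StudyConfig()
    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    transcripts, records = simulate_cohort(config.cohort)
    paths = [
        write_transcripts(transcripts, out / "transcripts.jsonl"),
        write_ground_truth(records, out / "ground_truth.csv"),
    ]
    write_manifest(out, config, paths)

    n_active = sum(r.x for r in records)
    n_fatigued = sum(t.turns[4].node_id == "FATIGUE_SEVERITY" for t in transcripts)
    print(f"simulated {len(records)} subjects: {n_active} active, "
          f"{len(records) - n_active} placebo; {n_fatigued} took the fatigue branch")
    print(f"wrote {paths[0].name} and {paths[1].name} to {out}\n")
    print("example dialogue (first subject):")
    for turn in transcripts[0].turns:
        print(f"  [{turn.role:5s}] {turn.text}")


if __name__ == "__main__":
    main()
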