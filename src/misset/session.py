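"""Append-only session log: the provenance trail of an analysis.

Each operation appends one JSON line to ``session.jsonl`` in its output
directory.  Steps form a tree via ``parent_step``: branching from an
earlier step plays the role of opening a new analysis tab, discarding a
branch that of closing one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class SessionStep:
    step_id: int
    operation: str
    parameters: dict
    parent_step: int | None = None


def log_session_step(
    out_dir: str | Path,
    operation: str,
    parameters: dict,
    parent_step: int | None = None,
) -> int:
    """Append a step to ``out_dir/session.jsonl``; returns its step id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = out_dir / "session.jsonl"
    step_id = 1
    if log.exists():
        step_id = sum(1 for _ in log.open(encoding="utf-8")) + 1
    step = SessionStep(step_id=step_id, operation=operation,
                       parameters=parameters, parent_step=parent_step)
    with log.open("a", encoding="utf-8") as fh:
        fh.write(json.dumps({
            "step_id": step.step_id,
            "operation": step.operation,
            "parameters": step.parameters,
            "parent_step": step.parent_step,
        }) + "\n")
    return step_id
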