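"""Training engine: stimulus scheduling and feedback-driven relocation.

Stimuli are shown for ``display_ms`` in a uniformly re-shuffled cycle on a
dark background; after each presentation the user has ``response_window_ms``
to click, followed by a uniformly random extra break of up to
``extra_break_max_ms``.  A detected stimulus is moved ``step_deg`` toward the
reference point inside the defect; a missed stimulus is moved ``step_deg``
straight away from the reference point (toward the intact side), so the
stimulus positions track the intact/defect border over the session.
"""

from __future__ import annotations

import hashlib
import json
import uuid
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .geometry import AngularPosition, angular_distance
from .session_io import SessionLog

__all__ = [
    "TrainingConfig",
    "StimulusState",
    "ScheduledEvent",
    "Responder",
    "schedule_session",
    "relocate",
    "run_training_session",
]

# detected-flag callable: (position, category, size_deg) -> clicked
Responder = Callable[..., bool]


class TrainingConfig(BaseModel):
    """Parameters of one training session."""

    stimulus_size_deg: float = Field(default=3.0, gt=0)
    stimulus_luminance_nominal: float = 1000.0  # cd/m^2, metadata only
    display_ms: float = Field(default=750.0, gt=0)
    response_window_ms: float = Field(default=2000.0, gt=0)
    extra_break_max_ms: float = Field(default=1500.0, ge=0)
    fixation_color_change_min_ms: float = Field(default=3000.0, gt=0)
    fixation_color_change_max_ms: float = Field(default=7000.0, gt=0)
    step_deg: float = Field(default=0.5, gt=0)
    reference_point: AngularPosition = AngularPosition(20.0, 0.0)
    intact_anchor: AngularPosition = AngularPosition(0.0, 0.0)
    session_duration_s: float = Field(default=300.0, ge=0)
    persistence_mode: Literal["cumulative", "reset"] = "cumulative"
    checkpoint_interval_s: float = Field(default=60.0, gt=0)
    fov_deg: float = Field(default=90.0, gt=0)
    seed: int = 0

    @field_validator("reference_point", "intact_anchor", mode="before")
    @classmethod
    def _coerce_position(cls, v):
        if isinstance(v, (list, tuple)) and len(v) == 2:
            return AngularPosition(float(v[0]), float(v[1]))
        return v

    @model_validator(mode="after")
    def _check_fixation_bounds(self) -> "TrainingConfig":
        if self.fixation_color_change_max_ms < self.fixation_color_change_min_ms:
            raise ValueError("fixation colour-change max must be >= min")
        return self

    def digest(self) -> str:
        """Checksum guarding against silent parameter drift between sessions."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class StimulusState:
    """One training stimulus with its relocation history."""

    id: str
    initial: AngularPosition
    history: list[tuple[int, AngularPosition, bool]] = field(default_factory=list)

    @property
    def current(self) -> AngularPosition:
        return self.history[-1][1] if self.history else self.initial

    def reset(self) -> "StimulusState":
        return StimulusState(id=self.id, initial=self.initial)


@dataclass(frozen=True)
class ScheduledEvent:
    onset_ms: float
    kind: Literal["stimulus", "fixation_color_change"]
    stimulus_id: Optional[str] = None


def schedule_session(
    config: TrainingConfig, stimuli: Sequence[StimulusState]
) -> list[ScheduledEvent]:
    """Presentation plan for one session; deterministic for a fixed seed.

    Stimuli cycle in uniformly shuffled order; consecutive onsets are
    separated by display + response window + U(0, extra break).  Fixation
    colour changes are interleaved at U(min, max) intervals.  The schedule is
    truncated at ``session_duration_s``.
    """
    if not stimuli:
        raise ValueError("at least one stimulus is required")
    rng = np.random.default_rng(config.seed)
    duration_ms = config.session_duration_s * 1000.0
    ids = [s.id for s in stimuli]

    events: list[ScheduledEvent] = []
    t = 0.0
    done = False
    while not done:
        order = rng.permutation(len(ids))
        for k in order:
            if t + config.display_ms > duration_ms:
                done = True
                break
            events.append(ScheduledEvent(t, "stimulus", ids[int(k)]))
            t += (
                config.display_ms
                + config.response_window_ms
                + float(rng.uniform(0.0, config.extra_break_max_ms))
            )
    tf = float(
        rng.uniform(config.fixation_color_change_min_ms, config.fixation_color_change_max_ms)
    )
    while tf < duration_ms:
        events.append(ScheduledEvent(tf, "fixation_color_change"))
        tf += float(
            rng.uniform(config.fixation_color_change_min_ms, config.fixation_color_change_max_ms)
        )
    events.sort(key=lambda e: (e.onset_ms, e.kind))
    return events


def _clamp_to_fov(p: AngularPosition, fov_deg: float) -> AngularPosition:
    half = fov_deg / 2.0
    r = p.eccentricity
    if r <= half:
        return p
    return AngularPosition(p.x_deg * half / r, p.y_deg * half / r)


def relocate(stim: StimulusState, detected: bool, config: TrainingConfig) -> StimulusState:
    """Move a stimulus one step after feedback, appending to its history.

    Detected: step toward the reference point, landing exactly on it when
    closer than one step.  Missed: step along the ray from the reference
    point through the stimulus, i.e. straight away from the defect centre,
    radially clamped to the field of view.  A missed stimulus sitting exactly
    on the reference point steps toward the intact anchor instead (the
    away-direction is undefined there).
    """
    cur = stim.current
    ref = config.reference_point
    d = angular_distance(cur, ref)
    step = config.step_deg
    if detected:
        if d <= step:
            new = ref
        else:
            f = step / d
            new = AngularPosition(
                cur.x_deg + f * (ref.x_deg - cur.x_deg),
                cur.y_deg + f * (ref.y_deg - cur.y_deg),
            )
    else:
        if d == 0.0:
            anchor = config.intact_anchor
            da = angular_distance(cur, anchor)
            if da == 0.0:
                raise ValueError("stimulus, reference point and intact anchor coincide")
            f = step / da
            new = AngularPosition(
                cur.x_deg + f * (anchor.x_deg - cur.x_deg),
                cur.y_deg + f * (anchor.y_deg - cur.y_deg),
            )
        else:
            f = step / d
            new = AngularPosition(
                cur.x_deg + f * (cur.x_deg - ref.x_deg),
                cur.y_deg + f * (cur.y_deg - ref.y_deg),
            )
        new = _clamp_to_fov(new, config.fov_deg)
    out = replace(stim, history=list(stim.history))
    out.history.append((len(stim.history), new, detected))
    return out


def run_training_session(
    config: TrainingConfig,
    responder: Responder,
    stimuli: Sequence[StimulusState],
) -> tuple[list[StimulusState], SessionLog]:
    """Run one session: present per schedule, relocate per response, log.

    In ``reset`` persistence mode the returned stimuli carry their initial
    coordinates (progress is documented in the log, but moved coordinates
    are discarded); ``cumulative`` mode returns the moved stimuli.  If the
    responder raises, the partial log is returned with
    ``terminated_normally=False``.
    """
    states = {s.id: replace(s, history=list(s.history)) for s in stimuli}
    order = [s.id for s in stimuli]
    schedule = schedule_session(config, stimuli)

    log = SessionLog(
        session_id=uuid.uuid4().hex,
        started_at=datetime.now(timezone.utc).isoformat(),
        runtime_s=config.session_duration_s,
        click_count=0,
        checkpoints=[],
        final_coordinates={},
        seed=config.seed,
        config_digest=config.digest(),
    )

    def snapshot() -> dict[str, tuple[float, float]]:
        return {sid: states[sid].current.as_tuple() for sid in order}

    next_checkpoint = config.checkpoint_interval_s
    normal = True
    for ev in schedule:
        while ev.onset_ms / 1000.0 >= next_checkpoint:
            log.checkpoints.append((next_checkpoint, snapshot()))
            next_checkpoint += config.checkpoint_interval_s
        if ev.kind != "stimulus":
            continue
        stim = states[ev.stimulus_id]
        try:
            detected = bool(
                responder(stim.current, category="training", size_deg=config.stimulus_size_deg)
            )
        except Exception:
            normal = False
            break
        if detected:
            log.click_count += 1
        states[ev.stimulus_id] = relocate(stim, detected, config)

    log.checkpoints.append((config.session_duration_s, snapshot()))
    log.final_coordinates = snapshot()
    log.terminated_normally = normal

    updated = [states[sid] for sid in order]
    if config.persistence_mode == "reset":
        updated = [s.reset() for s in updated]
    return updated, log
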