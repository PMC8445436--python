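"""Simulated observers that answer stimulus presentations.

Two styles:

* :class:`SimulatedObserver` — stochastic ground-truth observer.  The
  stimulus centre is perturbed by isotropic Gaussian fixation jitter; if the
  jittered centre lands on an INTACT cell the observer clicks with
  probability ``1 - lapse_rate``, otherwise with probability ``guess_rate``.
* :class:`QuotaResponder` — deterministic per-category quota responder that
  reproduces a subject's exact integer confusion counts from published
  sensitivity/specificity fractions.

All responders share the call signature
``responder(position, category=None, size_deg=None) -> bool``.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

from .geometry import AngularPosition
from .visual_field import FieldStatus, VisualFieldMap, classify_point

__all__ = [
    "ObserverParams",
    "SimulatedObserver",
    "respond",
    "QuotaResponder",
    "Table1Responder",
    "make_table1_responder",
]


class ObserverParams(BaseModel):
    """Noise model of a simulated participant."""

    fixation_jitter_sd_deg: float = Field(default=0.0, ge=0)
    lapse_rate: float = Field(default=0.0, ge=0, le=1)
    guess_rate: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0


class SimulatedObserver:
    """Stochastic observer backed by a ground-truth visual-field map.

    With all noise parameters at zero the observer is a deterministic
    function of field status: click iff the stimulus centre is INTACT.
    Detection uses the (jittered) stimulus centre only; ``size_deg`` is
    accepted for interface compatibility but does not enter the decision.
    """

    def __init__(self, params: ObserverParams, field: VisualFieldMap):
        self.params = params
        self.field = field
        self.rng = np.random.default_rng(params.seed)

    def __call__(
        self,
        position: AngularPosition,
        category: Optional[str] = None,
        size_deg: Optional[float] = None,
    ) -> bool:
        p = self.params
        eff = position
        if p.fixation_jitter_sd_deg > 0:
            dx, dy = self.rng.normal(0.0, p.fixation_jitter_sd_deg, size=2)
            eff = AngularPosition(position.x_deg + dx, position.y_deg + dy)
        if classify_point(self.field, eff) is FieldStatus.INTACT:
            if p.lapse_rate == 0.0:
                return True
            return bool(self.rng.random() >= p.lapse_rate)
        if p.guess_rate == 0.0:
            return False
        return bool(self.rng.random() < p.guess_rate)


def respond(
    params: ObserverParams, field: VisualFieldMap, stimulus_position: AngularPosition
) -> bool:
    """One-shot convenience wrapper around :class:`SimulatedObserver`."""
    return SimulatedObserver(params, field)(stimulus_position)


class QuotaResponder:
    """Deterministic responder replaying a subject's published hit fractions.

    Blind-spot-category presentations are clicked exactly
    ``n_blindspot - round(n_blindspot * sen)`` times; detectable-category
    presentations exactly ``round(n_detectable * spe)`` times, with clicks
    spread evenly over each category's presentation order.  Presentations in
    other categories (warm-up/buffer/training) are answered by field truth
    when a field is supplied, else always clicked.
    """

    def __init__(
        self,
        sen: float,
        spe: float,
        n_blindspot: int = 15,
        n_detectable: int = 85,
        field: Optional[VisualFieldMap] = None,
    ):
        if not (0.0 <= sen <= 1.0 and 0.0 <= spe <= 1.0):
            raise ValueError("sen and spe must lie in [0, 1]")
        self.sen = sen
        self.spe = spe
        self.field = field
        self._quota = {
            "blindspot": (n_blindspot - _round_half_up_int(n_blindspot * sen), n_blindspot),
            "detectable": (_round_half_up_int(n_detectable * spe), n_detectable),
        }
        self._seen = {"blindspot": 0, "detectable": 0}
        self._clicked = {"blindspot": 0, "detectable": 0}

    def __call__(
        self,
        position: AngularPosition,
        category: Optional[str] = None,
        size_deg: Optional[float] = None,
    ) -> bool:
        if category not in self._quota:
            if self.field is not None:
                return classify_point(self.field, position) is FieldStatus.INTACT
            return True
        clicks, total = self._quota[category]
        i = self._seen[category]
        self._seen[category] += 1
        # even spreading: click when the running quota crosses an integer
        want = int(((i + 1) * clicks) // total) if total else 0
        if self._clicked[category] < want:
            self._clicked[category] += 1
            return True
        return False


class Table1Responder(QuotaResponder):
    """Alias kept for the published-cohort replay interface."""


def make_table1_responder(
    sen: float,
    spe: float,
    mode: Literal["quota", "stochastic"] = "quota",
    n_blindspot: int = 15,
    n_detectable: int = 85,
    seed: int = 0,
):
    """Responder with fixed per-category miss/guess behaviour.

    ``quota`` (default) reproduces the implied integer counts exactly;
    ``stochastic`` draws an independent Bernoulli per presentation with
    click probability ``1 - sen`` for blind-spot stimuli and ``spe`` for
    detectable stimuli.
    """
    if mode == "quota":
        return QuotaResponder(sen, spe, n_blindspot=n_blindspot, n_detectable=n_detectable)
    if mode != "stochastic":
        raise ValueError(f"unknown responder mode {mode!r}")
    rng = np.random.default_rng(seed)

    def _respond(position, category=None, size_deg=None) -> bool:
        if category == "blindspot":
            return bool(rng.random() < 1.0 - sen)
        return bool(rng.random() < spe)

    return _respond


def _round_half_up_int(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))
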