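"""BCI-to-game command mapping and a configurable 16-section race simulator.

The race track has 16 sections, four of each type (left, right, headlight,
noinput).  Both-hands commands map to "left" and both-feet to "right"; the
third active command, "headlight", is produced sequentially: a delivered
BCI command of the *opposite* type arriving within a configurable window
(2 s) of the previous delivered game command is emitted as headlight
instead.  Silence is the "noinput" state.

The avatar advances at a base speed, accelerates for the rest of a section
after its correct command, and is slowed to a penalty speed for a fixed
interval after a wrong command (any command counts as wrong in a noinput
section).  The true game kinematics are unpublished; the defaults here are
package choices that preserve the orderings correct < none < wrong per
section and put a perfect pilot near 110 s and a silent pilot at the 240 s
cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CLASSES

__all__ = ["SECTION_TYPES", "RaceTrack", "Kinematics", "RaceResult",
           "map_to_game", "generate_track", "simulate_race"]

SECTION_TYPES = ("right", "headlight", "left", "noinput")
N_SECTIONS = 16

#: BCI class -> game command
COMMAND_MAP = {"both_hands": "left", "both_feet": "right"}


@dataclass(frozen=True)
class RaceTrack:
    sections: tuple[str, ...]
    section_length: float = 10.0

    def __post_init__(self) -> None:
        if len(self.sections) != N_SECTIONS:
            raise ValueError(f"track must have {N_SECTIONS} sections")
        for t in SECTION_TYPES:
            if self.sections.count(t) != N_SECTIONS // 4:
                raise ValueError("each section type must appear exactly 4 times")


@dataclass(frozen=True)
class Kinematics:
    v_base: float = 0.6          # units/s while coasting
    v_boost: float = 2.75        # after the correct command, rest of section
    v_penalty: float = 0.25      # during a penalty interval
    penalty_s: float = 2.0       # duration of the slow-down after a mistake
    reaction_s: float = 0.5      # pilot latency at a section entry (policy mode)
    time_cap: float = 240.0      # maximum allowed race time

    def __post_init__(self) -> None:
        if min(self.v_base, self.v_boost, self.v_penalty) <= 0:
            raise ValueError("speeds must be positive")


@dataclass
class RaceResult:
    completion_time: float
    completed: bool
    section_times: np.ndarray          # seconds spent per section (0 if unreached)
    command_log: list[tuple[float, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert abs(self.section_times.sum() - self.completion_time) < 1e-9


def map_to_game(commands: list[tuple[float, str]],
                headlight_window: float = 2.0) -> list[tuple[float, str]]:
    """Translate timestamped BCI commands into game commands.

    bh -> left, bf -> right; an opposite-type BCI command within
    ``headlight_window`` of the previously delivered game command becomes
    "headlight".  A headlight is therefore never first, and after one the
    sequence restarts from the BCI command that triggered it.
    """
    out: list[tuple[float, str]] = []
    prev_class: str | None = None
    prev_t = -np.inf
    for t, klass in commands:
        if klass not in COMMAND_MAP:
            raise ValueError(f"unknown BCI command {klass!r}")
        if t < prev_t:
            raise ValueError("timestamps must be non-decreasing")
        if (prev_class is not None and klass != prev_class
                and t - prev_t <= headlight_window):
            out.append((t, "headlight"))
        else:
            out.append((t, COMMAND_MAP[klass]))
        prev_class, prev_t = klass, t
    return out


def generate_track(seed: int, section_length: float = 10.0) -> RaceTrack:
    """Seeded uniform permutation of the 4+4+4+4 section multiset."""
    rng = np.random.default_rng(seed)
    sections = np.repeat(np.array(SECTION_TYPES, dtype=object), N_SECTIONS // 4)
    rng.shuffle(sections)
    return RaceTrack(tuple(sections), section_length)


def _section_time(kin: Kinematics, length: float, outcome: str,
                  delay: float) -> float:
    """Closed-form crossing time for one section.

    ``outcome``: 'correct' (boost after ``delay`` at base speed), 'none'
    (coast through), or 'wrong' (penalty interval after ``delay``, then
    base speed).  In noinput sections 'correct' means staying silent, i.e.
    coasting.
    """
    if outcome == "none":
        return length / kin.v_base
    d0 = min(delay, length / kin.v_base)
    covered = d0 * kin.v_base
    rest = length - covered
    if rest <= 0:
        return length / kin.v_base
    if outcome == "correct":
        return d0 + rest / kin.v_boost
    # wrong: penalty interval, then coast
    pen_t = min(kin.penalty_s, rest / kin.v_penalty)
    covered_pen = pen_t * kin.v_penalty
    rest2 = rest - covered_pen
    return d0 + pen_t + max(rest2, 0.0) / kin.v_base


def simulate_race(track: RaceTrack, kin: Kinematics | None = None, *,
                  accuracy: float | None = None, seed: int = 0,
                  game_commands: list[tuple[float, str]] | None = None
                  ) -> RaceResult:
    """Run one race, either from an accuracy-parameterized pilot policy or
    from an explicit timestamped game-command stream.

    Policy mode: at each section entry the pilot issues the correct command
    (probability ``accuracy``) after the reaction latency, otherwise a wrong
    one; in noinput sections "correct" is staying silent.  The per-section
    random draws are indexed by (seed, section), so race time is monotone
    non-increasing in accuracy at a fixed seed.

    Command mode walks the stream against the track: the correct active
    command boosts the rest of the section; a wrong command, or any command
    inside a noinput section, triggers a penalty interval.

    Time is capped at ``kin.time_cap``; a capped run is marked incomplete.
    """
    kin = kin or Kinematics()
    t = 0.0
    section_times = np.zeros(N_SECTIONS)
    log: list[tuple[float, str, bool]] = []
    if (accuracy is None) == (game_commands is None):
        raise ValueError("provide exactly one of accuracy or game_commands")

    for i, sec in enumerate(track.sections):
        if accuracy is not None:
            u = np.random.default_rng((int(seed), i)).random()
            good = u < accuracy
            if sec == "noinput":
                outcome = "none" if good else "wrong"
                if not good:
                    log.append((t + kin.reaction_s, "left", False))
            else:
                outcome = "correct" if good else "wrong"
                issued = sec if good else ("left" if sec != "left" else "right")
                log.append((t + kin.reaction_s, issued, good))
            dt = _section_time(kin, track.section_length, outcome,
                               kin.reaction_s if outcome != "none" else 0.0)
        else:
            dt = _command_mode_section(track, kin, i, t, game_commands, log)
        if t + dt >= kin.time_cap:
            section_times[i] = kin.time_cap - t
            return RaceResult(kin.time_cap, False, section_times, log)
        section_times[i] = dt
        t += dt
    return RaceResult(t, True, section_times, log)


def _command_mode_section(track: RaceTrack, kin: Kinematics, i: int,
                          t_start: float,
                          commands: list[tuple[float, str]],
                          log: list[tuple[float, str, bool]]) -> float:
    """Crossing time of section i given the global command stream."""
    sec = track.sections[i]
    # first command falling inside this section (simulated entry-time window)
    dt_none = track.section_length / kin.v_base
    for tc, cmd in commands:
        if tc < t_start or tc >= t_start + dt_none:
            continue
        delay = tc - t_start
        if sec == "noinput":
            log.append((tc, cmd, False))
            return _section_time(kin, track.section_length, "wrong", delay)
        good = cmd == sec
        log.append((tc, cmd, good))
        return _section_time(kin, track.section_length,
                             "correct" if good else "wrong", delay)
    return dt_none
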