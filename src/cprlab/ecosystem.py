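"""Two-resource, three-player harvesting game environment.

The game models a minimal "ecosystem" of two renewable resources harvested
by three players.  One player (*yellow*) has sole access to resource 1;
two players (*red* and *blue*) share resource 2 as a common pool, splitting
its harvest in proportion to their efforts.  Each resource has an
inverted-U yield curve in total harvesting effort — the maximum-sustainable
-yield idea: too little effort under-utilises the stock, too much collapses
it.  The two resources are ecologically interdependent: the further one
resource is harvested from its optimum, the lower the *peak* attainable
yield of the other.  The ecosystem resets at the end of every round, so
rounds are payoff-independent.

Efforts are whole hours on a 0..max_hours grid, which makes brute-force
optimisation exact: :func:`find_social_optimum` and :func:`best_response`
enumerate the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

__all__ = [
    "EcosystemParams",
    "EffortProfile",
    "RoundOutcome",
    "InvalidParameterError",
    "yield_curve",
    "coupling_factor",
    "split_cpr",
    "step_round",
    "find_social_optimum",
    "best_response",
    "load_params",
    "PLAYERS",
]

PLAYERS = ("yellow", "red", "blue")

YieldForm = Literal["parabola", "gauss"]


class InvalidParameterError(ValueError):
    """Raised when a game parameter or effort is outside its valid domain."""


@dataclass(frozen=True)
class EcosystemParams:
    """Calibrated parameters of the two-resource yield model.

    Defaults reproduce the reference calibration: individual optima
    (yellow 11 h; red and blue 7 h each, 14 h combined on the shared
    resource), individual peak earnings of 25 coins, and a 20-hour
    per-round effort cap over 22 rounds.

    ``width_*`` is the half-width of the inverted-U: yield is zero once
    total effort is more than one width away from the optimum.  With the
    default ``width = optimum`` the curve passes exactly through zero at
    zero effort.  ``coupling_strength`` in [0, 1] scales how strongly a
    deviation on one resource depresses the other resource's peak.
    """

    optimal_effort_r1: float = 11.0
    optimal_effort_r2_total: float = 14.0
    peak_individual_r1: float = 25.0
    peak_total_r2: float = 50.0
    width_r1: float = 11.0
    width_r2: float = 14.0
    coupling_strength: float = 0.5
    max_hours: int = 20
    n_rounds: int = 22
    yield_form: YieldForm = "parabola"

    def __post_init__(self) -> None:
        positive = {
            "optimal_effort_r1": self.optimal_effort_r1,
            "optimal_effort_r2_total": self.optimal_effort_r2_total,
            "peak_individual_r1": self.peak_individual_r1,
            "peak_total_r2": self.peak_total_r2,
            "width_r1": self.width_r1,
            "width_r2": self.width_r2,
        }
        for name, value in positive.items():
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise InvalidParameterError(
                f"coupling_strength must lie in [0, 1], got {self.coupling_strength!r}"
            )
        if self.max_hours < self.optimal_effort_r1:
            raise InvalidParameterError("max_hours must cover the resource-1 optimum")
        if self.max_hours < self.optimal_effort_r2_total / 2:
            raise InvalidParameterError("max_hours must cover half the resource-2 optimum")
        if self.n_rounds < 1:
            raise InvalidParameterError("n_rounds must be >= 1")
        if self.yield_form not in ("parabola", "gauss"):
            raise InvalidParameterError(f"unknown yield_form {self.yield_form!r}")

    def with_overrides(self, **kwargs: object) -> "EcosystemParams":
        return replace(self, **kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class EffortProfile:
    """One round's harvesting decision: whole hours per player."""

    yellow: int
    red: int
    blue: int

    def validate(self, max_hours: int) -> None:
        for name in PLAYERS:
            e = getattr(self, name)
            if not isinstance(e, (int,)) or isinstance(e, bool):
                raise InvalidParameterError(f"effort {name}={e!r} must be an integer")
            if not (0 <= e <= max_hours):
                raise InvalidParameterError(
                    f"effort {name}={e} outside [0, {max_hours}]"
                )

    def as_dict(self) -> dict[str, int]:
        return {"yellow": self.yellow, "red": self.red, "blue": self.blue}


@dataclass(frozen=True)
class RoundOutcome:
    """Yields, per-player coins and effort deviations for one round."""

    yield_r1: float
    yield_r2_total: float
    coins_yellow: float
    coins_red: float
    coins_blue: float
    deviation_r1: float
    deviation_r2: float

    @property
    def coins(self) -> tuple[float, float, float]:
        return (self.coins_yellow, self.coins_red, self.coins_blue)


def yield_curve(
    total_effort: float,
    peak: float,
    optimal: float,
    width: float,
    form: YieldForm = "parabola",
) -> float:
    """Yield (coins) of one resource as a function of total effort.

    ``parabola`` (default): ``peak * max(0, 1 - ((E - optimal)/width)^2)``,
    a truncated inverted parabola that is zero outside
    ``[optimal - width, optimal + width]``.  ``gauss`` is a Gaussian bump
    ``peak * exp(-((E - optimal)/width)^2)`` with the same peak location,
    accepted behind the same contract (strictly positive everywhere, so
    the hard-zero collapse region is a parabola-only feature).
    """
    for name, v in (("total_effort", total_effort), ("peak", peak),
                    ("optimal", optimal), ("width", width)):
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v!r}")
    if total_effort < 0:
        raise InvalidParameterError(f"total_effort must be >= 0, got {total_effort}")
    if peak <= 0 and peak != 0.0:
        raise InvalidParameterError(f"peak must be >= 0, got {peak}")
    if optimal <= 0 or width <= 0:
        raise InvalidParameterError("optimal and width must be > 0")
    z = (total_effort - optimal) / width
    if form == "gauss":
        return peak * math.exp(-z * z)
    return peak * max(0.0, 1.0 - z * z)


def coupling_factor(
    other_deviation: float, coupling_strength: float, other_optimal: float
) -> float:
    """Multiplier in [0, 1] applied to a resource's peak yield.

    Encodes the ecological interdependency: the further the *other*
    resource is harvested from its optimum, the lower the maximum yield
    attainable here.  Linear in the absolute deviation, floored at zero;
    equal to 1 at zero deviation.  Scales peak height only, so it never
    moves a resource's optimal effort.
    """
    if not math.isfinite(other_deviation) or other_deviation < 0:
        raise InvalidParameterError(
            f"other_deviation must be finite and >= 0, got {other_deviation!r}"
        )
    if not (0.0 <= coupling_strength <= 1.0):
        raise InvalidParameterError("coupling_strength must lie in [0, 1]")
    if other_optimal <= 0:
        raise InvalidParameterError("other_optimal must be > 0")
    return max(0.0, 1.0 - coupling_strength * other_deviation / other_optimal)


def split_cpr(
    total_harvest: float, effort_red: float, effort_blue: float
) -> tuple[float, float]:
    """Split the shared resource's harvest in proportion to efforts.

    Shares sum exactly to ``total_harvest``; two idle players get (0, 0).
    """
    if not math.isfinite(total_harvest) or total_harvest < 0:
        raise InvalidParameterError(f"total_harvest must be >= 0, got {total_harvest!r}")
    if effort_red < 0 or effort_blue < 0:
        raise InvalidParameterError("efforts must be >= 0")
    total_effort = effort_red + effort_blue
    if total_effort == 0:
        return (0.0, 0.0)
    share_red = total_harvest * effort_red / total_effort
    return (share_red, total_harvest - share_red)


def step_round(efforts: EffortProfile, params: EcosystemParams | None = None) -> RoundOutcome:
    """Resolve one round of the game for a full effort profile.

    Each resource's peak is scaled by the coupling factor of the *other*
    resource's same-round deviation, then evaluated on its yield curve.
    Red and blue split the shared yield proportionally.  Stateless: the
    ecosystem resets every round, so identical efforts give identical
    outcomes.
    """
    if params is None:
        params = EcosystemParams()
    efforts.validate(params.max_hours)
    e_total_r2 = efforts.red + efforts.blue
    dev_r1 = abs(efforts.yellow - params.optimal_effort_r1)
    dev_r2 = abs(e_total_r2 - params.optimal_effort_r2_total)

    peak_r1 = params.peak_individual_r1 * coupling_factor(
        dev_r2, params.coupling_strength, params.optimal_effort_r2_total
    )
    peak_r2 = params.peak_total_r2 * coupling_factor(
        dev_r1, params.coupling_strength, params.optimal_effort_r1
    )
    y1 = yield_curve(efforts.yellow, peak_r1, params.optimal_effort_r1,
                     params.width_r1, params.yield_form)
    y2 = yield_curve(e_total_r2, peak_r2, params.optimal_effort_r2_total,
                     params.width_r2, params.yield_form)
    coins_red, coins_blue = split_cpr(y2, efforts.red, efforts.blue)
    return RoundOutcome(
        yield_r1=y1,
        yield_r2_total=y2,
        coins_yellow=y1,
        coins_red=coins_red,
        coins_blue=coins_blue,
        deviation_r1=dev_r1,
        deviation_r2=dev_r2,
    )


def _group_total(outcome: RoundOutcome) -> float:
    return outcome.coins_yellow + outcome.coins_red + outcome.coins_blue


def find_social_optimum(params: EcosystemParams | None = None) -> EffortProfile:
    """Exhaustively search the integer effort grid for the profile
    maximising total group coins.

    Ties are broken toward the most equal red/blue split, then toward the
    lowest total effort, so the result is deterministic.  Under the
    default calibration this is (yellow 11, red 7, blue 7).
    """
    if params is None:
        params = EcosystemParams()
    m = params.max_hours
    best: tuple[float, float, int, EffortProfile] | None = None
    for y in range(m + 1):
        for r in range(m + 1):
            for b in range(m + 1):
                profile = EffortProfile(y, r, b)
                total = _group_total(step_round(profile, params))
                # sort key: max coins, then min |red-blue|, then min hours
                key = (-total, abs(r - b), y + r + b)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (total, abs(r - b), y + r + b, profile)
    assert best is not None
    return best[3]


def best_response(
    player: str, fixed: EffortProfile, params: EcosystemParams | None = None
) -> int:
    """Integer effort maximising ``player``'s own coins, others fixed.

    ``fixed`` supplies the two non-focal efforts (the focal entry is
    ignored).  Ties break toward lower effort.  For the CPR sharers the
    best response sits above the cooperative 7 hours — proportional
    sharing rewards out-working your partner — which is the formalised
    overharvesting incentive.
    """
    if params is None:
        params = EcosystemParams()
    if player not in PLAYERS:
        raise InvalidParameterError(f"unknown player {player!r}; expected one of {PLAYERS}")
    best_effort = 0
    best_coins = -math.inf
    for e in range(params.max_hours + 1):
        profile = EffortProfile(**{**fixed.as_dict(), player: e})
        coins = getattr(step_round(profile, params), f"coins_{player}")
        if coins > best_coins + 1e-12:
            best_coins = coins
            best_effort = e
    return best_effort


def load_params(path: str | Path) -> EcosystemParams:
    """Read ecosystem parameters from a plain-text ``key: value`` file.

    Unknown keys raise; omitted keys keep their defaults.  Lines starting
    with ``#`` and blank lines are ignored.
    """
    numeric_int = {"max_hours", "n_rounds"}
    fields = {f.name for f in EcosystemParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    overrides: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise InvalidParameterError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key not in fields:
            raise InvalidParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key == "yield_form":
            overrides[key] = value
        elif key in numeric_int:
            overrides[key] = int(value)
        else:
            overrides[key] = float(value)
    return EcosystemParams(**overrides)  # type: ignore[arg-type]
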