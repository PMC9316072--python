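"""Lower-body negative pressure (LBNP) protocol description.

The default protocol is a five-stage graded central-hypovolaemia session:
10 min baseline at 0 mmHg, three 7-min LBNP stages at -15/-30/-45 mmHg, and
a 10-min recovery at 0 mmHg. Analysis uses only the last two minutes of each
stage; the first two minutes of each LBNP stage and the first seven minutes
of recovery are excluded (settling intervals after a pressure change).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ProtocolError

__all__ = ["Stage", "ProtocolDefinition", "default_protocol", "BASELINE", "RECOVERY"]

BASELINE = "baseline"
RECOVERY = "recovery"


@dataclass(frozen=True)
class Stage:
    """One protocol stage.

    Parameters
    ----------
    label : str
        Stage identifier, unique within a protocol.
    chamber_pressure : float
        Chamber pressure in mmHg (0 for baseline/recovery, negative for LBNP).
    duration : float
        Stage duration in seconds.
    exclusion_head : float
        Initial interval (s) excluded from analysis.
    """

    label: str
    chamber_pressure: float
    duration: float
    exclusion_head: float


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered stage list plus the analysis-window length.

    ``window_length`` seconds at the *end* of each stage form the analysis
    window; the window must never overlap the stage's excluded head.
    """

    stages: tuple[Stage, ...]
    window_length: float = 120.0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ProtocolError("window_length must be positive")
        labels = [s.label for s in self.stages]
        if len(set(labels)) != len(labels):
            raise ProtocolError("stage labels must be unique")
        for s in self.stages:
            if s.duration <= 0:
                raise ProtocolError(f"stage {s.label!r}: non-positive duration")
            if s.exclusion_head < 0:
                raise ProtocolError(f"stage {s.label!r}: negative exclusion head")
            if s.duration < s.exclusion_head + self.window_length:
                raise ProtocolError(
                    f"stage {s.label!r}: duration {s.duration:g}s cannot hold "
                    f"{s.exclusion_head:g}s exclusion + {self.window_length:g}s window"
                )

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stages]

    def stage(self, label: str) -> Stage:
        for s in self.stages:
            if s.label == label:
                return s
        raise ProtocolError(f"unknown stage {label!r}")

    def order(self, label: str) -> int:
        """Position of a stage in protocol order (0 = first)."""
        return self.labels.index(label)

    def window_bounds(self, label: str) -> tuple[float, float]:
        """[start, end) of the analysis window in seconds from stage start."""
        s = self.stage(label)
        return s.duration - self.window_length, s.duration

    def to_dict(self) -> dict:
        return {
            "window_length": self.window_length,
            "stages": [
                {
                    "label": s.label,
                    "chamber_pressure": s.chamber_pressure,
                    "duration": s.duration,
                    "exclusion_head": s.exclusion_head,
                }
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolDefinition":
        return cls(
            stages=tuple(Stage(**s) for s in d["stages"]),
            window_length=d["window_length"],
        )


def default_protocol() -> ProtocolDefinition:
    """The five-stage graded LBNP session used throughout the package."""
    return ProtocolDefinition(
        stages=(
            Stage(BASELINE, 0.0, 600.0, 0.0),
            Stage("lbnp15", -15.0, 420.0, 120.0),
            Stage("lbnp30", -30.0, 420.0, 120.0),
            Stage("lbnp45", -45.0, 420.0, 120.0),
            Stage(RECOVERY, 0.0, 600.0, 420.0),
        ),
        window_length=120.0,
    )
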