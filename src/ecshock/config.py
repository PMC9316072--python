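"""Generator configuration for the synthetic LBNP cohort.

The defaults encode the statistical structure the downstream analysis
assumes: multiplicative stage responses relative to each subject's baseline
(cohort medians), log-normal between-subject response heterogeneity, and
stage-level idiosyncratic noise calibrated so that intra-subject Pearson
correlations with the echocardiographic reference stroke volume land on the
configured targets.

Parameter naming follows the electrical-cardiometry (EC) monitor channel
list: sv (stroke volume, mL), hr (min^-1), co (L/min, derived), si/ci
(BSA-indexed, derived), pep/lvet (systolic time intervals, ms), ftc
(rate-corrected flow time, derived), str (systolic time ratio = pep/lvet,
derived), icon (contractility index), vic (variation in contractility, %),
svv (stroke-volume variation, %), hrv (heart-rate variability, ms), and the
entropy/stationarity channels hrc, mse, pnn, stat, plus the ccc beat
counter. ``sv_tte`` is the echo reference; sbp/dbp/map are per-stage cuff
vital signs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "EC_PARAMETERS",
    "GENERATED_PARAMETERS",
    "DERIVED_PARAMETERS",
    "VITAL_SIGNS",
    "STAGE_LABELS",
]

#: protocol-ordered stage labels the default multiplier tables refer to
STAGE_LABELS = ("baseline", "lbnp15", "lbnp30", "lbnp45", "recovery")

#: the 18 EC monitor channels, in beat-table column order
EC_PARAMETERS = (
    "sv", "hr", "co", "si", "ci", "pep", "lvet", "ftc", "str",
    "icon", "vic", "svv", "hrv", "hrc", "mse", "pnn", "stat", "ccc",
)

#: channels produced directly by the stage-response model
GENERATED_PARAMETERS = (
    "sv", "hr", "pep", "lvet", "icon", "vic", "svv", "hrv",
    "hrc", "mse", "pnn", "stat",
)

#: channels derived per beat from identities (never configured directly)
DERIVED_PARAMETERS = ("co", "si", "ci", "ftc", "str", "ccc")

#: per-stage cuff measurements, one reading per stage
VITAL_SIGNS = ("sbp", "dbp", "map")


def _default_multipliers() -> dict[str, tuple[float, ...]]:
    # Median stage level relative to baseline, per channel, in protocol
    # order (baseline, -15, -30, -45 mmHg, recovery). Endpoints at -45 mmHg
    # and the heart-rate / pressure trajectories follow the cohort medians
    # the analysis is designed around; intermediate stages interpolate a
    # monotone graded response.
    return {
        "sv_tte": (1.0, 0.88, 0.77, 0.657, 0.90),
        "sv":     (1.0, 0.93, 0.87, 0.799, 0.92),
        "icon":   (1.0, 0.90, 0.80, 0.704, 0.88),
        "hr":     (1.0, 0.969, 1.022, 1.095, 0.92),
        "pep":    (1.0, 1.05, 1.12, 1.20, 1.05),
        "lvet":   (1.0, 0.96, 0.92, 0.87, 0.97),
        "svv":    (1.0, 1.15, 1.35, 1.60, 1.10),
        "hrv":    (1.0, 0.85, 0.70, 0.55, 0.90),
        "vic":    (1.0, 1.0, 1.0, 1.0, 1.0),
        "hrc":    (1.0, 1.0, 1.0, 1.0, 1.0),
        "mse":    (1.0, 1.0, 1.0, 1.0, 1.0),
        "pnn":    (1.0, 1.0, 1.0, 1.0, 1.0),
        "stat":   (1.0, 1.0, 1.0, 1.0, 1.0),
        "sbp":    (1.0, 0.98, 0.953, 0.948, 1.0),
        "dbp":    (1.0, 1.0, 1.01, 1.027, 1.038),
        "map":    (1.0, 1.0, 1.0, 1.0, 1.02),
    }


def _default_correlation_targets() -> dict[str, float]:
    # Target median intra-subject Pearson correlation with sv_tte across
    # the five stage timepoints.
    return {
        "sv": 0.856,
        "icon": 0.806,
        "pep": -0.839,
        "str": -0.902,
        "svv": -0.706,
        "hrv": 0.797,
        "sbp": 0.624,
        "hr": -0.576,
    }


def _default_beat_cv() -> dict[str, float]:
    # Beat-to-beat coefficient of variation (log-scale sd) per generated
    # channel; hr jitter acts on the RR interval.
    return {
        "sv": 0.06, "hr": 0.04, "pep": 0.04, "lvet": 0.03,
        "icon": 0.12, "vic": 0.15, "svv": 0.15, "hrv": 0.20,
        "hrc": 0.10, "mse": 0.10, "pnn": 0.20, "stat": 0.05,
    }


def _default_baselines() -> dict[str, float]:
    # Population-median baselines for a young healthy supine male cohort.
    return {
        "sv": 95.0,     # mL
        "hr": 62.0,     # min^-1
        "pep": 100.0,   # ms
        "lvet": 300.0,  # ms
        "icon": 50.0,
        "vic": 10.0,    # %
        "svv": 10.0,    # %
        "hrv": 50.0,    # ms
        "hrc": 1.0,
        "mse": 1.0,
        "pnn": 30.0,    # %
        "stat": 0.8,
        "sbp": 125.0,   # mmHg
        "dbp": 70.0,    # mmHg
        "map": 88.0,    # mmHg
    }


@dataclass
class GeneratorConfig:
    """Full description of the synthetic cohort's statistical structure.

    Attributes
    ----------
    stage_multipliers : mapping parameter -> per-stage median relative level
        Strictly positive; the baseline entry must be 1.
    between_subject_sd : float
        Log-scale sd of the shared subject "response severity" factor.
    response_jitter_sd : float
        Extra per-(subject, parameter) log-scale response heterogeneity.
    correlation_targets : mapping parameter -> target median intra-subject
        Pearson correlation with the echo reference stroke volume.
    lvet_correlation_target : float
        Calibration target for lvet (its own correlation is not reported;
        this value is chosen so the derived str channel lands on target).
    sv_tte_stage_sd : float
        Log-scale stage-level idiosyncratic noise of the echo reference.
    vti_cv : float
        Coefficient of variation of individual VTI (velocity-time integral)
        measurements; nine samples are medianed per stage.
    n_vti_samples : int
        VTI samples per stage-echo measurement.
    beat_cv : mapping parameter -> beat-to-beat coefficient of variation.
    baselines : mapping parameter -> population-median baseline value.
    baseline_cv : float
        Log-scale between-subject sd of baseline levels.
    noise_factor : float
        Global multiplier on every noise scale (stage-level, beat-level,
        echo). 0 gives a noise-free cohort; 1 is the calibrated default.
    missingness_rate_echo : float
        Probability a stage-echo measurement is missing (flagged, in [0, 1)).
    missingness_rate_absolute : float
        Probability a whole (subject, stage) EC recording is missing.
    seed : int
        Default generator seed (overridable at generation time).
    """

    stage_multipliers: dict[str, tuple[float, ...]] = field(default_factory=_default_multipliers)
    between_subject_sd: float = 0.25
    response_jitter_sd: float = 0.10
    correlation_targets: dict[str, float] = field(default_factory=_default_correlation_targets)
    lvet_correlation_target: float = 0.80
    sv_tte_stage_sd: float = 0.03
    vti_cv: float = 0.04
    n_vti_samples: int = 9
    beat_cv: dict[str, float] = field(default_factory=_default_beat_cv)
    baselines: dict[str, float] = field(default_factory=_default_baselines)
    baseline_cv: float = 0.10
    noise_factor: float = 1.0
    missingness_rate_echo: float = 0.057
    missingness_rate_absolute: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for param, mults in self.stage_multipliers.items():
            arr = tuple(float(m) for m in mults)
            if any(m <= 0 for m in arr):
                raise ConfigurationError(f"{param}: stage multipliers must be strictly positive")
            if abs(arr[0] - 1.0) > 1e-12:
                raise ConfigurationError(f"{param}: baseline multiplier must be 1, got {arr[0]}")
        for name in ("missingness_rate_echo", "missingness_rate_absolute"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {rate}")
        if self.noise_factor < 0:
            raise ConfigurationError("noise_factor must be non-negative")
        if self.between_subject_sd < 0 or self.response_jitter_sd < 0:
            raise ConfigurationError("dispersion parameters must be non-negative")
        if self.n_vti_samples < 1:
            raise ConfigurationError("n_vti_samples must be >= 1")
        for rho in self.correlation_targets.values():
            if not (-1.0 < rho < 1.0) or rho == 0:
                raise ConfigurationError("correlation targets must lie in (-1, 1) and be non-zero")

    # -- presets ---------------------------------------------------------

    @classmethod
    def low_noise(cls, **overrides) -> "GeneratorConfig":
        """Calibrated structure with all noise scales halved.

        Used for signal-recovery benchmarks where the question is whether
        the pipeline finds structure that is unambiguously present.
        """
        overrides.setdefault("noise_factor", 0.5)
        return cls(**overrides)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_multipliers"] = {k: list(v) for k, v in d["stage_multipliers"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "stage_multipliers" in d:
            d["stage_multipliers"] = {k: tuple(v) for k, v in d["stage_multipliers"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
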