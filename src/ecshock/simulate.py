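"""Synthetic LBNP cohort generator.

Emulates the data-generating situation of a graded lower-body negative
pressure (LBNP) session in healthy volunteers: beat-to-beat electrical
cardiometry (EC) channels per subject and stage, a per-stage transthoracic
echo (TTE) reference stroke volume, and per-stage cuff vital signs.

Generation model
----------------
Everything is multiplicative on the log scale:

* each subject draws a baseline level per channel (log-normal around the
  population median) and a shared "response severity" factor ``g_i``
  (log-normal, sd = ``between_subject_sd``) with per-channel jitter;
* the stage effect is the configured median multiplier raised to the
  subject's response scale, plus stage-level idiosyncratic Gaussian noise
  whose sd is *calibrated* from the configured intra-subject correlation
  targets (see :func:`calibrate_stage_noise`);
* beats inside a stage are stationary around the stage level with
  independent log-normal beat-to-beat noise; beat times follow jittered
  RR intervals.

Derived channels are computed per beat from exact identities:
``co = sv * hr / 1000``, ``si = sv / bsa``, ``ci = co / bsa``,
``str = pep / lvet``, ``ftc = lvet / sqrt(rr_seconds)`` (Bazett), and the
``ccc`` channel is the running beat counter.

The echo reference is built the way the reference measurement is made:
a baseline LVOT (left ventricular outflow tract) diameter fixes the
cross-sectional area, each stage draws ``n_vti_samples`` noisy VTI
(velocity-time integral) readings around the true stage value, and
``sv_tte = CSA * median(VTI)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GENERATED_PARAMETERS, VITAL_SIGNS, GeneratorConfig
from .errors import ConfigurationError, DomainError
from .protocol import ProtocolDefinition, default_protocol

__all__ = [
    "SubjectProfile",
    "CohortDataset",
    "bsa_dubois",
    "compute_sv_from_vti",
    "calibrate_stage_noise",
    "generate_cohort",
    "inject_missingness",
]

#: stage-level log-sd for channels without a correlation target
_DEFAULT_STAGE_SD = 0.04


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the DuBois formula."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def compute_sv_from_vti(lvot_diameter_cm: float, vti_samples) -> float:
    """Echo stroke volume (mL): LVOT cross-sectional area times median VTI.

    CSA = pi * (d/2)^2 in cm^2, VTI in cm, so the product is in cm^3 = mL.
    """
    vti = np.asarray(vti_samples, dtype=float)
    if lvot_diameter_cm <= 0:
        raise DomainError("LVOT diameter must be positive")
    if vti.size == 0:
        raise DomainError("need at least one VTI sample")
    csa = np.pi * (lvot_diameter_cm / 2.0) ** 2
    return float(csa * np.median(vti))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject latent parameters of the generation model."""

    subject_id: str
    body_height_cm: float
    body_weight_kg: float
    bsa_m2: float
    baseline_values: dict[str, float]
    response_scale: dict[str, float]
    noise_scale: dict[str, float]
    lvot_diameter_cm: float

    def __post_init__(self) -> None:
        if self.bsa_m2 <= 0:
            raise DomainError("BSA must be positive")
        if not (50.0 <= self.baseline_values["hr"] <= 100.0):
            raise DomainError("baseline HR outside [50, 100] min^-1")
        if not (60.0 <= self.baseline_values["sv"] <= 130.0):
            raise DomainError("baseline SV outside [60, 130] mL")
        if any(r <= 0 for r in self.response_scale.values()):
            raise DomainError("response scales must be strictly positive")


@dataclass
class CohortDataset:
    """A generated cohort: subjects, beat table, echo table, vitals table.

    ``beats`` has one row per heartbeat (subject_id, stage, time_s and the
    18 EC channels); ``echo`` one row per (subject, stage) with the VTI
    samples, derived sv_tte_ml and a missing flag; ``vitals`` one cuff
    reading per (subject, stage).
    """

    subjects: list[SubjectProfile]
    beats: pd.DataFrame
    echo: pd.DataFrame
    vitals: pd.DataFrame
    config: GeneratorConfig
    protocol: ProtocolDefinition
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.beats.to_csv(outdir / "beats.csv", index=False)
        self.echo.to_csv(outdir / "echo.csv", index=False)
        self.vitals.to_csv(outdir / "vitals.csv", index=False)
        self.config.to_yaml(outdir / "generator_config.yaml")

    @classmethod
    def read_csv(cls, indir, protocol: ProtocolDefinition | None = None) -> "CohortDataset":
        """Reload the tabular part of a cohort written by :meth:`write_csv`.

        Subject latent profiles are generation-time internals and are not
        round-tripped; downstream analysis only needs the three tables.
        """
        indir = Path(indir)
        config = GeneratorConfig.from_yaml(indir / "generator_config.yaml")
        return cls(
            subjects=[],
            beats=pd.read_csv(indir / "beats.csv"),
            echo=pd.read_csv(indir / "echo.csv"),
            vitals=pd.read_csv(indir / "vitals.csv"),
            config=config,
            protocol=protocol or default_protocol(),
            seed=config.seed,
        )


# ---------------------------------------------------------------------------
# calibration


def _log_multipliers(config: GeneratorConfig, param: str, n_stages: int) -> np.ndarray:
    mults = config.stage_multipliers.get(param)
    if mults is None:
        return np.zeros(n_stages)
    if len(mults) != n_stages:
        raise ConfigurationError(
            f"{param}: {len(mults)} multipliers for {n_stages} stages"
        )
    return np.log(np.asarray(mults, dtype=float))


_CALIBRATION_SEED = 20_220_706  # fixed: calibration is a property of the design
_CALIBRATION_REPS = 4000


def _median_sample_corr(mx: np.ndarray, my: np.ndarray, tau_x: float,
                        tau_y: float, draws: dict[str, np.ndarray]) -> float:
    """Median n-point sample Pearson correlation under the stage model.

    Uses pre-drawn common random numbers so the value is a smooth,
    deterministic, monotone-in-``tau_x`` function.
    """
    rx = draws["g"] * draws["jx"]
    ry = draws["g"] * draws["jy"]
    x = rx[:, None] * mx + tau_x * draws["zx"]
    y = ry[:, None] * my + tau_y * draws["zy"]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    r = np.divide((xc * yc).sum(axis=1), denom,
                  out=np.zeros(len(denom)), where=denom > 0)
    return float(np.median(r))


def calibrate_stage_noise(config: GeneratorConfig, n_stages: int = 5) -> dict[str, float]:
    """Stage-level log-noise sd per channel, solved from correlation targets.

    For each channel with a target, the within-subject sample Pearson
    correlation (across the protocol's stage timepoints, echo reference
    noise and subject heterogeneity included) is a monotone decreasing
    function of the channel's stage-level noise sd; the sd is found by
    bisection on the Monte-Carlo median of that sample correlation, using
    fixed common random numbers so the result is a deterministic function
    of the configuration. Channels without a target get a flat default.
    """
    y = _log_multipliers(config, "sv_tte", n_stages)
    # log-sd of the median of n iid log-normal VTI samples
    echo_sd = 1.2533 * config.vti_cv / np.sqrt(config.n_vti_samples)
    tau_tte = config.sv_tte_stage_sd
    tau_y = float(np.hypot(tau_tte, echo_sd))

    targets = dict(config.correlation_targets)
    targets.pop("str", None)  # derived channel: calibrated via pep and lvet
    targets["lvet"] = config.lvet_correlation_target

    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_REPS
    draws = {
        "g": np.exp(rng.normal(0.0, config.between_subject_sd, n)),
        "jx": np.exp(rng.normal(0.0, config.response_jitter_sd, n)),
        "jy": np.exp(rng.normal(0.0, config.response_jitter_sd, n)),
        "zx": rng.standard_normal((n, n_stages)),
        "zy": rng.standard_normal((n, n_stages)),
    }

    taus: dict[str, float] = {"sv_tte": tau_tte}
    for param in (*GENERATED_PARAMETERS, *VITAL_SIGNS):
        x = _log_multipliers(config, param, n_stages)
        rho = targets.get(param)
        if rho is None or np.allclose(x, x[0]):
            taus[param] = _DEFAULT_STAGE_SD
            continue
        sx = float(np.std(x, ddof=1))
        r0 = _median_sample_corr(x, y, 0.0, tau_y, draws)
        if rho * r0 <= 0 or abs(rho) >= abs(r0):
            raise ConfigurationError(
                f"{param}: correlation target {rho} unattainable "
                f"(trajectory-limited maximum {r0:.3f})"
            )
        lo, hi = 0.0, 20.0 * sx
        while abs(_median_sample_corr(x, y, hi, tau_y, draws)) > abs(rho) \
                and hi < 1e3 * sx:
            hi *= 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if abs(_median_sample_corr(x, y, mid, tau_y, draws)) > abs(rho):
                lo = mid
            else:
                hi = mid
        taus[param] = 0.5 * (lo + hi)
    return taus


# ---------------------------------------------------------------------------
# generation


def _draw_subjects(n: int, config: GeneratorConfig, taus: dict[str, float],
                   rng: np.random.Generator) -> list[SubjectProfile]:
    subjects = []
    width = max(2, len(str(n)))
    for i in range(n):
        height = float(np.clip(rng.normal(183.0, 3.5), 165.0, 205.0))
        weight = float(np.clip(rng.normal(80.0, 11.0), 55.0, 120.0))
        baselines = {}
        for param in (*GENERATED_PARAMETERS, *VITAL_SIGNS):
            pop = config.baselines[param]
            val = pop * np.exp(rng.normal(0.0, config.baseline_cv))
            if param == "hr":
                val = np.clip(val, 52.0, 98.0)
            elif param == "sv":
                val = np.clip(val, 62.0, 128.0)
            baselines[param] = float(val)
        # echo reference: true SV equals the subject's SV scale up to a small
        # EC calibration bias; CSA fixed by a baseline LVOT diameter
        ec_bias = np.exp(rng.normal(0.0, 0.06))
        baselines["sv_tte"] = float(np.clip(baselines["sv"] * ec_bias, 60.0, 130.0))
        lvot = float(np.clip(rng.normal(2.2, 0.08), 1.9, 2.5))
        g = np.exp(rng.normal(0.0, config.between_subject_sd))
        response = {
            param: float(g * np.exp(rng.normal(0.0, config.response_jitter_sd)))
            for param in ("sv_tte", *GENERATED_PARAMETERS, *VITAL_SIGNS)
        }
        noise = {param: float(config.noise_factor * taus[param]) for param in taus}
        subjects.append(SubjectProfile(
            subject_id=f"S{i + 1:0{width}d}",
            body_height_cm=height,
            body_weight_kg=weight,
            bsa_m2=bsa_dubois(height, weight),
            baseline_values=baselines,
            response_scale=response,
            noise_scale=noise,
            lvot_diameter_cm=lvot,
        ))
    return subjects


def _stage_levels(subject: SubjectProfile, config: GeneratorConfig,
                  logm: dict[str, np.ndarray], n_stages: int,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-stage log-normal levels for every non-derived channel."""
    levels = {}
    for param in ("sv_tte", *GENERATED_PARAMETERS, *VITAL_SIGNS):
        base = subject.baseline_values[param]
        r = subject.response_scale[param]
        tau = subject.noise_scale[param]
        z = rng.standard_normal(n_stages)
        levels[param] = base * np.exp(r * logm[param] + tau * z)
    return levels


def generate_cohort(n_subjects: int,
                    config: GeneratorConfig | None = None,
                    protocol: ProtocolDefinition | None = None,
                    seed: int | None = None) -> CohortDataset:
    """Generate a synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Number of volunteers (>= 1).
    config : GeneratorConfig, optional
        Statistical structure; defaults to the calibrated default.
    protocol : ProtocolDefinition, optional
        Stage timing; defaults to the five-stage session.
    seed : int, optional
        Overrides ``config.seed``. Identical (config, seed) pairs yield
        bit-identical datasets.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    config = config or GeneratorConfig()
    config.validate()
    protocol = protocol or default_protocol()
    seed = config.seed if seed is None else int(seed)

    n_stages = len(protocol.stages)
    taus = calibrate_stage_noise(config, n_stages)
    logm = {p: _log_multipliers(config, p, n_stages)
            for p in ("sv_tte", *GENERATED_PARAMETERS, *VITAL_SIGNS)}
    nf = config.noise_factor
    echo_cols = [f"vti_{k + 1}" for k in range(config.n_vti_samples)]

    ss = np.random.SeedSequence(seed)
    subj_seed, beat_seed, miss_seed = ss.spawn(3)
    rng = np.random.default_rng(subj_seed)
    subjects = _draw_subjects(n_subjects, config, taus, rng)

    beat_rng = np.random.default_rng(beat_seed)
    beat_frames, echo_rows, vital_rows = [], [], []
    for subject in subjects:
        levels = _stage_levels(subject, config, logm, n_stages, beat_rng)
        csa = np.pi * (subject.lvot_diameter_cm / 2.0) ** 2
        for j, stage in enumerate(protocol.stages):
            # echo reference: noisy VTI samples around the true stage value
            vti_true = levels["sv_tte"][j] / csa
            vti = vti_true * np.exp(
                nf * config.vti_cv * beat_rng.standard_normal(config.n_vti_samples))
            echo_rows.append({
                "subject_id": subject.subject_id, "stage": stage.label,
                "lvot_diameter_cm": subject.lvot_diameter_cm,
                **dict(zip(echo_cols, vti)),
                "sv_tte_ml": compute_sv_from_vti(subject.lvot_diameter_cm, vti),
                "missing": False,
            })
            vital_rows.append({
                "subject_id": subject.subject_id, "stage": stage.label,
                **{v: levels[v][j] for v in VITAL_SIGNS},
            })
            # beat-to-beat EC channels
            rr_level = 60.0 / levels["hr"][j]
            n_max = int(stage.duration / rr_level * 1.3) + 20
            rr = rr_level * np.exp(
                nf * config.beat_cv["hr"] * beat_rng.standard_normal(n_max))
            t = np.cumsum(rr)
            chan = {
                p: levels[p][j] * np.exp(
                    nf * config.beat_cv[p] * beat_rng.standard_normal(n_max))
                for p in GENERATED_PARAMETERS if p != "hr"
            }
            keep = t < stage.duration
            rr, t = rr[keep], t[keep]
            chan = {p: v[keep] for p, v in chan.items()}
            hr = 60.0 / rr
            frame = pd.DataFrame({
                "subject_id": subject.subject_id,
                "stage": stage.label,
                "time_s": t,
                "sv": chan["sv"],
                "hr": hr,
                "co": chan["sv"] * hr / 1000.0,
                "si": chan["sv"] / subject.bsa_m2,
                "ci": chan["sv"] * hr / 1000.0 / subject.bsa_m2,
                "pep": chan["pep"],
                "lvet": chan["lvet"],
                "ftc": chan["lvet"] / np.sqrt(rr),
                "str": chan["pep"] / chan["lvet"],
                "icon": chan["icon"],
                "vic": chan["vic"],
                "svv": chan["svv"],
                "hrv": chan["hrv"],
                "hrc": chan["hrc"],
                "mse": chan["mse"],
                "pnn": chan["pnn"],
                "stat": chan["stat"],
                "ccc": np.arange(1, keep.sum() + 1, dtype=float),
            })
            beat_frames.append(frame)

    cohort = CohortDataset(
        subjects=subjects,
        beats=pd.concat(beat_frames, ignore_index=True),
        echo=pd.DataFrame(echo_rows),
        vitals=pd.DataFrame(vital_rows),
        config=config,
        protocol=protocol,
        seed=seed,
    )
    return inject_missingness(cohort, config, seed=miss_seed)


def inject_missingness(cohort: CohortDataset,
                       config: GeneratorConfig | None = None,
                       seed=None) -> CohortDataset:
    """Flag missing stage-echo measurements and drop failed EC recordings.

    Echo missingness only flags rows (``missing=True``); the beat table is
    untouched. Absolute missingness removes the whole (subject, stage) beat
    recording and blanks the cuff reading. Both rates must lie in [0, 1);
    a rate of 0 leaves the dataset identical.
    """
    config = config or cohort.config
    for name in ("missingness_rate_echo", "missingness_rate_absolute"):
        rate = getattr(config, name)
        if not (0.0 <= rate < 1.0):
            raise ConfigurationError(f"{name} must lie in [0, 1), got {rate}")
    if config.missingness_rate_echo == 0 and config.missingness_rate_absolute == 0:
        return cohort

    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    echo = cohort.echo.copy()
    echo["missing"] = echo["missing"] | (
        rng.random(len(echo)) < config.missingness_rate_echo)

    beats, vitals = cohort.beats, cohort.vitals
    if config.missingness_rate_absolute > 0:
        drop = rng.random(len(vitals)) < config.missingness_rate_absolute
        dropped = set(map(tuple, vitals.loc[drop, ["subject_id", "stage"]].to_numpy()))
        if dropped:
            mask = [
                (s, st) not in dropped
                for s, st in zip(beats["subject_id"], beats["stage"])
            ]
            beats = beats.loc[mask].reset_index(drop=True)
            vitals = vitals.loc[~drop].reset_index(drop=True)

    return CohortDataset(
        subjects=cohort.subjects, beats=beats, echo=echo, vitals=vitals,
        config=config, protocol=cohort.protocol, seed=cohort.seed,
    )
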