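import math

import numpy as np
import pytest

from ecshock import GeneratorConfig, compute_sv_from_vti, generate_cohort
from ecshock.config import GENERATED_PARAMETERS
from ecshock.errors import ConfigurationError, DomainError
from ecshock.simulate import bsa_dubois, inject_missingness


class TestSvFromVti:
    def test_single_sample(self):
        assert compute_sv_from_vti(2.0, [20.0]) == pytest.approx(
            math.pi * 1.0**2 * 20.0)

    def test_median_of_symmetric_samples(self):
        assert compute_sv_from_vti(2.0, [18.0, 20.0, 22.0]) == pytest.approx(
            math.pi * 20.0)

    def test_nine_samples_against_independent_arithmetic(self, rng):
        vti = 21.0 + rng.normal(0, 1, 9)
        expected = (math.pi * (2.1 / 2) * (2.1 / 2)) * float(np.sort(vti)[4])
        assert compute_sv_from_vti(2.1, vti) == pytest.approx(expected, rel=1e-12)

    def test_errors(self):
        with pytest.raises(DomainError):
            compute_sv_from_vti(2.0, [])
        with pytest.raises(DomainError):
            compute_sv_from_vti(-1.0, [20.0])


def test_bsa_dubois_reference_value():
    # 79 kg, 183 cm -> just over 2 m^2
    assert bsa_dubois(183.0, 79.0) == pytest.approx(2.008, abs=0.01)


class TestGenerateCohort:
    def test_beat_identities(self, small_cohort):
        """Derived channels satisfy their defining identities per beat."""
        bsa = {s.subject_id: s.bsa_m2 for s in small_cohort.subjects}
        b = small_cohort.beats
        w = b["subject_id"].map(bsa).to_numpy()
        assert np.abs(b.si - b.sv / w).max() < 1e-9
        assert np.abs(b.ci - b.co / w).max() < 1e-9
        assert np.abs(b["str"] - b.pep / b.lvet).max() < 1e-9
        assert np.abs(b.co - b.sv * b.hr / 1000.0).max() < 1e-9
        rr = 60.0 / b.hr
        assert np.abs(b.ftc - b.lvet / np.sqrt(rr)).max() < 1e-9

    def test_echo_identity(self, small_cohort):
        e = small_cohort.echo
        vti_cols = [c for c in e.columns if c.startswith("vti_")]
        for _, row in e.head(20).iterrows():
            assert row["sv_tte_ml"] == pytest.approx(
                compute_sv_from_vti(row["lvot_diameter_cm"], row[vti_cols]))

    def test_seed_determinism(self):
        cfg = GeneratorConfig()
        a = generate_cohort(2, cfg, seed=7)
        b = generate_cohort(2, cfg, seed=7)
        assert a.beats.equals(b.beats)
        assert a.echo.equals(b.echo)
        assert a.vitals.equals(b.vitals)

    def test_monotone_sv_decline_without_noise(self):
        cohort = generate_cohort(5, GeneratorConfig(noise_factor=0.0), seed=1)
        piv = cohort.echo.pivot(index="subject_id", columns="stage",
                                values="sv_tte_ml")
        for col_pair in [("baseline", "lbnp15"), ("lbnp15", "lbnp30"),
                         ("lbnp30", "lbnp45")]:
            assert (piv[col_pair[1]] < piv[col_pair[0]]).all()

    def test_unit_multipliers_give_constant_channels(self):
        cfg = GeneratorConfig(
            stage_multipliers={p: (1.0,) * 5
                               for p in GeneratorConfig().stage_multipliers},
            correlation_targets={}, noise_factor=0.0)
        cohort = generate_cohort(1, cfg, seed=2)
        for param in GENERATED_PARAMETERS:
            assert cohort.beats[param].nunique() == 1

    def test_subject_physiology_in_range(self, small_cohort):
        for s in small_cohort.subjects:
            assert 50 <= s.baseline_values["hr"] <= 100
            assert 60 <= s.baseline_values["sv"] <= 130
            assert s.bsa_m2 > 0

    def test_beat_times_increasing_within_stage(self, small_cohort):
        for _, grp in small_cohort.beats.groupby(["subject_id", "stage"]):
            assert (np.diff(grp["time_s"]) > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            generate_cohort(0, GeneratorConfig())
        with pytest.raises(ConfigurationError):
            GeneratorConfig(stage_multipliers={"sv_tte": (1, 0.9, -0.8, 0.7, 1)})
        with pytest.raises(ConfigurationError):
            GeneratorConfig(stage_multipliers={"sv_tte": (0.9, 0.9, 0.8, 0.7, 1)})
        with pytest.raises(ConfigurationError):
            GeneratorConfig(missingness_rate_echo=1.0)

    def test_multiplier_recovery_moderate_n(self):
        cohort = generate_cohort(50, GeneratorConfig(), seed=31)
        piv = cohort.echo.pivot(index="subject_id", columns="stage",
                                values="sv_tte_ml")
        rel = (piv["lbnp45"] / piv["baseline"]).median()
        assert rel == pytest.approx(0.657, abs=0.05)


class TestMissingness:
    def test_zero_rate_is_identity(self, small_cohort):
        out = inject_missingness(small_cohort,
                                 GeneratorConfig(missingness_rate_echo=0.0),
                                 seed=5)
        assert out.echo.equals(small_cohort.echo)
        assert out.beats.equals(small_cohort.beats)

    def test_rate_one_rejected(self, small_cohort):
        cfg = GeneratorConfig()
        cfg.missingness_rate_echo = 1.0  # bypass constructor validation
        with pytest.raises(ConfigurationError):
            inject_missingness(small_cohort, cfg, seed=5)

    def test_flag_count_within_binomial_bounds(self):
        cohort = generate_cohort(40, GeneratorConfig(missingness_rate_echo=0.0),
                                 seed=17)
        out = inject_missingness(cohort,
                                 GeneratorConfig(missingness_rate_echo=0.11),
                                 seed=99)
        n = len(out.echo)  # 200 stage-echo entries
        flagged = int(out.echo["missing"].sum())
        # 99% binomial interval around n * 0.11
        sd = np.sqrt(n * 0.11 * 0.89)
        assert abs(flagged - n * 0.11) < 2.6 * sd
        assert out.beats.equals(cohort.beats)  # echo missingness spares beats


def test_config_yaml_roundtrip(tmp_path):
    cfg = GeneratorConfig(between_subject_sd=0.3, missingness_rate_echo=0.08)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()
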