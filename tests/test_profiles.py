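"""Profile data model, tolerances, normalization and cross-sample matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peptimark import (MatchingParams, NormalizationError, PeptideRecord,
                       SampleProfile, ValidationError, mass_tolerance,
                       match_peptides, migration_tolerance, normalize_profile,
                       read_matrix, read_profiles, write_matrix,
                       write_profiles)
from peptimark.errors import FormatError

PARAMS = MatchingParams()


def make_profile(peps, sid="S1", fluid="bile", group="CCA"):
    return SampleProfile(sid, fluid, group, peps)


class TestRecordInvariants:
    def test_rejects_nonpositive_mass_and_negative_intensity(self):
        with pytest.raises(ValidationError):
            PeptideRecord(mass=-1, cetime=20, intensity=5)
        with pytest.raises(ValidationError):
            PeptideRecord(mass=1000, cetime=20, intensity=-5)

    def test_sequence_must_match_coordinates(self):
        with pytest.raises(ValidationError):
            PeptideRecord(1000, 20, 5, sequence="PEPTIDE", start=1, end=5)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            make_profile([])


class TestTolerances:
    @pytest.mark.parametrize("mass,expected", [
        (1000.0, 50.0),    # small peptide
        (10000.0, 75.0),   # large peptide
        (6000.0, 50.0),    # boundary counts as small
    ])
    def test_mass_tolerance_size_classes(self, mass, expected):
        assert mass_tolerance(mass, PARAMS) == expected

    @pytest.mark.parametrize("t,expected", [
        (19.0, 2.0), (45.0, 5.0), (32.0, 3.5),   # endpoints and midpoint
        (10.0, 2.0), (60.0, 5.0),                 # clamped outside the range
    ])
    def test_migration_tolerance_linear_interpolation(self, t, expected):
        assert migration_tolerance(t, PARAMS) == pytest.approx(expected)

    @given(st.floats(min_value=0.1, max_value=100),
           st.floats(min_value=0.1, max_value=100))
    @settings(derandomize=True, max_examples=50)
    def test_migration_tolerance_monotone_and_bounded(self, t1, t2):
        lo, hi = sorted([t1, t2])
        v1, v2 = migration_tolerance(lo, PARAMS), migration_tolerance(hi, PARAMS)
        assert v1 <= v2
        assert 2.0 <= v1 <= 5.0 and 2.0 <= v2 <= 5.0


class TestIO:
    def test_three_row_tsv_single_profile(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tfluid\tgroup\tmass\tcetime\tintensity\n"
            + "".join(f"S1\tbile\tCCA\t{m}\t25.0\t100.0\n"
                      for m in (1000.0, 2000.0, 3000.0))
        )
        profiles = read_profiles(path)
        assert len(profiles) == 1
        assert [p.mass for p in profiles[0].peptides] == [1000.0, 2000.0, 3000.0]

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tfluid\tmass\tcetime\tintensity\nS1\tbile\t1\t2\t3\n")
        with pytest.raises(FormatError, match="group"):
            read_profiles(path)

    def test_negative_intensity_reports_row(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tfluid\tgroup\tmass\tcetime\tintensity\n"
            "S1\tbile\tCCA\t1000\t25\t10\nS1\tbile\tCCA\t1100\t26\t-4\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_profiles(path)

    def test_profile_round_trip_preserves_all_fields(self, tmp_path):
        peps = [
            PeptideRecord(1234.5678, 22.5, 321.0, sequence="PEPTIDE",
                          parent_id="PROT001", start=10, end=16),
            PeptideRecord(987.6543, 33.25, 0.0),
        ]
        original = [make_profile(peps, "S1"), make_profile(list(peps), "S2", group="PSC")]
        path = tmp_path / "rt.tsv"
        write_profiles(original, path)
        back = read_profiles(path)
        assert [p.sample_id for p in back] == ["S1", "S2"]
        for a, b in zip(original, back):
            assert a.peptides == b.peptides

    def test_matrix_round_trip(self, tmp_path, rng):
        profiles = [
            make_profile([PeptideRecord(1000.0 + i, 20.0 + i, float(rng.integers(1, 500)))
                          for i in range(5)], sid=f"S{j}")
            for j in range(3)
        ]
        matrix = match_peptides(profiles, PARAMS)
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path)
        assert back.fluid == matrix.fluid
        assert np.array_equal(back.intensities.to_numpy(), matrix.intensities.to_numpy())
        assert np.array_equal(back.markers["mass"].to_numpy(),
                              matrix.markers["mass"].to_numpy())


class TestNormalization:
    def _standards(self):
        return [PeptideRecord(1000.0, 20.0, 100.0),
                PeptideRecord(2000.0, 25.0, 200.0),
                PeptideRecord(3000.0, 30.0, 400.0)]

    def _profile_with_standards(self, scale=1.0):
        peps = [PeptideRecord(s.mass, s.cetime, s.intensity * scale)
                for s in self._standards()]
        peps.append(PeptideRecord(1500.0, 22.0, 50.0 * scale))
        return make_profile(peps)

    def test_identity_when_standards_match_references(self):
        prof = self._profile_with_standards(scale=1.0)
        out = normalize_profile(prof, self._standards())
        for a, b in zip(out.peptides, prof.peptides):
            assert a.intensity == pytest.approx(b.intensity, rel=1e-9)

    def test_global_scale_inverted(self):
        out = normalize_profile(self._profile_with_standards(scale=10.0),
                                self._standards())
        for pep, std in zip(out.peptides[:3], self._standards()):
            assert pep.intensity == pytest.approx(std.intensity, rel=1e-9)
        assert out.peptides[3].intensity == pytest.approx(50.0, rel=1e-9)

    def test_two_matched_standards_is_error(self):
        prof = self._profile_with_standards()
        with pytest.raises(NormalizationError, match="2 internal standards"):
            normalize_profile(prof, self._standards()[:2])

    def test_idempotent(self):
        once = normalize_profile(self._profile_with_standards(scale=3.0),
                                 self._standards())
        twice = normalize_profile(once, self._standards())
        for a, b in zip(once.peptides, twice.peptides):
            assert a.intensity == pytest.approx(b.intensity, abs=1e-9, rel=1e-9)

    def test_drift_beyond_qc_bound_warns(self):
        # late-migrating standards: the tolerance window admits a 0.5 min
        # shift, but the 0.45 min calibration QC bound flags it
        stds = [PeptideRecord(1000.0, 25.0, 100.0),
                PeptideRecord(2000.0, 30.0, 200.0),
                PeptideRecord(3000.0, 35.0, 400.0)]
        peps = [PeptideRecord(s.mass, s.cetime + 0.5, s.intensity) for s in stds]
        prof = make_profile(peps)
        with pytest.warns(UserWarning, match="drift"):
            normalize_profile(prof, stds)


class TestMatching:
    def test_49ppm_merges_60ppm_splits(self):
        a = make_profile([PeptideRecord(1000.000, 25.0, 100.0)], "S1")
        b = make_profile([PeptideRecord(1000.049, 25.0, 100.0)], "S2")
        c = make_profile([PeptideRecord(1000.060, 25.0, 100.0)], "S3")
        assert len(match_peptides([a, b], PARAMS).marker_ids) == 1
        assert len(match_peptides([a, c], PARAMS).marker_ids) == 2

    def test_shared_peptide_across_five_samples(self):
        profiles = [make_profile([PeptideRecord(1500.0, 30.0, 100.0 + i)], f"S{i}")
                    for i in range(5)]
        matrix = match_peptides(profiles, PARAMS)
        assert matrix.intensities.shape == (1, 5)
        assert (matrix.intensities.to_numpy() > 0).all()

    def test_mixed_fluids_rejected(self):
        a = make_profile([PeptideRecord(1000, 25, 1)], "S1", fluid="bile")
        b = make_profile([PeptideRecord(1000, 25, 1)], "S2", fluid="urine")
        with pytest.raises(ValidationError, match="fluid"):
            match_peptides([a, b], PARAMS)

    def test_order_independent(self, rng):
        profiles = []
        for j in range(4):
            peps = [PeptideRecord(float(m), float(t), float(i))
                    for m, t, i in zip(rng.uniform(800, 5000, 30),
                                       rng.uniform(19, 45, 30),
                                       rng.uniform(1, 1000, 30))]
            profiles.append(make_profile(peps, f"S{j}"))
        m1 = match_peptides(profiles, PARAMS)
        m2 = match_peptides(profiles[::-1], PARAMS)
        assert np.allclose(m1.markers["mass"], m2.markers["mass"])
        assert np.allclose(m1.intensities[m2.intensities.columns].to_numpy(),
                           m2.intensities[m2.intensities.columns].to_numpy())

    def test_cluster_mass_spread_within_twice_tolerance(self, rng):
        # triangle bound: any two members lie within 2x tolerance at consensus
        profiles = []
        for j in range(6):
            masses = np.repeat([1000.0, 2500.0, 4000.0], 3)
            masses = masses * (1 + rng.normal(0, 10e-6, masses.size))
            peps = [PeptideRecord(float(m), 25.0, float(rng.uniform(10, 100)))
                    for m in masses]
            profiles.append(make_profile(peps, f"S{j}"))
        matrix = match_peptides(profiles, PARAMS)
        # consensus masses must sit near the true masses: jitter is 10 ppm
        # (1 sigma) so member spread stays within 2x the 50 ppm tolerance
        for m in matrix.markers["mass"]:
            rel = np.min(np.abs(np.array([1000.0, 2500.0, 4000.0]) - m) / m) * 1e6
            assert rel < 2 * mass_tolerance(m, PARAMS)
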