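"""R2,eff construction, duplicate-based errors, R_ex screening, table I/O."""

import warnings

import numpy as np
import pytest

from cpmgdisp.exchange import ExchangeParams, InvalidInputError, dispersion_curve
from cpmgdisp.profiles import (
    DispersionProfile,
    IntensityRecord,
    SIGMA_FLOOR,
    estimate_sigma_from_duplicates,
    r2eff_from_intensities,
    read_dispersion_table,
    rex_observed,
    screen_dispersing,
    write_dispersion_table,
    write_intensity_table,
    read_intensity_table,
)
from cpmgdisp.simulate import make_dispersion_dataset, preset


def _records(intensities_by_nu, i_ref=1000.0, rid=67, aa="L", mid="a", fl="18.8T"):
    recs = [IntensityRecord(rid, aa, mid, fl, None, i_ref)]
    for nu, vals in intensities_by_nu.items():
        if np.isscalar(vals):
            vals = [vals]
        for k, v in enumerate(vals):
            recs.append(IntensityRecord(rid, aa, mid, fl, nu, v, replicate=k))
    return recs


class TestR2effFromIntensities:
    def test_identity_and_closed_form(self):
        prof = r2eff_from_intensities(
            _records({100.0: 1000.0, 200.0: 500.0}), t_relax=0.02
        )
        by_nu = dict(zip(prof.nu, prof.r2eff))
        assert by_nu[100.0] == pytest.approx(0.0, abs=1e-12)
        assert by_nu[200.0] == pytest.approx(np.log(2) / 0.02, abs=1e-9)

    def test_round_trip_through_intensities(self, cluster1_params, field_800, schedule):
        """Intensity synthesis followed by conversion recovers the curve exactly."""
        curve = dispersion_curve(cluster1_params, field_800, schedule)
        recs = _records(
            {nu: 1000.0 * np.exp(-r2 * schedule.t_relax)
             for nu, r2 in zip(schedule.nu_cpmg, curve)}
        )
        prof = r2eff_from_intensities(recs, schedule.t_relax)
        order = np.argsort(prof.nu)
        expect = curve[np.argsort(schedule.nu_cpmg)]
        assert np.allclose(prof.r2eff[order], expect, atol=1e-12)

    def test_negative_r2eff_warns(self):
        with pytest.warns(UserWarning, match="negative R2,eff"):
            r2eff_from_intensities(_records({100.0: 1100.0}), t_relax=0.02)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            IntensityRecord(67, "L", "a", "18.8T", 100.0, 0.0)

    def test_duplicates_recorded_and_averaged(self):
        prof = r2eff_from_intensities(
            _records({200.0: [600.0, 620.0], 400.0: 800.0}), t_relax=0.02
        )
        dup_nus = [nu for nu, _ in prof.duplicates]
        assert 200.0 in dup_nus
        pair = dict(prof.duplicates)[200.0]
        assert dict(zip(prof.nu, prof.r2eff))[200.0] == pytest.approx(np.mean(pair))


class TestSigmaFromDuplicates:
    def _profile_with_pairs(self, pairs, fl="18.8T"):
        return DispersionProfile(
            residue_id=1, aa="L", methyl_id="a", field_label=fl,
            nu=np.array([100.0, 200.0]), r2eff=np.array([10.0, 10.0]),
            sigma=np.array([1.0, 1.0]), duplicates=pairs,
        )

    def test_identical_duplicates_hit_floor(self):
        p = self._profile_with_pairs([(100.0, (10.0, 10.0))])
        assert estimate_sigma_from_duplicates([p]) == {"18.8T": SIGMA_FLOOR}

    def test_two_pair_hand_arithmetic(self):
        # pairs differing by 2*delta contribute delta*sqrt(2):
        # sigma^2 = mean((d_i^2)/2) with d = 1.0 and 3.0
        p = self._profile_with_pairs([(100.0, (10.5, 9.5)), (200.0, (13.5, 10.5))])
        expect = np.sqrt((1.0**2 / 2 + 3.0**2 / 2) / 2)
        assert estimate_sigma_from_duplicates([p])["18.8T"] == pytest.approx(expect)

    def test_recovers_true_noise_level(self):
        """>= 20 Gaussian pairs at sigma 0.3 pool to within 30% of the truth."""
        rng = np.random.default_rng(7)
        pairs = [
            (float(100 + i), tuple(rng.normal(10.0, 0.3, size=2))) for i in range(24)
        ]
        p = self._profile_with_pairs(pairs)
        est = estimate_sigma_from_duplicates([p])["18.8T"]
        assert est == pytest.approx(0.3, rel=0.3)

    def test_no_duplicates_anywhere_raises(self):
        p = self._profile_with_pairs([])
        with pytest.raises(InvalidInputError, match="sigma explicitly"):
            estimate_sigma_from_duplicates([p])


class TestRexObserved:
    def _profile(self, nu, r2, fl="18.8T"):
        return DispersionProfile(
            residue_id=1, aa="V", methyl_id="b", field_label=fl,
            nu=np.asarray(nu, float), r2eff=np.asarray(r2, float),
            sigma=np.ones(len(nu)),
        )

    def test_flat_profile_gives_zero(self):
        assert rex_observed(self._profile([100, 200, 3000, 6000], [10] * 4)) == 0.0

    def test_two_point_degenerate_grid(self):
        assert rex_observed(self._profile([100, 6000], [18.0, 11.0])) == pytest.approx(7.0)

    def test_matches_noiseless_curve_displacement(self, cluster1_params, field_800, schedule):
        curve = dispersion_curve(cluster1_params, field_800, schedule)
        order = np.argsort(schedule.nu_cpmg)
        nu = np.asarray(schedule.nu_cpmg)[order]
        r2 = curve[order]
        got = rex_observed(self._profile(nu, r2))
        expect = np.mean(r2[:2]) - np.mean(r2[-2:])
        assert got == pytest.approx(expect)
        assert got > 0

    def test_single_point_rejected(self):
        with pytest.raises(InvalidInputError):
            rex_observed(self._profile([100.0], [10.0]))


class TestScreening:
    def test_planted_dispersing_set_recovered(self):
        spec = preset("dbd_300K")
        profiles, truth = make_dispersion_dataset(spec, seed=11)
        got = screen_dispersing(profiles, 5.0, "18.8T")
        assert got == truth.dispersing_residues

    def test_all_flat_dataset_empty(self, schedule):
        spec = preset("dbd_300K")
        profiles, _ = make_dispersion_dataset(spec, seed=1)
        flat = [p for p in profiles if p.residue_id in {58, 73, 85}]
        assert screen_dispersing(flat, 5.0, "18.8T") == set()

    def test_monotone_in_threshold(self):
        spec = preset("dbd_300K")
        profiles, _ = make_dispersion_dataset(spec, seed=3)
        prev = None
        for thr in (2.0, 5.0, 10.0, 20.0, np.inf):
            cur = screen_dispersing(profiles, thr, "18.8T")
            if prev is not None:
                assert cur <= prev
            prev = cur
        assert screen_dispersing(profiles, np.inf, "18.8T") == set()


class TestTableRoundTrips:
    def test_dispersion_table_round_trip(self, tmp_path):
        spec = preset("dbd_300K")
        profiles, _ = make_dispersion_dataset(spec, seed=5)
        path = tmp_path / "disp.tsv"
        write_dispersion_table(profiles, path)
        back = read_dispersion_table(path)
        assert len(back) == len(profiles)
        by_key = {(p.key, p.field_label): p for p in back}
        for p in profiles:
            q = by_key[(p.key, p.field_label)]
            order_p, order_q = np.argsort(p.nu), np.argsort(q.nu)
            np.testing.assert_allclose(q.nu[order_q], p.nu[order_p], rtol=1e-9)
            np.testing.assert_allclose(q.r2eff[order_q], p.r2eff[order_p], rtol=1e-9)
            assert sorted(nu for nu, _ in q.duplicates if nu) == sorted(
                nu for nu, _ in p.duplicates if nu
            )

    def test_round_trip_bit_identical_on_rewrite(self, tmp_path):
        """write -> read -> write reproduces the file byte-for-byte."""
        spec = preset("dbd_290K")
        profiles, _ = make_dispersion_dataset(spec, seed=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_dispersion_table(profiles, p1)
        write_dispersion_table(read_dispersion_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_intensity_table_round_trip(self, tmp_path):
        recs = _records({100.0: [900.0, 910.0], 200.0: 500.0})
        path = tmp_path / "int.tsv"
        write_intensity_table(recs, path)
        back = read_intensity_table(path)
        assert back == recs

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("residue_id\taa\n1\tL\n")
        with pytest.raises(InvalidInputError, match="missing columns"):
            read_dispersion_table(path)
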