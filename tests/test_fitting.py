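"""Fitting machinery: round-trip recovery, model selection, clustering,
chi2-ratio ejection, and Monte Carlo uncertainty contracts."""

import numpy as np
import pytest

from cpmgdisp.exchange import ExchangeParams, InvalidInputError, dispersion_curve
from cpmgdisp.fitting import (
    ClusterExchangeModel,
    MethylExchangeModel,
    accept_member,
    cluster_by_kex,
    fit_individual,
    model_select,
)
from cpmgdisp.profiles import DispersionProfile, rex_observed


def make_profiles(params, fields, schedule, rid=67, aa="L", mid="a",
                  sigma=0.3, rng=None):
    """Noiseless (rng=None) or noisy two-field profiles from known params."""
    out = []
    for lbl, f in fields.items():
        curve = dispersion_curve(params, f, schedule)
        y = curve if rng is None else curve + rng.normal(0.0, sigma, len(curve))
        out.append(
            DispersionProfile(
                residue_id=rid, aa=aa, methyl_id=mid, field_label=lbl,
                nu=np.asarray(schedule.nu_cpmg, float), r2eff=y,
                sigma=np.full(len(curve), sigma),
            )
        )
    return out


class TestIndividualFit:
    def test_noiseless_round_trip(self, cluster1_params, fields, schedule):
        profs = make_profiles(cluster1_params, fields, schedule)
        res = fit_individual(profs, fields, schedule)
        assert res.converged
        assert res.params.k_ex == pytest.approx(cluster1_params.k_ex, rel=1e-3)
        assert res.params.p_B == pytest.approx(cluster1_params.p_B, rel=1e-3)
        assert res.params.dw_ppm == pytest.approx(cluster1_params.dw_ppm, rel=1e-3)
        for lbl in fields:
            assert res.params.r20(lbl) == pytest.approx(
                cluster1_params.r20(lbl), rel=1e-3
            )
        assert res.chi2 < 1e-10

    def test_noisy_recovery_within_mc_errors(self, cluster1_params, fields, schedule):
        rng = np.random.default_rng(42)
        profs = make_profiles(cluster1_params, fields, schedule, rng=rng)
        res = fit_individual(profs, fields, schedule)
        sig = res.monte_carlo(n_reps=50, seed=1)
        assert abs(res.params.k_ex - cluster1_params.k_ex) < 3 * sig["k_ex"]

    def test_flat_data_prefers_flat_model(self, fields, schedule):
        flat = ExchangeParams(k_ex=1000.0, p_B=0.0, dw_ppm=0.0,
                              r20_by_field={"11.7T": 12.0, "18.8T": 15.0})
        rng = np.random.default_rng(0)
        profs = make_profiles(flat, fields, schedule, rng=rng)
        model = MethylExchangeModel(profs, fields, schedule)
        ex, fl = model.fit(), model.fit_flat()
        rex = rex_observed(profs[1])
        assert model_select(ex, fl, rex=rex) == "flat"

    def test_exchange_selected_for_dispersing_data(self, cluster1_params, fields, schedule):
        rng = np.random.default_rng(5)
        profs = make_profiles(cluster1_params, fields, schedule, rng=rng)
        model = MethylExchangeModel(profs, fields, schedule)
        rex = rex_observed([p for p in profs if p.field_label == "18.8T"][0])
        assert model_select(model.fit(), model.fit_flat(), rex=rex) == "exchange"

    def test_alpha_zero_always_flat(self, cluster1_params, fields, schedule):
        profs = make_profiles(cluster1_params, fields, schedule)
        model = MethylExchangeModel(profs, fields, schedule)
        assert model_select(model.fit(), model.fit_flat(), alpha=0.0) == "flat"

    def test_too_few_points_rejected(self, cluster1_params, fields, schedule):
        profs = make_profiles(cluster1_params, fields, schedule)
        short = [
            DispersionProfile(
                residue_id=1, aa="L", methyl_id="a", field_label="18.8T",
                nu=profs[0].nu[:3], r2eff=profs[0].r2eff[:3], sigma=profs[0].sigma[:3],
            )
        ]
        with pytest.raises(InvalidInputError):
            MethylExchangeModel(short, fields, schedule)


class TestAcceptMember:
    @pytest.mark.parametrize("chi2_cluster,chi2_individual,expected", [
        (1.0, 1.0, True),
        (1.9, 1.0, True),   # boundary below 2
        (2.0, 1.0, False),  # strict inequality
        (2.1, 1.0, False),
        (0.0, 0.0, True),   # both ~0: treated as ratio 1
        (0.5, 0.0, False),  # individual perfect, cluster not
    ])
    def test_ratio_rule(self, chi2_cluster, chi2_individual, expected):
        assert accept_member(chi2_cluster, chi2_individual) is expected


class TestClusterByKex:
    def _fit_like(self, k_ex, key):
        res = type("R", (), {})()
        res.model = "exchange"
        res.converged = True
        res.params = ExchangeParams(k_ex=k_ex, p_B=0.05, dw_ppm=1.0)
        return key, res

    def test_all_equal_one_group(self):
        fits = dict(self._fit_like(1000.0, (i, "a")) for i in range(5))
        groups = cluster_by_kex(fits)
        assert len(groups) == 1 and len(groups[0]) == 5

    def test_two_planted_rates_split(self):
        fits = dict(
            [self._fit_like(1640.0 * (1 + e), (i, "a"))
             for i, e in enumerate((-0.05, 0.0, 0.04))]
            + [self._fit_like(420.0 * (1 + e), (10 + i, "a"))
               for i, e in enumerate((-0.03, 0.06))]
        )
        groups = cluster_by_kex(fits)
        assert len(groups) == 2
        assert {k[0] for k in groups[0]} == {0, 1, 2}
        assert {k[0] for k in groups[1]} == {10, 11}

    def test_single_fit_no_partition(self):
        fits = dict([self._fit_like(1000.0, (1, "a"))])
        assert cluster_by_kex(fits) == [[(1, "a")]]


class TestClusterGlobalFit:
    def _cluster_setup(self, fields, schedule, k_ex=1640.0, p_B=0.042,
                      dws=(0.6, 1.0, 1.4), rng=None, outlier=None):
        profiles_by_member, individual = {}, {}
        for i, dw in enumerate(dws):
            params = ExchangeParams(
                k_ex=k_ex if outlier != i else k_ex * 4.0,
                p_B=p_B, dw_ppm=dw,
                r20_by_field={"11.7T": 12.0 + i, "18.8T": 15.0 + i},
            )
            profs = make_profiles(params, fields, schedule, rid=50 + i, rng=rng)
            key = (50 + i, "a")
            profiles_by_member[key] = profs
            individual[key] = fit_individual(profs, fields, schedule)
        return profiles_by_member, individual

    def test_noiseless_round_trip_all_retained(self, fields, schedule):
        members, individual = self._cluster_setup(fields, schedule)
        res = ClusterExchangeModel(members, fields, schedule, individual).fit()
        assert not res.is_empty and not res.ejected
        assert res.k_ex == pytest.approx(1640.0, rel=1e-3)
        assert res.p_B == pytest.approx(0.042, rel=1e-3)
        for i, dw in enumerate((0.6, 1.0, 1.4)):
            assert res.dw_by_member[(50 + i, "a")] == pytest.approx(dw, rel=1e-3)

    def test_planted_outlier_ejected(self, fields, schedule):
        rng = np.random.default_rng(3)
        members, individual = self._cluster_setup(fields, schedule, rng=rng, outlier=2)
        res = ClusterExchangeModel(members, fields, schedule, individual).fit()
        assert (52, "a") in res.ejected
        assert set(res.member_ids) == {(50, "a"), (51, "a")}
        assert res.k_ex == pytest.approx(1640.0, rel=0.05)

    def test_identical_members_match_individual_fit(self, fields, schedule):
        params = ExchangeParams(k_ex=900.0, p_B=0.06, dw_ppm=1.1,
                                r20_by_field={"11.7T": 12.0, "18.8T": 15.0})
        profs = make_profiles(params, fields, schedule, rid=7)
        members = {(7, "a"): profs, (8, "a"): [
            DispersionProfile(
                residue_id=8, aa="L", methyl_id="a", field_label=p.field_label,
                nu=p.nu, r2eff=p.r2eff, sigma=p.sigma,
            ) for p in profs
        ]}
        individual = {k: fit_individual(v, fields, schedule) for k, v in members.items()}
        res = ClusterExchangeModel(members, fields, schedule, individual).fit()
        assert res.k_ex == pytest.approx(individual[(7, "a")].params.k_ex, rel=1e-4)
        assert res.p_B == pytest.approx(individual[(7, "a")].params.p_B, rel=1e-4)

    def test_objective_decreases_over_ejection_rounds(self, fields, schedule):
        rng = np.random.default_rng(9)
        members, individual = self._cluster_setup(fields, schedule, rng=rng, outlier=1)
        res = ClusterExchangeModel(members, fields, schedule, individual).fit()
        assert len(res.objective_history) >= 2
        assert np.all(np.diff(res.objective_history) < 0)

    def test_needs_two_members(self, fields, schedule, cluster1_params):
        profs = make_profiles(cluster1_params, fields, schedule)
        with pytest.raises(InvalidInputError):
            ClusterExchangeModel({(1, "a"): profs}, fields, schedule, {})


class TestMonteCarlo:
    def test_deterministic_under_seed(self, cluster1_params, fields, schedule):
        rng = np.random.default_rng(2)
        profs = make_profiles(cluster1_params, fields, schedule, rng=rng)
        res = fit_individual(profs, fields, schedule)
        s1 = dict(res.monte_carlo(n_reps=20, seed=123))
        s2 = dict(res.monte_carlo(n_reps=20, seed=123))
        assert s1 == s2

    def test_sigmas_shrink_with_noise(self, cluster1_params, fields, schedule):
        """Near-noiseless data must give near-zero parameter uncertainties."""
        profs = make_profiles(cluster1_params, fields, schedule, sigma=1e-3)
        res = fit_individual(profs, fields, schedule)
        sig = res.monte_carlo(n_reps=20, seed=0)
        assert sig["k_ex"] < 1.0       # s^-1, vs ~1e3 scale
        assert sig["p_B"] < 1e-4
        assert sig["dw_ppm"] < 1e-3
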