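"""Branching-flux model: loading, site probabilities, flux, Monte Carlo."""

import math

import numpy as np
import pytest

from magscan import (
    AugKnockout,
    ConstructSpec,
    ContextResponse,
    FuseReporter,
    InputError,
    ParameterError,
    ScanningParams,
    StopKnockout,
    annotate,
    apply_mutation,
    closed_form_flux,
    loading_rate,
    make_leader_fixture,
    simulate_scanning,
    site_init_prob,
)
from magscan.simulate import GEOMETRY_PRESETS, GeometrySpec


def _params(strong=0.5, adequate=(0.05, 0.95, 0.8, 0.1), q=0.2, **kw):
    return ScanningParams(
        loading_amp=kw.get("amp", 100.0),
        loading_center=kw.get("center", (0.8, 1.0 / 300.0)),
        loading_width=kw.get("width", 0.25),
        contexts={
            "strong": ContextResponse(strong, strong, 0.8, 1.0),
            "adequate": ContextResponse(*adequate),
            "weak": ContextResponse(0.02, 0.5, 1.0, 0.15),
        },
        reinit_prob=q,
        uncapped_scale=kw.get("eps", 0.05),
    )


class TestLoadingRate:
    def test_peak_equals_amplitude(self, simple_params):
        c = simple_params.center(60.0)
        assert loading_rate(simple_params, c, 60.0) == pytest.approx(100.0)

    def test_optimum_shifts_up_with_potassium(self, simple_params):
        mg = np.linspace(0.2, 2.0, 400)
        argmax = {
            k: mg[np.argmax([loading_rate(simple_params, m, k) for m in mg])]
            for k in (60.0, 150.0)
        }
        assert argmax[150.0] > argmax[60.0]

    def test_uncapped_scaling(self):
        p = _params(eps=0.0)
        assert loading_rate(p, 0.9, 60.0, capped=False) == 0.0
        p2 = _params(eps=0.05)
        assert loading_rate(p2, 0.9, 60.0, capped=False) == pytest.approx(
            0.05 * loading_rate(p2, 0.9, 60.0, capped=True)
        )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            _params(width=0.0)


class TestSiteInitProb:
    def test_low_mg_tail_is_floor(self):
        p = _params(adequate=(0.05, 0.95, 1.0, 0.05))
        mg = 1.0 - 10 * 0.05  # ten steepness units below the midpoint
        assert site_init_prob(p, "adequate", mg) == pytest.approx(
            0.05, abs=1e-4
        )

    def test_midpoint_is_halfway(self, simple_params):
        ctx = simple_params.context("adequate")
        assert site_init_prob(
            simple_params, "adequate", ctx.midpoint
        ) == pytest.approx((ctx.floor + ctx.ceil) / 2)

    def test_adequate_rises_with_mg(self, simple_params):
        assert site_init_prob(simple_params, "adequate", 1.4) > site_init_prob(
            simple_params, "adequate", 0.6
        )

    def test_monotone_nondecreasing(self, simple_params):
        mg = np.linspace(0.1, 2.5, 100)
        for cls in ("strong", "adequate", "weak"):
            p = [site_init_prob(simple_params, cls, m) for m in mg]
            assert np.all(np.diff(p) >= -1e-15)

    def test_unknown_class_rejected(self, simple_params):
        with pytest.raises(ParameterError, match="unknown context class"):
            site_init_prob(simple_params, "superb", 0.8)

    def test_strong_class_flat_over_assay_range(self, paper_params):
        p = [site_init_prob(paper_params, "strong", m) for m in (0.2, 0.8, 1.4)]
        assert max(p) - min(p) < 0.05


class TestClosedFormFlux:
    def test_no_uorf_engagement(self, constructs, simple_params):
        # both uAUGs knocked out: flux = loading x p_main
        c = constructs["1AUC2AUC-Luc-M7"]
        fr = closed_form_flux(c, simple_params, 0.8, 60.0)
        expect = loading_rate(simple_params, 0.8, 60.0) * 0.5
        assert fr.reporter_flux == pytest.approx(expect)

    def test_full_sequestration_zero_flux(self, constructs):
        p = _params(strong=1.0)  # uAUG1 always initiates; uORF1 overlaps
        fr = closed_form_flux(constructs["M7-Luc-M7"], p, 0.8, 60.0)
        assert fr.reporter_flux == 0.0

    def test_wild_type_algebra(self, constructs, simple_params):
        # flux = L (1-p1) [1-p2 + p2 q] p_main on the two-uORF leader
        mg, k = 1.0, 60.0
        p1 = site_init_prob(simple_params, "strong", mg)
        p2 = site_init_prob(simple_params, "adequate", mg)
        q = simple_params.reinit_prob
        expect = (
            loading_rate(simple_params, mg, k)
            * (1 - p1) * (1 - p2 + p2 * q) * p1
        )
        fr = closed_form_flux(constructs["M7-Luc-M7"], simple_params, mg, k)
        assert fr.reporter_flux == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("name", [
        "M7-Luc-M7", "beta-Luc-M7", "1AUC-Luc-M7", "2AUC-Luc-M7",
        "1AUC2AUC-Luc-M7", "2stopCGA-Luc-M7", "2ndLuc-M7",
    ])
    @pytest.mark.parametrize("mg", [0.2, 0.8, 1.4])
    def test_branch_probabilities_conserve_mass(
        self, constructs, simple_params, name, mg
    ):
        fr = closed_form_flux(constructs[name], simple_params, mg, 90.0)
        assert sum(fr.branch_probabilities.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_flux_nonincreasing_in_uaug1_probability(self):
        # leader whose uAUG1 is adequate-context so its probability can
        # be moved without touching the (strong) main AUG
        spec = GeometrySpec(
            name="adeq-first",
            length=200,
            main_start=101,
            uaug_positions=(21,),
            uorf_lengths=(120,),   # overlaps the main ORF
            contexts=(("U", "G"),),
        )
        construct = ConstructSpec(
            name="adeq-first", annotation=annotate(make_leader_fixture(spec, 3))
        )
        fluxes = []
        for level in np.linspace(0.0, 1.0, 11):
            p = _params(adequate=(level, level, 0.8, 0.1))
            fluxes.append(
                closed_form_flux(construct, p, 0.9, 60.0).reporter_flux
            )
        assert np.all(np.diff(fluxes) <= 1e-12)

    def test_fused_reporter_branch_algebra(self, constructs, simple_params):
        mg = 1.1
        p1 = site_init_prob(simple_params, "strong", mg)
        p2 = site_init_prob(simple_params, "adequate", mg)
        fr = closed_form_flux(constructs["2ndLuc-M7"], simple_params, mg, 60.0)
        expect = loading_rate(simple_params, mg, 60.0) * (1 - p1) * p2
        assert fr.reporter_flux == pytest.approx(expect, rel=1e-12)

    def test_stop_knockout_sequesters(self, constructs, simple_params):
        mg = 1.0
        p1 = site_init_prob(simple_params, "strong", mg)
        p2 = site_init_prob(simple_params, "adequate", mg)
        fr = closed_form_flux(
            constructs["2stopCGA-Luc-M7"], simple_params, mg, 60.0
        )
        expect = loading_rate(simple_params, mg, 60.0) * (1 - p1) * (1 - p2) * p1
        assert fr.reporter_flux == pytest.approx(expect, rel=1e-12)


class TestMutations:
    def test_double_knockout_equals_no_uorf_leader(
        self, constructs, simple_params
    ):
        # with the same (strong) main context, the double knockout and
        # the beta-globin-like leader give identical flux at any point
        for mg in (0.4, 0.8, 1.2):
            a = closed_form_flux(
                constructs["1AUC2AUC-Luc-M7"], simple_params, mg, 60.0
            ).reporter_flux
            b = closed_form_flux(
                constructs["beta-Luc-M7"], simple_params, mg, 60.0
            ).reporter_flux
            assert a == pytest.approx(b, rel=1e-12)

    def test_unknown_positions_rejected(self, constructs):
        with pytest.raises(InputError):
            apply_mutation(constructs["M7-Luc-M7"], AugKnockout(999))
        with pytest.raises(InputError):
            apply_mutation(constructs["M7-Luc-M7"], StopKnockout(999))
        with pytest.raises(InputError):
            apply_mutation(constructs["M7-Luc-M7"], FuseReporter(999))

    def test_mutations_do_not_mutate_in_place(self, constructs):
        wt = constructs["M7-Luc-M7"]
        mut = apply_mutation(wt, AugKnockout(101))
        assert wt.knocked_out_augs == frozenset()
        assert mut.knocked_out_augs == frozenset({101})


class TestFittedPresetBehaviour:
    """Directional claims the fitted preset must reproduce."""

    MG = np.round(np.arange(0.2, 1.41, 0.2), 1)

    def _profile(self, constructs, params, name, k):
        return np.array([
            closed_form_flux(constructs[name], params, mg, k).reporter_flux
            for mg in self.MG
        ])

    def test_knockout_dominance(self, constructs, paper_params):
        # removing both uAUGs can only help the reporter, everywhere
        for k in (60.0, 90.0, 120.0, 150.0):
            wt = self._profile(constructs, paper_params, "M7-Luc-M7", k)
            ko = self._profile(constructs, paper_params, "1AUC2AUC-Luc-M7", k)
            assert np.all(ko >= wt - 1e-12)

    def test_double_knockout_shifts_optimum_up(self, constructs, paper_params):
        from magscan import fit_bell

        wt = fit_bell(
            self.MG, self._profile(constructs, paper_params, "M7-Luc-M7", 60.0)
        ).optimum
        ko = fit_bell(
            self.MG,
            self._profile(constructs, paper_params, "1AUC2AUC-Luc-M7", 60.0),
        ).optimum
        assert ko > wt

    def test_uorf2_reporter_has_higher_optimum(self, constructs, paper_params):
        from magscan import fit_bell

        wt = fit_bell(
            self.MG, self._profile(constructs, paper_params, "M7-Luc-M7", 60.0)
        ).optimum
        uorf2 = fit_bell(
            self.MG, self._profile(constructs, paper_params, "2ndLuc-M7", 60.0)
        ).optimum
        assert uorf2 > wt

    def test_no_uorf_optimum_strictly_increases_with_k(
        self, constructs, paper_params
    ):
        from magscan import fit_bell

        optima = [
            fit_bell(
                self.MG,
                self._profile(constructs, paper_params, "beta-Luc-M7", k),
            ).optimum
            for k in (60.0, 90.0, 120.0, 150.0)
        ]
        assert np.all(np.diff(optima) > 0)


class TestMonteCarlo:
    def test_single_ribosome_outcome(self, constructs, simple_params):
        fr = simulate_scanning(
            constructs["M7-Luc-M7"], simple_params, 0.8, 60.0, 1, seed=5
        )
        load = loading_rate(simple_params, 0.8, 60.0)
        assert fr.reporter_flux in (0.0, pytest.approx(load))

    def test_seed_reproducibility(self, constructs, simple_params):
        a = simulate_scanning(
            constructs["M7-Luc-M7"], simple_params, 0.8, 60.0, 5000, seed=7
        )
        b = simulate_scanning(
            constructs["M7-Luc-M7"], simple_params, 0.8, 60.0, 5000, seed=7
        )
        assert a.branch_probabilities == b.branch_probabilities

    def test_deterministic_params_exact(self, constructs):
        p = _params(strong=1.0, adequate=(0.0, 0.0, 0.8, 0.1), q=0.0)
        cf = closed_form_flux(constructs["M7-Luc-M7"], p, 0.8, 60.0)
        mc = simulate_scanning(constructs["M7-Luc-M7"], p, 0.8, 60.0, 37, seed=1)
        assert mc.reporter_flux == cf.reporter_flux == 0.0
        assert mc.branch_probabilities == cf.branch_probabilities

    @pytest.mark.parametrize("name", ["M7-Luc-M7", "2stopCGA-Luc-M7", "2ndLuc-M7"])
    def test_agrees_with_closed_form_within_3_sigma(
        self, constructs, paper_params, name
    ):
        n = 200_000
        cf = closed_form_flux(constructs[name], paper_params, 0.8, 60.0)
        mc = simulate_scanning(
            constructs[name], paper_params, 0.8, 60.0, n, seed=42
        )
        for branch, p in cf.branch_probabilities.items():
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(mc.branch_probabilities.get(branch, 0.0) - p) <= 3 * se
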