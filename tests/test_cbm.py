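"""FBA / pFBA / FVA, media conversion, knockouts, and concordance scoring.

The packaged toy network has a hand-derived optimum mu(A, C) = min(A/3, C);
cobrapy serves as an independent solver cross-check, never as the
implementation under test.
"""

import math

import numpy as np
import pytest
from scipy import optimize

from elenta import cbm, synth


class TestModelIO:
    def test_json_roundtrip(self, tmp_path, toy_spec_full):
        path = tmp_path / "toy.json"
        cbm.save_model(toy_spec_full.model, path)
        back = cbm.load_model(path)
        m = toy_spec_full.model
        assert set(back.reactions) == set(m.reactions)
        assert set(back.metabolites) == set(m.metabolites)
        assert back.genes == m.genes
        assert back.objective_reaction_id == m.objective_reaction_id
        for rid in m.reactions:
            assert back.reactions[rid].stoichiometry == m.reactions[rid].stoichiometry
            assert back.reactions[rid].lower_bound == m.reactions[rid].lower_bound
            assert back.reactions[rid].gpr == m.reactions[rid].gpr

    def test_sbml_roundtrip(self, tmp_path, toy_spec):
        path = tmp_path / "toy.xml"
        cbm.save_model(toy_spec.model, path)
        back = cbm.load_model(path, dialect="sbml-fbc")
        m = toy_spec.model
        assert set(back.reactions) == set(m.reactions)
        assert len(back.metabolites) == len(m.metabolites)
        assert back.objective_reaction_id == m.objective_reaction_id
        for rid in m.reactions:
            assert back.reactions[rid].lower_bound == pytest.approx(m.reactions[rid].lower_bound)
            assert back.reactions[rid].upper_bound == pytest.approx(m.reactions[rid].upper_bound)
        assert cbm.fba(back).mu == pytest.approx(cbm.fba(m).mu, abs=1e-9)

    def test_missing_objective_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"metabolites": [], "reactions": [], "objective": ""}')
        with pytest.raises(ValueError, match="objective"):
            cbm.load_model(path)

    def test_dangling_metabolite_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolite"):
            cbm.MetabolicModel(
                id="bad",
                metabolites={"a": cbm.Metabolite("a")},
                reactions={"r": cbm.Reaction("r", {"a": -1, "ghost": 1})},
                objective_reaction_id="r",
            )


class TestMediaToBounds:
    def test_uptake_formula(self, toy_spec):
        media = cbm.MediaDefinition(
            quantitative={"EX_arg_e": 1.0}, biomass_density=0.01, duration=10.0
        )
        assert media.uptake_rate(1.0) == pytest.approx(10.0)  # 1 mM / (0.01 gDW/L x 10 h)
        out, missing = cbm.media_to_bounds(toy_spec.model, media)
        assert out.reactions["EX_arg_e"].lower_bound == pytest.approx(-10.0)
        assert missing == []

    def test_qualitative_bound_and_closed_exchanges(self, toy_spec):
        media = cbm.MediaDefinition(
            quantitative={}, qualitative={"EX_ac_e"}, biomass_density=0.01, duration=10.0
        )
        out, _ = cbm.media_to_bounds(toy_spec.model, media)
        assert out.reactions["EX_ac_e"].lower_bound == -1.0
        # unlisted exchanges closed to uptake, secretion untouched
        assert out.reactions["EX_arg_e"].lower_bound == 0.0
        assert out.reactions["EX_orn_e"].upper_bound == 1000

    def test_zero_concentration_closes_uptake(self, toy_spec):
        media = cbm.MediaDefinition(quantitative={"EX_arg_e": 0.0})
        out, _ = cbm.media_to_bounds(toy_spec.model, media)
        assert out.reactions["EX_arg_e"].lower_bound == 0.0

    def test_missing_exchange_reported(self, toy_spec):
        media = cbm.MediaDefinition(quantitative={"EX_nothere": 5.0})
        _, missing = cbm.media_to_bounds(toy_spec.model, media)
        assert missing == ["EX_nothere"]

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="biomass_density"):
            cbm.MediaDefinition(quantitative={}, biomass_density=0.0)


class TestFba:
    def test_matches_closed_form_at_defaults(self, toy_spec):
        sol = cbm.fba(toy_spec.model)
        assert sol.status == "optimal"
        assert sol.mu == pytest.approx(toy_spec.closed_form_mu(10.0, 1.0), abs=1e-6)

    def test_closed_form_over_uptake_grid(self):
        for A in [0.0, 1.0, 3.0, 6.0, 12.0]:
            for C in [0.0, 0.5, 1.0, 2.0, 5.0]:
                spec = synth.gen_toy_model(arginine_uptake=A, acetate_uptake=C)
                sol = cbm.fba(spec.model)
                assert sol.mu == pytest.approx(spec.closed_form_mu(A, C), abs=1e-6)

    def test_all_uptakes_closed_no_growth(self):
        spec = synth.gen_toy_model(arginine_uptake=0.0, acetate_uptake=0.0)
        assert cbm.fba(spec.model).mu == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_and_bounds(self, toy_spec_full):
        sol = cbm.fba(toy_spec_full.model)
        m = toy_spec_full.model
        S = m.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in m.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6
        for rid in m.reaction_ids:
            r = m.reactions[rid]
            assert r.lower_bound - 1e-9 <= sol.fluxes[rid] <= r.upper_bound + 1e-9

    def test_agmatine_replaces_arginine(self):
        spec = synth.gen_toy_model(arginine_uptake=0.0, acetate_uptake=1.0,
                                   agmatine_uptake=6.0)
        sol = cbm.fba(spec.model)
        assert sol.mu == pytest.approx(spec.closed_form_mu(0.0, 1.0, 6.0), abs=1e-6)
        assert sol.mu > 0

    def test_cross_check_against_cobrapy(self, toy_spec_full):
        cobra = pytest.importorskip("cobra")
        m = toy_spec_full.model
        cm = cobra.Model("toy")
        cm.add_metabolites([cobra.Metabolite(mid) for mid in m.metabolite_ids])
        rxns = []
        for rid, r in m.reactions.items():
            cr = cobra.Reaction(rid, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            rxns.append(cr)
        cm.add_reactions(rxns)
        for rid, r in m.reactions.items():
            cm.reactions.get_by_id(rid).add_metabolites(
                {cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()}
            )
        cm.objective = cm.reactions.get_by_id(m.objective_reaction_id)
        assert cbm.fba(m).mu == pytest.approx(cm.slim_optimize(), abs=1e-6)


class TestPfba:
    def test_matches_fba_flux_when_optimum_unique(self, toy_spec):
        f = cbm.fba(toy_spec.model)
        p = cbm.pfba(toy_spec.model)
        for rid in toy_spec.model.reaction_ids:
            assert p.fluxes[rid] == pytest.approx(f.fluxes[rid], abs=1e-6)

    def test_futile_cycle_zeroed(self, toy_spec_full):
        p = cbm.pfba(toy_spec_full.model)
        assert abs(p.fluxes["FC1"]) < 1e-9
        assert abs(p.fluxes["FC2"]) < 1e-9

    def test_total_flux_not_above_fba(self, toy_spec_full):
        f = cbm.fba(toy_spec_full.model)
        p = cbm.pfba(toy_spec_full.model)
        assert sum(abs(v) for v in p.fluxes.values()) <= sum(abs(v) for v in f.fluxes.values()) + 1e-6
        assert p.mu == pytest.approx(f.mu, abs=1e-9)


def _fva_oracle(model, fraction=0.99):
    """Independent per-reaction two-LP oracle built directly from arrays."""
    rids = model.reaction_ids
    mets = model.metabolite_ids
    S = np.zeros((len(mets), len(rids)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(rids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[midx[met], j] = coef
    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound) for r in rids]
    c = np.zeros(len(rids))
    c[rids.index(model.objective_reaction_id)] = -1.0
    base = optimize.linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    mu = -base.fun
    A_ub = c.reshape(1, -1)  # -mu(v) <= -fraction * mu*
    b_ub = np.array([-fraction * mu])
    out = {}
    for j, rid in enumerate(rids):
        obj = np.zeros(len(rids))
        obj[j] = 1.0
        lo = optimize.linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(len(mets)),
                              bounds=bounds, method="highs")
        hi = optimize.linprog(-obj, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(len(mets)),
                              bounds=bounds, method="highs")
        out[rid] = (lo.fun, -hi.fun)
    return out


class TestFva:
    def test_matches_independent_oracle(self, toy_spec_full):
        ranges = cbm.fva(toy_spec_full.model, fraction=0.99)
        oracle = _fva_oracle(toy_spec_full.model, fraction=0.99)
        for r in ranges:
            lo, hi = oracle[r.reaction_id]
            assert r.min_flux == pytest.approx(lo, abs=1e-9)
            assert r.max_flux == pytest.approx(hi, abs=1e-9)

    def test_objective_range(self, toy_spec):
        mu = cbm.fba(toy_spec.model).mu
        ranges = {r.reaction_id: r for r in cbm.fva(toy_spec.model, fraction=0.99)}
        obj = ranges["BIOMASS"]
        assert obj.min_flux == pytest.approx(0.99 * mu, abs=1e-8)
        assert obj.max_flux == pytest.approx(mu, abs=1e-8)

    def test_pfba_within_fva_ranges(self, toy_spec_full):
        p = cbm.pfba(toy_spec_full.model)
        for r in cbm.fva(toy_spec_full.model, fraction=0.99):
            assert r.min_flux - 1e-8 <= p.fluxes[r.reaction_id] <= r.max_flux + 1e-8

    def test_cross_check_against_cobrapy(self, toy_spec):
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        m = toy_spec.model
        cm = cobra.Model("toy")
        cm.add_metabolites([cobra.Metabolite(mid) for mid in m.metabolite_ids])
        cm.add_reactions([
            cobra.Reaction(rid, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            for rid, r in m.reactions.items()
        ])
        for rid, r in m.reactions.items():
            cm.reactions.get_by_id(rid).add_metabolites(
                {cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()}
            )
        cm.objective = cm.reactions.get_by_id(m.objective_reaction_id)
        ref = flux_variability_analysis(cm, fraction_of_optimum=0.99)
        for r in cbm.fva(m, fraction=0.99):
            assert r.min_flux == pytest.approx(ref.loc[r.reaction_id, "minimum"], abs=1e-6)
            assert r.max_flux == pytest.approx(ref.loc[r.reaction_id, "maximum"], abs=1e-6)

    def test_no_growth_rejected(self):
        spec = synth.gen_toy_model(arginine_uptake=0.0, acetate_uptake=0.0)
        with pytest.raises(ValueError, match="mu > 0"):
            cbm.fva(spec.model)


class TestLeaveOneOut:
    def _media(self):
        return cbm.MediaDefinition(
            quantitative={"EX_arg_e": 1.0, "EX_ac_e": 0.1},
            biomass_density=0.01, duration=10.0,
        )

    def test_removing_atp_source_kills_growth(self, toy_spec):
        loo = cbm.simulate_leave_one_out(toy_spec.model, self._media())
        assert loo["EX_arg_e"] == pytest.approx(0.0, abs=1e-9)
        assert loo["EX_ac_e"] == pytest.approx(0.0, abs=1e-9)  # sole carbon source

    def test_redundant_substrate_no_effect(self):
        # agmatine variant: arginine and agmatine are interchangeable ATP sources
        spec = synth.gen_toy_model(arginine_uptake=10.0, acetate_uptake=1.0,
                                   agmatine_uptake=10.0)
        media = cbm.MediaDefinition(
            quantitative={"EX_arg_e": 30.0, "EX_ac_e": 0.1, "EX_agm_e": 30.0},
            biomass_density=0.01, duration=10.0,
        )
        loo = cbm.simulate_leave_one_out(spec.model, media)
        full, _ = cbm.media_to_bounds(spec.model, media)
        mu_full = cbm.fba(full).mu
        assert loo["EX_arg_e"] == pytest.approx(mu_full, abs=1e-8)

    def test_removal_never_increases_growth(self, toy_spec):
        media = self._media()
        full, _ = cbm.media_to_bounds(toy_spec.model, media)
        mu_full = cbm.fba(full).mu
        for mu in cbm.simulate_leave_one_out(toy_spec.model, media).values():
            assert mu <= mu_full + 1e-9

    def test_unknown_compound_rejected(self, toy_spec):
        with pytest.raises(ValueError, match="not in media"):
            cbm.simulate_leave_one_out(toy_spec.model, self._media(), ["EX_bogus"])


class TestGrowthConfusion:
    def test_perfect_agreement(self):
        pred = {f"c{i}": i < 5 for i in range(10)}
        s = cbm.growth_confusion(pred, dict(pred))
        assert s.mcc == pytest.approx(1.0)
        assert (s.tp, s.tn, s.fp, s.fn) == (5, 5, 0, 0)

    def test_degenerate_all_growth_prediction(self):
        pred = {f"c{i}": True for i in range(10)}
        obs = {f"c{i}": i < 5 for i in range(10)}
        assert cbm.growth_confusion(pred, obs).mcc == 0.0

    def test_mcc_formula(self):
        pred, obs = {}, {}
        # construct tp=8, fp=2, fn=1, tn=4
        i = 0
        for _ in range(8):
            pred[f"c{i}"], obs[f"c{i}"] = True, True; i += 1
        for _ in range(2):
            pred[f"c{i}"], obs[f"c{i}"] = True, False; i += 1
        for _ in range(1):
            pred[f"c{i}"], obs[f"c{i}"] = False, True; i += 1
        for _ in range(4):
            pred[f"c{i}"], obs[f"c{i}"] = False, False; i += 1
        s = cbm.growth_confusion(pred, obs)
        assert s.mcc == pytest.approx(30 / math.sqrt(2700))  # 0.5774
        assert 0 <= s.fisher_p <= 1 and s.odds_ratio > 1


class TestKnockouts:
    def test_objective_knockout_essential(self, toy_spec):
        kos = {k.reaction_id: k for k in cbm.single_reaction_knockouts(toy_spec.model)}
        assert kos["BIOMASS"].category == "essential"

    def test_carbamate_kinase_step_essential(self, toy_spec):
        kos = {k.reaction_id: k for k in cbm.single_reaction_knockouts(toy_spec.model)}
        assert kos["CK"].category == "essential"  # sole ATP source
        assert kos["CK"].below_70pct

    def test_blocked_reaction_neutral(self, toy_spec_full):
        ranges = {r.reaction_id: r for r in cbm.fva(toy_spec_full.model, fraction=1.0)}
        kos = {k.reaction_id: k for k in cbm.single_reaction_knockouts(toy_spec_full.model)}
        for rid, r in ranges.items():
            if abs(r.min_flux) < 1e-10 and abs(r.max_flux) < 1e-10:
                assert kos[rid].category == "neutral"


class TestFvaExchangeConcordance:
    def _ranges(self):
        return [
            cbm.FvaRange("EX_a", -5.0, 0.0),
            cbm.FvaRange("EX_b", 0.0, 3.0),
            cbm.FvaRange("EX_c", -5.0, 0.0),
        ]

    def test_verdicts(self):
        frac, df = cbm.fva_exchange_concordance(
            self._ranges(),
            {"a": "decreased", "b": "increased", "c": "increased", "d": "increased"},
            {"a": "EX_a", "b": "EX_b", "c": "EX_c"},
        )
        v = df.set_index("metabolite")["verdict"]
        assert v["a"] == "compatible"      # import-only, decreased
        assert v["b"] == "compatible"      # secretable, increased
        assert v["c"] == "incompatible"    # import-only but increased
        assert v["d"] == "unmapped"
        assert frac == pytest.approx(2 / 3)


class TestFluxExpressionConcordance:
    def test_rank_identical_rho_one(self, toy_spec_full):
        p = cbm.pfba(toy_spec_full.model)
        m = toy_spec_full.model
        expression = {}
        for rid, r in m.reactions.items():
            for g in r.genes():
                expression[g] = abs(p.fluxes[rid]) + 0.001 * hash(g) % 1 * 1e-6
        out = cbm.flux_expression_concordance(p, expression, m)
        assert out["spearman_rho"] > 0.9

    def test_shuffled_expression_uncorrelated(self, toy_spec_full):
        p = cbm.pfba(toy_spec_full.model)
        m = toy_spec_full.model
        genes = sorted({g for r in m.reactions.values() for g in r.genes()})
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(50):
            expression = dict(zip(genes, rng.permutation(len(genes)).astype(float)))
            out = cbm.flux_expression_concordance(p, expression, m)
            rhos.append(abs(out["spearman_rho"]))
        # with few genes the null spread is wide; just check centering near 0
        assert np.median(rhos) < 0.5

    def test_requires_pairs(self, toy_spec):
        p = cbm.pfba(toy_spec.model)
        with pytest.raises(ValueError, match=">= 10"):
            cbm.flux_expression_concordance(p, {"nope": 1.0}, toy_spec.model)


class TestKnockoutConservation:
    def test_planted_separation_detected(self, toy_spec_full):
        kos = cbm.single_reaction_knockouts(toy_spec_full.model)
        m = toy_spec_full.model
        effect_rxns = {k.reaction_id for k in kos if k.below_70pct}
        presence, core = {}, {}
        rng = np.random.default_rng(1)
        for rid, r in m.reactions.items():
            for g in r.genes():
                if rid in effect_rxns:
                    presence[g], core[g] = 1.0, True
                else:
                    presence.setdefault(g, float(rng.uniform(0.3, 0.7)))
                    core.setdefault(g, False)
        out = cbm.knockout_conservation_test(kos, m, presence, core)
        assert out["wilcoxon_p"] < 0.05
        assert out["fisher_or"] == math.inf or out["fisher_or"] > 1

    def test_planted_separation_power_at_n50(self):
        # rank-sum power check at the planted presence split 1.0 vs ~0.5
        rng = np.random.default_rng(2)
        from scipy import stats as sstats

        hits = 0
        for _ in range(20):
            eff = np.ones(50)
            oth = rng.uniform(0.3, 0.7, 50)
            p = sstats.mannwhitneyu(eff, oth, alternative="two-sided").pvalue
            hits += p < 0.01
        assert hits == 20

    def test_empty_partition_rejected(self, toy_spec):
        kos = [k for k in cbm.single_reaction_knockouts(toy_spec.model) if not k.below_70pct]
        with pytest.raises(ValueError, match="partition"):
            cbm.knockout_conservation_test(kos, toy_spec.model, {"g_adi": 1.0}, {"g_adi": True})
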