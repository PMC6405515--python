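import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from liverflux.constraints import ConditionBounds, apply_condition
from liverflux.errors import (
    DegenerateScoreError,
    InfeasibleError,
    ValidationError,
)
from liverflux.netmodel import Metabolite, NetworkModel, Reaction
from liverflux.timbr import (
    STATUS_OK,
    STATUS_ZERO,
    DemandProblem,
    ScoreTable,
    max_production_capability,
    minimum_total_flux,
    production_demand,
    raw_score,
    run_timbr,
    z_transform,
)

from conftest import random_small_model
from _oracles import oracle_max_flux, oracle_min_weighted_abs


class TestMaxCapability:
    def test_bottleneck_bound(self, chain_model):
        assert max_production_capability(chain_model, "B") == pytest.approx(10.0)

    def test_no_producing_reaction_gives_zero(self):
        model = NetworkModel(
            [Metabolite("A"), Metabolite("P")],
            [Reaction("EX_A", {"A": -1}, -10, 0), Reaction("EX_P", {"P": -1}, 0, 100)],
        )
        assert max_production_capability(model, "P") == 0.0

    def test_temporary_exchange_added_when_absent(self, chain_model):
        # B's own exchange removed: a temp secretion route must be synthesized
        model = NetworkModel(
            chain_model.metabolites,
            [r for r in chain_model.reactions if r.id != "EX_B"],
        )
        assert max_production_capability(model, "B") == pytest.approx(10.0)

    def test_contradictory_bounds_raise_infeasible(self):
        model = NetworkModel(
            [Metabolite("P")],
            [Reaction("EX_P", {"P": -1}, 5.0, 10.0)],  # forced secretion, no source
        )
        with pytest.raises(InfeasibleError):
            max_production_capability(model, "P")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_vertex_enumeration_oracle(self, seed):
        model = random_small_model(np.random.default_rng(seed), n_rxns=6)
        lb, ub = model.bounds_arrays()
        S = model.S.toarray()
        for j, rxn in enumerate(model.reactions):
            if not rxn.is_exchange:
                continue
            met = next(iter(rxn.stoichiometry))
            if rxn.stoichiometry[met] >= 0:
                continue
            expected = oracle_max_flux(S, lb, ub, j)
            if expected is None:
                continue
            got = max_production_capability(model, met)
            assert got == pytest.approx(max(0.0, expected), abs=1e-6)


class TestProductionDemand:
    def test_chain_full_capability(self, chain_model):
        x, status = production_demand(DemandProblem(chain_model, "B", 1.0))
        assert status == STATUS_OK
        assert x == pytest.approx(30.0, abs=1e-6)  # three reactions x flux 10

    def test_chain_half_capability(self, chain_model):
        x, status = production_demand(DemandProblem(chain_model, "B", 0.5))
        assert x == pytest.approx(15.0, abs=1e-6)  # single path is linear

    def test_zero_capability_flagged_without_lp(self):
        model = NetworkModel(
            [Metabolite("P")], [Reaction("EX_P", {"P": -1}, 0, 100)]
        )
        x, status = production_demand(DemandProblem(model, "P", 0.9))
        assert status == STATUS_ZERO and math.isnan(x)

    def test_shorter_route_wins(self):
        """Given a 2-step and a 3-step internal route, the cheaper one carries flux."""
        mets = [Metabolite(m) for m in ("A", "C", "P")]
        rxns = [
            Reaction("EX_A", {"A": -1}, -5, 0),
            Reaction("DIRECT", {"A": -1, "P": 1}),        # 2-step: DIRECT + EX_P
            Reaction("VIA1", {"A": -1, "C": 1}),          # 3-step detour
            Reaction("VIA2", {"C": -1, "P": 1}),
            Reaction("EX_P", {"P": -1}, 0, 100),
        ]
        model = NetworkModel(mets, rxns)
        x, v = minimum_total_flux(model, "EX_P", 5.0)
        # uptake 5 + DIRECT 5 + EX_P 5; the detour would add 5 more
        assert x == pytest.approx(15.0, abs=1e-6)
        names = dict(zip(model.reaction_ids, v))
        assert names["DIRECT"] == pytest.approx(5.0, abs=1e-6)
        assert names["VIA1"] == pytest.approx(0.0, abs=1e-6)

    def test_negative_weight_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="weight"):
            minimum_total_flux(chain_model, "EX_B", 1.0, weights={"CONV": -1.0})

    def test_steady_state_residual_small(self, toy):
        model = apply_condition(toy.model, toy.cb_early)
        x, v = minimum_total_flux(model, "EX_ket", 3.0)
        resid = np.abs(model.S.toarray() @ v).max()
        assert resid <= 1e-6 * max(1.0, np.abs(v).max())

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_orthant_vertex_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = random_small_model(rng, n_rxns=5)
        S = model.S.toarray()
        lb, ub = model.bounds_arrays()
        for j, rxn in enumerate(model.reactions):
            if not (rxn.is_exchange and rxn.stoichiometry[next(iter(rxn.stoichiometry))] < 0):
                continue
            met = next(iter(rxn.stoichiometry))
            cap = max_production_capability(model, met)
            if cap <= 1e-9:
                continue
            req = 0.5 * cap
            lb2 = lb.copy()
            lb2[j] = max(lb2[j], req)
            expected = oracle_min_weighted_abs(S, lb2, ub, np.ones(len(lb)))
            got, _ = minimum_total_flux(model, rxn.id, req)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_no_sampled_point_beats_the_optimum(self, toy):
        """Random feasible vectors never undercut the reported demand."""
        model = apply_condition(toy.model, toy.cb_early)
        req = 0.9 * max_production_capability(model, "ket")
        x_opt, _ = minimum_total_flux(model, "EX_ket", req)
        rng = np.random.default_rng(0)
        n = len(model.reactions)
        samples = []
        for _ in range(100):
            c = rng.normal(size=n)
            _, v = _feasible_vertex(model, "EX_ket", req, c)
            samples.append(v)
        # random convex combinations stay feasible (polytope) — check them too
        for _ in range(50):
            w = rng.dirichlet(np.ones(4))
            idx = rng.choice(len(samples), 4, replace=False)
            samples.append(sum(wi * samples[i] for wi, i in zip(w, idx)))
        for v in samples:
            assert np.abs(v).sum() >= x_opt - 1e-6


def _feasible_vertex(model, ex_id, req, objective):
    from scipy.optimize import linprog

    lb, ub = model.bounds_arrays()
    j = model.reaction_index(ex_id)
    lb[j] = max(lb[j], req)
    res = linprog(
        objective, A_eq=model.S, b_eq=np.zeros(len(model.metabolites)),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    assert res.status == 0
    return res.fun, res.x


class TestRawScore:
    @pytest.mark.parametrize(
        "early,late,expected", [(3, 1, 0.5), (7.5, 7.5, 0.0), (0, 5, -1.0), (5, 0, 1.0)]
    )
    def test_known_values(self, early, late, expected):
        assert raw_score(early, late) == pytest.approx(expected)

    @given(
        a=st.floats(0, 1e6), b=st.floats(0, 1e6),
    )
    def test_range_and_antisymmetry(self, a, b):
        if a + b <= 0:
            return
        s = raw_score(a, b)
        assert -1.0 <= s <= 1.0
        assert raw_score(b, a) == pytest.approx(-s, abs=1e-12)

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            raw_score(0.0, 0.0)


class TestZTransform:
    def test_closed_form_three_values(self):
        xs, mu, sigma = z_transform([1.0, 2.0, 3.0])
        assert mu == pytest.approx(2.0)
        assert xs == pytest.approx([-1.224744871391589, 0.0, 1.224744871391589])

    def test_population_moments(self):
        rng = np.random.default_rng(3)
        xs, _, _ = z_transform(rng.normal(5, 2, size=40))
        assert abs(xs.mean()) <= 1e-9
        assert abs(xs.std() - 1.0) <= 1e-9

    @given(
        shift=st.floats(-100, 100), scale=st.floats(0.01, 100),
    )
    def test_affine_invariance_and_order(self, shift, scale):
        base = np.array([0.3, -0.2, 0.9, 0.1])
        xs1, *_ = z_transform(base)
        xs2, *_ = z_transform(base * scale + shift)
        assert xs2 == pytest.approx(xs1, abs=1e-9)
        assert np.all(np.sign(np.diff(xs1)) == np.sign(np.diff(base)))

    def test_degenerate_sigma_raises(self):
        with pytest.raises(DegenerateScoreError):
            z_transform([0.4, 0.4, 0.4])


class TestRunTimbr:
    def test_ketone_scores_positive_when_late_bottleneck_relaxes(self, toy):
        st_ = run_timbr(
            toy.model, toy.cb_early, toy.cb_late, metabolites=toy.scored_metabolites
        )
        row = st_.table.set_index("metabolite_id").loc["ket"]
        assert row["status"] == STATUS_OK
        assert row["X_raw"] > 0
        assert row["X_s"] > 0

    def test_identical_conditions_degenerate(self, toy):
        with pytest.raises(DegenerateScoreError):
            run_timbr(
                toy.model, toy.cb_early, toy.cb_early,
                metabolites=toy.scored_metabolites,
            )

    def test_uptake_only_metabolites_flagged_zero_capability(self, toy):
        st_ = run_timbr(toy.model, toy.cb_early, toy.cb_late)
        by_met = st_.table.set_index("metabolite_id")
        for met in ("glyc", "lac", "ala", "ffa"):
            assert by_met.loc[met, "status"] == STATUS_ZERO

    def test_weight_scaling_leaves_scores_invariant(self, toy):
        mets = toy.scored_metabolites
        base = run_timbr(toy.model, toy.cb_early, toy.cb_late, metabolites=mets)
        scaled = run_timbr(
            toy.model, toy.cb_early, toy.cb_late, metabolites=mets,
            weights={r: 2.5 for r in toy.model.reaction_ids},
        )
        np.testing.assert_allclose(
            scaled.table["X_early"], 2.5 * base.table["X_early"], rtol=1e-6
        )
        np.testing.assert_allclose(
            scaled.table["X_raw"], base.table["X_raw"], atol=1e-7
        )
        np.testing.assert_allclose(scaled.table["X_s"], base.table["X_s"], atol=1e-6)

    def test_tightening_a_bound_never_lowers_demand(self, toy):
        model = apply_condition(toy.model, toy.cb_early)
        req = 0.9 * max_production_capability(model, "ket")
        x_base, _ = minimum_total_flux(model, "EX_ket", req)
        tighter = model.copy()
        # shrink the lactate allowance but keep the demand target attainable
        tighter.reaction("EX_lac").lower_bound = -62.0
        x_tight, _ = minimum_total_flux(tighter, "EX_ket", req)
        assert x_tight >= x_base - 1e-6

    def test_z_population_excludes_flagged_rows(self, toy):
        st_ = run_timbr(toy.model, toy.cb_early, toy.cb_late)
        ok = st_.ok()
        assert abs(ok["X_s"].mean()) <= 1e-9
        assert abs(ok["X_s"].std(ddof=0) - 1.0) <= 1e-9
        flagged = st_.table[st_.table["status"] != STATUS_OK]
        assert flagged["X_s"].isna().all()

    def test_score_table_round_trip(self, toy, tmp_path):
        st_ = run_timbr(
            toy.model, toy.cb_early, toy.cb_late, metabolites=toy.scored_metabolites
        )
        path = str(tmp_path / "scores.tsv")
        st_.to_tsv(path)
        back = ScoreTable.from_tsv(path)
        assert back.mu == st_.mu and back.sigma == st_.sigma
        np.testing.assert_allclose(back.table["X_s"], st_.table["X_s"])
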