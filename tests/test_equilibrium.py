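"""Equilibrium solver: mass balance, oracles, limits and lane rendering."""

import math

import numpy as np
import pytest

from poudimer.equilibrium import (
    Band,
    BindingReaction,
    DnaMotifSpecies,
    EquilibriumSystem,
    LanePattern,
    ProteinSpecies,
    apparent_kd,
    predict_band_pattern,
    predict_bound_fraction_curve,
    rank_complexes,
    solve_equilibrium,
)


def monomer(kd=25.0, protein_conc=0.0, dna_conc=5.0):
    return EquilibriumSystem(
        proteins=(ProteinSpecies("P", protein_conc, "GFP"),),
        motifs=(DnaMotifSpecies("D", "OTHER", dna_conc, "Cy5"),),
        reactions=(BindingReaction("PD", "D", {"P": 1}, (kd,)),),
    )


# ---------------------------------------------------------------------------
# independent oracle: nested 1-D bisection on the free protein concentrations


def bisection_oracle(system, tol=1e-13):
    """Solve <=2-protein systems by nested bisection on the free concs.

    DNA frees are linear given protein frees; each protein's mass-balance
    residual is continuous and brackets a sign change on [0, total]."""
    proteins = [p for p in system.proteins if p.total_conc > 0]

    def dna_free(free_p):
        out = {}
        for d in system.motifs:
            denom = 1.0
            for r in system.reactions:
                if r.dna != d.name:
                    continue
                term = r.cooperativity / math.prod(r.kd_steps)
                for name, s in r.protein_stoichiometry.items():
                    term *= free_p.get(name, 0.0) ** s
                denom += term
            out[d.name] = d.total_conc / denom
        return out

    def residual(name, free_p):
        fd = dna_free(free_p)
        bound = 0.0
        for r in system.reactions:
            s = r.protein_stoichiometry.get(name, 0)
            if s:
                c = fd[r.dna] * r.cooperativity / math.prod(r.kd_steps)
                for pn, ps in r.protein_stoichiometry.items():
                    c *= free_p.get(pn, 0.0) ** ps
                bound += s * c
        total = next(p.total_conc for p in proteins if p.name == name)
        return free_p[name] + bound - total

    def solve_inner(name, outer):
        lo, hi = 0.0, next(p.total_conc for p in proteins if p.name == name)
        for _ in range(200):
            mid = (lo + hi) / 2
            if residual(name, {**outer, name: mid}) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    if not proteins:
        free_p = {}
    elif len(proteins) == 1:
        free_p = {proteins[0].name: solve_inner(proteins[0].name, {})}
    else:
        n1, n2 = proteins[0].name, proteins[1].name
        lo, hi = 0.0, proteins[0].total_conc
        for _ in range(200):
            mid = (lo + hi) / 2
            f2 = solve_inner(n2, {n1: mid})
            if residual(n1, {n1: mid, n2: f2}) > 0:
                hi = mid
            else:
                lo = mid
        f1 = (lo + hi) / 2
        free_p = {n1: f1, n2: solve_inner(n2, {n1: f1})}
    for p in system.proteins:
        free_p.setdefault(p.name, 0.0)
    fd = dna_free(free_p)
    complexes = {}
    for r in system.reactions:
        c = fd[r.dna] * r.cooperativity / math.prod(r.kd_steps)
        for pn, ps in r.protein_stoichiometry.items():
            c *= free_p[pn] ** ps
        complexes[r.complex_id] = c
    return {**free_p, **fd}, complexes


def random_two_protein_system(rng):
    kd = lambda: float(rng.uniform(1.0, 100.0))
    conc = lambda: float(rng.uniform(0.5, 200.0))
    return EquilibriumSystem(
        proteins=(ProteinSpecies("A", conc()), ProteinSpecies("B", conc())),
        motifs=(
            DnaMotifSpecies("D1", "OTHER", float(rng.uniform(0.5, 20.0))),
            DnaMotifSpecies("D2", "OTHER", float(rng.uniform(0.5, 20.0))),
        ),
        reactions=(
            BindingReaction("A_D1", "D1", {"A": 1}, (kd(),)),
            BindingReaction("B_D1", "D1", {"B": 1}, (kd(),)),
            BindingReaction("AB_D1", "D1", {"A": 1, "B": 1}, (kd(), kd()), float(rng.uniform(0.1, 20.0))),
            BindingReaction("A2_D2", "D2", {"A": 2}, (kd(), kd()), float(rng.uniform(0.5, 10.0))),
            BindingReaction("B_D2", "D2", {"B": 1}, (kd(),)),
        ),
    )


class TestSolver:
    def test_zero_protein_leaves_all_dna_free(self):
        state = solve_equilibrium(monomer(protein_conc=0.0))
        assert state.free_conc["D"] == pytest.approx(5.0)
        assert state.complex_conc["PD"] == 0.0
        assert state.dna_bound_fraction("D") == 0.0

    def test_half_saturation_at_kd_without_depletion(self):
        state = solve_equilibrium(monomer(kd=25.0, protein_conc=25.0, dna_conc=0.001))
        assert state.dna_bound_fraction("D") == pytest.approx(0.5, abs=1e-3)

    def test_monomer_matches_quadratic_closed_form(self):
        # P + D <=> PD with depletion: PD solves the quadratic
        # PD^2 - (P+D+Kd) PD + P D = 0, taking the physical root
        p, d, kd = 25.0, 5.0, 25.0
        s = p + d + kd
        pd_complex = (s - math.sqrt(s**2 - 4 * p * d)) / 2
        state = solve_equilibrium(monomer(kd=kd, protein_conc=p, dna_conc=d))
        assert state.complex_conc["PD"] == pytest.approx(pd_complex, rel=1e-8)
        curve = predict_bound_fraction_curve(monomer(kd=kd, dna_conc=d), "P", [p])
        assert curve["bound_fraction"][0] == pytest.approx(pd_complex / d, rel=1e-8)

    def test_mass_conservation_and_oracle_agreement_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            system = random_two_protein_system(rng)
            state = solve_equilibrium(system)
            # mass balance per species
            for p in system.proteins:
                bound = sum(
                    r.protein_stoichiometry.get(p.name, 0) * state.complex_conc[r.complex_id]
                    for r in system.reactions
                )
                assert state.free_conc[p.name] + bound == pytest.approx(
                    p.total_conc, rel=1e-8
                )
            for d in system.motifs:
                bound = sum(
                    state.complex_conc[r.complex_id]
                    for r in system.reactions
                    if r.dna == d.name
                )
                assert state.free_conc[d.name] + bound == pytest.approx(
                    d.total_conc, rel=1e-8
                )
            # brute-force nested-bisection oracle
            free_o, complexes_o = bisection_oracle(system)
            for name, val in free_o.items():
                assert state.free_conc[name] == pytest.approx(val, rel=1e-6, abs=1e-9)
            for cid, val in complexes_o.items():
                assert state.complex_conc[cid] == pytest.approx(val, rel=1e-6, abs=1e-9)

    def test_path_independence_of_heterodimer(self):
        # same overall constant via either addition order
        def system(kd_steps, omega):
            return EquilibriumSystem(
                proteins=(ProteinSpecies("A", 40.0), ProteinSpecies("B", 70.0)),
                motifs=(DnaMotifSpecies("D", "SOX_OCT", 5.0),),
                reactions=(
                    BindingReaction("AB_D", "D", {"A": 1, "B": 1}, kd_steps, omega),
                ),
            )

        s1 = solve_equilibrium(system((20.0, 50.0), 4.0))
        s2 = solve_equilibrium(system((50.0, 20.0), 4.0))
        s3 = solve_equilibrium(system((10.0, 25.0), 1.0))  # same product Kd1*Kd2/w = 250
        assert s1.complex_conc["AB_D"] == pytest.approx(s2.complex_conc["AB_D"], rel=1e-9)
        assert s1.complex_conc["AB_D"] == pytest.approx(s3.complex_conc["AB_D"], rel=1e-9)

    def test_no_depletion_limit_recovers_langmuir(self):
        p, kd = 60.0, 25.0
        system = monomer(kd=kd, protein_conc=p, dna_conc=1e-6)
        state = solve_equilibrium(system)
        assert state.dna_bound_fraction("D") == pytest.approx(p / (p + kd), rel=1e-4)

    def test_validation_rejects_triple_occupancy_and_bad_refs(self):
        with pytest.raises(ValueError, match="protein copies"):
            BindingReaction("X", "D", {"A": 2, "B": 1}, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="unknown motif"):
            EquilibriumSystem(
                proteins=(ProteinSpecies("A", 1.0),),
                motifs=(DnaMotifSpecies("D", "OTHER", 1.0),),
                reactions=(BindingReaction("A_E", "E", {"A": 1}, (1.0,)),),
            )


class TestBoundFractionCurve:
    def test_monotone_in_concentration(self):
        grid = np.geomspace(0.5, 800, 15)
        curve = predict_bound_fraction_curve(monomer(), "P", grid)
        assert np.all(np.diff(curve["bound_fraction"]) >= 0)

    def test_cooperativity_raises_bound_fraction_pointwise(self):
        def het(omega):
            return EquilibriumSystem(
                proteins=(ProteinSpecies("P", 0.0), ProteinSpecies("S", 132.0)),
                motifs=(DnaMotifSpecies("D", "SOX_OCT", 5.0),),
                reactions=(
                    BindingReaction("P_D", "D", {"P": 1}, (22.5,)),
                    BindingReaction("PS_D", "D", {"P": 1, "S": 1}, (22.5, 100.0), omega),
                ),
            )

        grid = np.geomspace(1, 500, 10)
        base = predict_bound_fraction_curve(het(1.0), "P", grid)["bound_fraction"]
        coop = predict_bound_fraction_curve(het(5.0), "P", grid)["bound_fraction"]
        assert np.all(coop.to_numpy() > base.to_numpy())

    def test_unknown_motif_rejected(self):
        with pytest.raises(KeyError):
            predict_bound_fraction_curve(monomer(), "P", [1.0, 10.0], motif="nope")

    def test_apparent_kd_matches_curve_crossing(self):
        system = monomer(kd=22.5)
        akd = apparent_kd(system, "P")
        curve = predict_bound_fraction_curve(system, "P", [akd])
        assert curve["bound_fraction"][0] == pytest.approx(0.5, abs=1e-8)


class TestLanePattern:
    def test_free_dna_only_lane(self):
        state = solve_equilibrium(monomer(protein_conc=0.0))
        lane = predict_band_pattern(state, "Cy5")
        assert [b.mobility_class for b in lane.bands if b.intensity > 0] == ["free_dna"]

    def test_homodimer_counts_two_labels_in_protein_channel(self):
        system = EquilibriumSystem(
            proteins=(ProteinSpecies("P", 50.0, "GFP"),),
            motifs=(DnaMotifSpecies("D", "MORE", 5.0, "Cy5"),),
            reactions=(
                BindingReaction("P_D", "D", {"P": 1}, (20.0,)),
                BindingReaction("P2_D", "D", {"P": 2}, (20.0, 20.0), 5.0),
            ),
        )
        state = solve_equilibrium(system)
        lane = predict_band_pattern(state, "GFP")
        by_class = {b.mobility_class: b.intensity for b in lane.bands}
        assert by_class["homodimer"] == pytest.approx(2 * state.complex_conc["P2_D"], rel=1e-9)
        assert by_class["monomer"] == pytest.approx(state.complex_conc["P_D"], rel=1e-9)
        assert "free_dna" not in by_class  # GFP does not label the probe
        dna_lane = predict_band_pattern(state, "Cy5")
        dna_by_class = {b.mobility_class: b.intensity for b in dna_lane.bands}
        assert dna_by_class["homodimer"] == pytest.approx(state.complex_conc["P2_D"], rel=1e-9)
        assert dna_by_class["free_dna"] == pytest.approx(state.free_conc["D"], rel=1e-9)

    def test_unknown_channel_rejected(self):
        state = solve_equilibrium(monomer())
        with pytest.raises(KeyError):
            predict_band_pattern(state, "FITC")

    def test_band_order_validation(self):
        with pytest.raises(ValueError, match="ordered"):
            LanePattern((Band("free_dna", "Cy5", 1.0), Band("monomer", "Cy5", 1.0)))


class TestRankComplexes:
    def test_empty(self):
        state = solve_equilibrium(
            EquilibriumSystem(
                proteins=(), motifs=(DnaMotifSpecies("D", "OTHER", 5.0),), reactions=()
            )
        )
        assert rank_complexes(state) == []

    def test_tie_broken_lexicographically(self):
        system = EquilibriumSystem(
            proteins=(ProteinSpecies("P", 30.0),),
            motifs=(DnaMotifSpecies("D", "OTHER", 5.0),),
            reactions=(
                BindingReaction("zeta", "D", {"P": 1}, (10.0,)),
                BindingReaction("alpha", "D", {"P": 1}, (10.0,)),
            ),
        )
        ranked = rank_complexes(solve_equilibrium(system))
        assert [cid for cid, _ in ranked] == ["alpha", "zeta"]
        assert ranked[0][1] == pytest.approx(ranked[1][1], rel=1e-12)
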