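"""Mass-action equilibria for POU/Sox transcription factors binding DNA motifs.

POU factors such as Oct4 and Oct6 occupy their cis elements as monomers,
as homodimers (on the palindromic MORE and pseudo-palindromic PORE), or as
cooperative heterodimers with Sox2 (on composite Sox/Oct motifs).  This
module represents such a mixture as an :class:`EquilibriumSystem` — proteins
and DNA motifs with total concentrations plus a list of binding reactions —
and solves the coupled mass-action/mass-balance equations for the free and
complex concentrations at equilibrium.

Concentrations are nanomolar throughout; unit conversion belongs at I/O
boundaries, never here.

A reaction assembles one complex on one DNA molecule by sequential protein
addition (at most two protein copies per DNA).  Each step carries a stepwise
dissociation constant; a dimensionless cooperativity factor ``omega``
divides the final step's Kd, so ``omega > 1`` means the second subunit binds
more tightly once the first is in place.  The overall association constant
of a complex is therefore ``omega / prod(kd_steps)`` and at equilibrium

    [complex] = [DNA]_free * prod_p [P]_free**stoich_p * omega / prod(kd_steps)

Because only the product ``prod(kd_steps)/omega`` enters the equilibrium,
two parameterizations of the same heterodimer that differ in addition order
but share that product are thermodynamically identical (cycle closure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ProteinSpecies",
    "DnaMotifSpecies",
    "BindingReaction",
    "EquilibriumSystem",
    "EquilibriumState",
    "LanePattern",
    "Band",
    "SolverError",
    "solve_equilibrium",
    "predict_bound_fraction_curve",
    "predict_band_pattern",
    "rank_complexes",
    "apparent_kd",
    "ELEMENT_CLASSES",
]

ELEMENT_CLASSES = ("SOX_OCT", "PORE", "MORE", "OTHER")

#: mobility ordering used to lay out gel lanes, slowest species first
_MOBILITY_ORDER = ("heterodimer", "homodimer", "monomer", "free_protein", "free_dna")


class SolverError(RuntimeError):
    """Raised when the equilibrium solver cannot reach the requested tolerance."""


@dataclass(frozen=True)
class ProteinSpecies:
    """A protein present in the binding mix.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"Oct4"``.
    total_conc : float
        Total (free + complexed) concentration in nM.
    label : str or None
        Fluorophore tag carried by the fusion protein (``"GFP"``,
        ``"mCherry"``), or None for untagged protein.
    """

    name: str
    total_conc: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.total_conc < 0:
            raise ValueError(f"total_conc of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class DnaMotifSpecies:
    """A double-stranded DNA probe carrying one cis element."""

    name: str
    element_class: str
    total_conc: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"element_class must be one of {ELEMENT_CLASSES}, got {self.element_class!r}"
            )
        if self.total_conc < 0:
            raise ValueError(f"total_conc of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class BindingReaction:
    """Sequential assembly of one protein–DNA complex.

    ``kd_steps`` lists the stepwise dissociation constants (nM), one per
    protein copy added; ``cooperativity`` divides the final step's Kd.
    ``protein_stoichiometry`` maps protein name to copy number in the final
    complex; the total never exceeds two (higher-order complexes are not
    modeled).
    """

    complex_id: str
    dna: str
    protein_stoichiometry: Mapping[str, int]
    kd_steps: Sequence[float]
    cooperativity: float = 1.0

    def __post_init__(self) -> None:
        n_prot = sum(self.protein_stoichiometry.values())
        if n_prot < 1 or n_prot > 2:
            raise ValueError(
                f"reaction {self.complex_id!r}: total protein copies must be 1 or 2, got {n_prot}"
            )
        if any(c < 1 for c in self.protein_stoichiometry.values()):
            raise ValueError(f"reaction {self.complex_id!r}: stoichiometries must be >= 1")
        if len(self.kd_steps) != n_prot:
            raise ValueError(
                f"reaction {self.complex_id!r}: expected {n_prot} kd_steps, got {len(self.kd_steps)}"
            )
        if any(k <= 0 for k in self.kd_steps):
            raise ValueError(f"reaction {self.complex_id!r}: kd_steps must be > 0")
        if self.cooperativity <= 0:
            raise ValueError(f"reaction {self.complex_id!r}: cooperativity must be > 0")

    @property
    def overall_kd_product(self) -> float:
        """Product of stepwise Kds divided by cooperativity (nM**n_steps)."""
        return math.prod(self.kd_steps) / self.cooperativity

    @property
    def n_proteins(self) -> int:
        return sum(self.protein_stoichiometry.values())

    def mobility_class(self) -> str:
        """EMSA band class this complex migrates as."""
        if self.n_proteins == 1:
            return "monomer"
        if len(self.protein_stoichiometry) == 1:
            return "homodimer"
        return "heterodimer"


@dataclass(frozen=True)
class EquilibriumSystem:
    """Complete definition of a binding mix: species plus reactions."""

    proteins: Sequence[ProteinSpecies]
    motifs: Sequence[DnaMotifSpecies]
    reactions: Sequence[BindingReaction]

    def __post_init__(self) -> None:
        names = [p.name for p in self.proteins] + [d.name for d in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        known_p = {p.name for p in self.proteins}
        known_d = {d.name for d in self.motifs}
        cids = [r.complex_id for r in self.reactions]
        if len(set(cids)) != len(cids):
            raise ValueError("complex_ids must be unique")
        for r in self.reactions:
            if r.dna not in known_d:
                raise ValueError(f"reaction {r.complex_id!r} references unknown motif {r.dna!r}")
            for p in r.protein_stoichiometry:
                if p not in known_p:
                    raise ValueError(
                        f"reaction {r.complex_id!r} references unknown protein {p!r}"
                    )

    def protein(self, name: str) -> ProteinSpecies:
        for p in self.proteins:
            if p.name == name:
                return p
        raise KeyError(name)

    def motif(self, name: str) -> DnaMotifSpecies:
        for d in self.motifs:
            if d.name == name:
                return d
        raise KeyError(name)

    def with_protein_conc(self, name: str, total_conc: float) -> "EquilibriumSystem":
        """Copy of the system with one protein's total concentration replaced."""
        self.protein(name)  # raise KeyError early
        proteins = tuple(
            ProteinSpecies(p.name, total_conc, p.label) if p.name == name else p
            for p in self.proteins
        )
        return EquilibriumSystem(proteins, tuple(self.motifs), tuple(self.reactions))


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium: free concentrations and complex concentrations (nM)."""

    system: EquilibriumSystem
    free_conc: Mapping[str, float]
    complex_conc: Mapping[str, float]

    def dna_bound_fraction(self, motif: str) -> float:
        """Fraction of the named probe's molecules in any complex."""
        total = self.system.motif(motif).total_conc
        if total == 0:
            return 0.0
        return 1.0 - self.free_conc[motif] / total

    def protein_complex_dna_fraction(self, motif: str, protein: str) -> float:
        """Fraction of the probe bound in complexes that contain the named protein.

        This is the quantity a band-shift quantitation reads out when only
        the shifts containing the labeled protein are summed (e.g. an Oct4
        titration in the presence of Sox2, where Sox2-only complexes migrate
        separately).
        """
        total = self.system.motif(motif).total_conc
        if total == 0:
            return 0.0
        bound = sum(
            self.complex_conc[r.complex_id]
            for r in self.system.reactions
            if r.dna == motif and protein in r.protein_stoichiometry
        )
        return bound / total


@dataclass(frozen=True)
class Band:
    mobility_class: str
    channel: str
    intensity: float


@dataclass(frozen=True)
class LanePattern:
    """Ordered EMSA lane: slowest (dimer) bands first, free DNA last."""

    bands: Sequence[Band] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(b.intensity < 0 for b in self.bands):
            raise ValueError("band intensities must be >= 0")
        order = [_MOBILITY_ORDER.index(b.mobility_class) for b in self.bands]
        if order != sorted(order):
            raise ValueError("bands must be ordered from slowest (dimer) to fastest (free DNA)")


# ---------------------------------------------------------------------------
# solver


def _complex_conc(reaction: BindingReaction, free_p: Mapping[str, float], free_d: float) -> float:
    c = free_d * reaction.cooperativity / math.prod(reaction.kd_steps)
    for name, stoich in reaction.protein_stoichiometry.items():
        c *= free_p[name] ** stoich
    return c


def _free_dna_given_proteins(
    system: EquilibriumSystem, free_p: Mapping[str, float]
) -> dict[str, float]:
    # DNA mass balance is linear in free DNA once protein frees are fixed:
    # D_tot = D_free * (1 + sum_c prod_p f_p^s / Kd_overall)
    out = {}
    for d in system.motifs:
        denom = 1.0
        for r in system.reactions:
            if r.dna != d.name:
                continue
            term = r.cooperativity / math.prod(r.kd_steps)
            for name, stoich in r.protein_stoichiometry.items():
                term *= free_p[name] ** stoich
            denom += term
        out[d.name] = d.total_conc / denom
    return out


def _protein_residuals(
    system: EquilibriumSystem,
    active: Sequence[str],
    free_vals: Sequence[float],
) -> np.ndarray:
    free_p = {p.name: 0.0 for p in system.proteins}
    free_p.update(dict(zip(active, free_vals)))
    free_d = _free_dna_given_proteins(system, free_p)
    res = np.empty(len(active))
    for i, name in enumerate(active):
        total = system.protein(name).total_conc
        bound = 0.0
        for r in system.reactions:
            s = r.protein_stoichiometry.get(name, 0)
            if s:
                bound += s * _complex_conc(r, free_p, free_d[r.dna])
        res[i] = (free_p[name] + bound - total) / total
    return res


def solve_equilibrium(
    system: EquilibriumSystem,
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the coupled mass-action equilibria of a binding system.

    The DNA mass balances are linear in each probe's free concentration once
    the protein frees are fixed, so the probes are eliminated in closed form
    and a damped Newton iteration runs on the log free concentrations of the
    proteins only.  Working in log space keeps every concentration positive;
    the residual is the relative mass-balance error per protein.

    Raises
    ------
    SolverError
        If the worst relative mass-balance residual exceeds ``rtol`` after
        ``max_iter`` iterations; the error names the offending species.
    """
    active = [p.name for p in system.proteins if p.total_conc > 0]

    if active:
        totals = np.array([system.protein(n).total_conc for n in active])

        def fun(logf: np.ndarray) -> np.ndarray:
            return _protein_residuals(system, active, np.exp(logf) * totals)

        x0 = np.log(np.full(len(active), 0.5))  # start at half the total
        sol = optimize.root(fun, x0, method="hybr", options={"xtol": 1e-14, "maxfev": 400 * (len(active) + 1)})
        x = sol.x
        res = fun(x)
        if np.max(np.abs(res)) > rtol:
            # damped Newton fallback with numerical Jacobian
            for _ in range(max_iter):
                res = fun(x)
                if np.max(np.abs(res)) <= rtol:
                    break
                jac = optimize.approx_fprime(x, fun, 1e-8)
                jac = np.atleast_2d(jac)
                try:
                    step = np.linalg.solve(jac, -res)
                except np.linalg.LinAlgError:
                    step = -res
                step = np.clip(step, -2.0, 2.0)
                lam = 1.0
                base = np.max(np.abs(res))
                while lam > 1e-6:
                    trial = x + lam * step
                    if np.max(np.abs(fun(trial))) < base:
                        break
                    lam /= 2
                x = x + lam * step
            res = fun(x)
            if np.max(np.abs(res)) > rtol:
                worst = active[int(np.argmax(np.abs(res)))]
                raise SolverError(
                    f"equilibrium solver failed to converge; worst mass-balance "
                    f"residual {np.max(np.abs(res)):.3g} on species {worst!r}"
                )
        free_vals = np.exp(x) * totals
    else:
        free_vals = np.array([])

    free_p = {p.name: 0.0 for p in system.proteins}
    free_p.update(dict(zip(active, free_vals)))
    free_d = _free_dna_given_proteins(system, free_p)

    complex_conc = {
        r.complex_id: _complex_conc(r, free_p, free_d[r.dna]) for r in system.reactions
    }
    free_conc = {**free_p, **free_d}
    return EquilibriumState(system, free_conc, complex_conc)


# ---------------------------------------------------------------------------
# derived predictions


def predict_bound_fraction_curve(
    system_template: EquilibriumSystem,
    protein: str,
    conc_grid: Sequence[float],
    motif: str | None = None,
    count: str = "all",
) -> pd.DataFrame:
    """Noiseless bound-fraction titration of one protein.

    For each concentration in ``conc_grid`` the named protein's total is set
    to that value, the system is solved, and the probed motif's bound
    fraction recorded.  ``count="all"`` reads 1 - free/total DNA (every
    shifted band counts); ``count="protein"`` counts only complexes
    containing the titrated protein, mirroring a quantitation that sums only
    that protein's band shifts.

    Returns a DataFrame with columns ``protein_conc_nM`` and
    ``bound_fraction``.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("conc_grid must be a non-empty 1-D sequence")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("conc_grid must be strictly increasing and positive")
    if motif is None:
        if len(system_template.motifs) != 1:
            raise ValueError("motif must be named when the system has several probes")
        motif = system_template.motifs[0].name
    else:
        system_template.motif(motif)  # KeyError if absent
    if count not in ("all", "protein"):
        raise ValueError("count must be 'all' or 'protein'")

    fracs = []
    for conc in grid:
        state = solve_equilibrium(system_template.with_protein_conc(protein, conc))
        if count == "all":
            fracs.append(state.dna_bound_fraction(motif))
        else:
            fracs.append(state.protein_complex_dna_fraction(motif, protein))
    return pd.DataFrame({"protein_conc_nM": grid, "bound_fraction": fracs})


def apparent_kd(
    system_template: EquilibriumSystem,
    protein: str,
    motif: str | None = None,
    count: str = "all",
    conc_hi: float = 1e6,
) -> float:
    """Total protein concentration at which the probe is 50% bound.

    This is the operational apparent dissociation constant of a titration:
    the model curve's 0.5 crossing, located by bisection on the titrated
    protein's total concentration.  Raises ``ValueError`` if the curve does
    not reach 0.5 by ``conc_hi``.
    """
    if motif is None:
        if len(system_template.motifs) != 1:
            raise ValueError("motif must be named when the system has several probes")
        motif = system_template.motifs[0].name

    def frac(conc: float) -> float:
        state = solve_equilibrium(system_template.with_protein_conc(protein, conc))
        if count == "all":
            return state.dna_bound_fraction(motif)
        return state.protein_complex_dna_fraction(motif, protein)

    lo, hi = 1e-9, conc_hi
    if frac(hi) < 0.5:
        raise ValueError("titration never reaches 50% bound fraction")
    return float(optimize.brentq(lambda c: frac(c) - 0.5, lo, hi, xtol=1e-9, rtol=1e-10))


def predict_band_pattern(state: EquilibriumState, channel: str) -> LanePattern:
    """Render a solved state as an EMSA lane seen in one fluorophore channel.

    Each band's intensity is proportional to the species concentration times
    the number of labeled entities of that channel it carries (a homodimer
    of a GFP fusion is twice as bright per complex as the monomer).  The
    free-DNA band appears only when the probe itself carries the channel's
    label.
    """
    system = state.system
    known = {p.label for p in system.proteins} | {d.label for d in system.motifs}
    known.discard(None)
    if channel not in known:
        raise KeyError(f"unknown channel {channel!r}; labels present: {sorted(known)}")

    labels_p = {p.name: p.label for p in system.proteins}
    labels_d = {d.name: d.label for d in system.motifs}

    acc: dict[str, float] = {m: 0.0 for m in _MOBILITY_ORDER}
    for r in system.reactions:
        n_labeled = sum(
            s for name, s in r.protein_stoichiometry.items() if labels_p[name] == channel
        )
        if labels_d[r.dna] == channel:
            n_labeled += 1
        if n_labeled:
            acc[r.mobility_class()] += n_labeled * state.complex_conc[r.complex_id]
    for p in system.proteins:
        if labels_p[p.name] == channel:
            acc["free_protein"] += state.free_conc[p.name]
    for d in system.motifs:
        if labels_d[d.name] == channel:
            acc["free_dna"] += state.free_conc[d.name]

    bands = tuple(
        Band(m, channel, acc[m]) for m in _MOBILITY_ORDER if acc[m] > 0 or m == "free_dna"
    )
    # drop the free-DNA placeholder if the channel does not label any probe
    if not any(labels_d[d.name] == channel for d in system.motifs):
        bands = tuple(b for b in bands if b.mobility_class != "free_dna")
    return LanePattern(bands)


def rank_complexes(state: EquilibriumState) -> list[tuple[str, float]]:
    """Complexes sorted by descending concentration; ties broken by id."""
    items = [(cid, conc) for cid, conc in state.complex_conc.items()]
    return sorted(items, key=lambda t: (-t[1], t[0]))
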