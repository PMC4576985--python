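"""Seeded synthetic inputs for every pipeline stage.

Three generators produce the data the analysis modules consume, each a pure
function of its parameters and a seed:

- noisy bound-fraction titrations from an equilibrium-model ground truth
  (multiplicative lognormal noise of chosen CV, clipped to [0, 1]);
- FCS autocorrelation curves from the diffusion + triplet model with
  lag-dependent Gaussian noise emulating finite acquisition time;
- ranked peak sets with elements planted at known subtypes, strands, ranks
  and positions in otherwise element-free background sequence (guaranteed
  by rejection sampling), together with a TSS table and a truth table.

Defaults mirror the bench conditions of the titration assays: 12
log-spaced concentrations from 1 to 500 nM, 5 nM probe, three replicates,
5% multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .emsa import TitrationPoint, TitrationSeries
from .equilibrium import EquilibriumSystem, predict_bound_fraction_curve
from .fcs import FcsCurve, FcsModel, autocorrelation
from .mining import PeakRecord, TssRecord, write_peaks_bed, write_tss_table
from .motifs import (
    MotifDefinition,
    build_more,
    build_pore,
    build_sox_oct,
    default_motif_set,
    scan_sequence,
)

__all__ = [
    "TitrationDesign",
    "SnrDesign",
    "PlantSpec",
    "PlantElement",
    "PeakFixture",
    "generate_titration",
    "generate_fcs_curve",
    "generate_peak_fixture",
    "default_lag_grid",
    "default_plant_spec",
    "motif_from_label",
]


# ---------------------------------------------------------------------------
# titrations


@dataclass(frozen=True)
class TitrationDesign:
    """Sampling design of a simulated titration."""

    conc_grid: tuple[float, ...] = tuple(np.geomspace(1.0, 500.0, 12))
    dna_conc: float = 5.0
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_titration(
    system_template: EquilibriumSystem,
    protein: str,
    design: TitrationDesign,
    motif: str | None = None,
    count: str = "all",
) -> TitrationSeries:
    """Noisy bound-fraction titration from an equilibrium ground truth.

    The noiseless curve comes from the equilibrium solver; each replicate
    point is that value times a lognormal factor with unit mean and
    coefficient of variation ``design.noise_cv``, clipped to [0, 1].
    ``count`` selects the band-quantitation convention (see
    :func:`poudimer.equilibrium.predict_bound_fraction_curve`).
    """
    curve = predict_bound_fraction_curve(
        system_template, protein, design.conc_grid, motif=motif, count=count
    )
    rng = np.random.default_rng(design.seed)
    cv = design.noise_cv
    points = []
    for rep in range(design.replicates):
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=len(curve))
        else:
            factors = np.ones(len(curve))
        noisy = np.clip(curve["bound_fraction"].to_numpy() * factors, 0.0, 1.0)
        points.extend(
            TitrationPoint(float(c), float(f), rep)
            for c, f in zip(curve["protein_conc_nM"], noisy)
        )
    return TitrationSeries(design.dna_conc, tuple(points), protein=protein, probe=motif or "")


# ---------------------------------------------------------------------------
# FCS curves


@dataclass(frozen=True)
class SnrDesign:
    """Noise level of a simulated correlator acquisition.

    The per-lag standard deviation is
    ``noise_scale * sqrt(1 + tau/tau_D) / sqrt(acquisition_s)`` — a simple
    monotone stand-in for correlator noise that grows with lag as averaging
    statistics worsen.
    """

    noise_scale: float = 0.01
    acquisition_s: float = 30.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0 or self.acquisition_s <= 0:
            raise ValueError("noise_scale >= 0 and acquisition_s > 0 required")


def default_lag_grid(n: int = 200, lo: float = 1e-6, hi: float = 1.0) -> np.ndarray:
    """Log-spaced correlator lag grid (s)."""
    return np.geomspace(lo, hi, n)


def generate_fcs_curve(
    model: FcsModel,
    lags: np.ndarray | None = None,
    snr: SnrDesign | None = None,
    seed: int = 0,
) -> FcsCurve:
    """Model autocorrelation plus seeded lag-dependent Gaussian noise."""
    lags = default_lag_grid() if lags is None else np.asarray(lags, dtype=float)
    snr = snr or SnrDesign()
    g = autocorrelation(model, lags)
    if snr.noise_scale > 0:
        rng = np.random.default_rng(seed)
        tau_ref = max(model.tau_d)
        sd = snr.noise_scale * np.sqrt(1.0 + lags / tau_ref) / np.sqrt(snr.acquisition_s)
        g = g + rng.normal(0.0, sd)
    return FcsCurve(lags, g)


# ---------------------------------------------------------------------------
# peak fixtures


@dataclass(frozen=True)
class PlantElement:
    """One group of identical-subtype plants: label, count, optional ranks."""

    subtype: str
    count: int
    ranks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.ranks is not None and len(self.ranks) != self.count:
            raise ValueError("ranks, when given, must list one rank per plant")


@dataclass(frozen=True)
class PlantSpec:
    """Design of a planted-element peak fixture."""

    n_peaks: int = 4000
    peak_len: int = 250
    plants: tuple[PlantElement, ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    top_ranks: int = 200  # plants without explicit ranks land in 1..top_ranks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1 or self.peak_len < 1:
            raise ValueError("n_peaks and peak_len must be >= 1")
        total = sum(p.count for p in self.plants)
        if total > self.n_peaks:
            raise ValueError("more plants than peaks")
        if not np.isclose(sum(self.background), 1.0):
            raise ValueError("background frequencies must sum to 1")


def default_plant_spec(seed: int = 0) -> PlantSpec:
    """Fixture emulating a mined top-200 peak set: 7 MORE-C4, 10 MORE-A4,
    8 MORE-A4C4 and 8 MORE+1 elements planted among 4000 ranked peaks, the
    first MORE-C4 in the very top peak."""
    return PlantSpec(
        plants=(
            PlantElement("MORE-C4", 7),
            PlantElement("MORE-A4", 10),
            PlantElement("MORE-A4C4", 8),
            PlantElement("MORE+1-A4", 8),
        ),
        seed=seed,
    )


def motif_from_label(label: str) -> MotifDefinition:
    """Resolve a subtype label ("MORE-A4C4", "MORE+1-C4", "PORE",
    "SOX_OCT") to its definition."""
    if label == "PORE":
        return build_pore()
    if label == "SOX_OCT":
        return build_sox_oct()
    for prefix, insertion in (("MORE+1-", 1), ("MORE-", 0)):
        if label.startswith(prefix):
            core = label[len(prefix) :]
            if len(core) == 2 and core[1] == "4":
                return build_more(core[0], insertion)
            if len(core) == 4 and core[1] == core[3] == "4":
                return build_more((core[0], core[2]), insertion)
    raise ValueError(f"unrecognized element label {label!r}")


@dataclass(frozen=True)
class PeakFixture:
    """In-memory peak fixture: ranked peaks, genome, TSS table, truth table."""

    peaks: tuple[PeakRecord, ...]
    genome: Mapping[str, str]
    tss: tuple[TssRecord, ...]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Write genome FASTA, peaks BED, TSS TSV and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_peaks_bed(self.peaks, outdir / "peaks.bed")
        write_tss_table(self.tss, outdir / "tss.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


_CHROM = "chrS"
_GAP = 250  # element-free spacer between adjacent peaks (bp)
_MAX_RETRIES = 200


def _random_background(
    rng: np.random.Generator, length: int, freqs, grammar
) -> str:
    """Background sequence guaranteed free of every grammar element."""
    bases = np.array(list("ACGT"))
    for _ in range(_MAX_RETRIES):
        seq = "".join(rng.choice(bases, size=length, p=freqs))
        if not scan_sequence(seq, grammar):
            return seq
    raise RuntimeError("could not draw element-free background")


def _render_element(defn: MotifDefinition, rng: np.random.Generator) -> str:
    """Concrete element string, drawing unconstrained spacer bases."""
    seq = defn.consensus
    if "N" in seq:
        bases = "ACGT"
        seq = "".join(b if b != "N" else bases[rng.integers(4)] for b in seq)
    return seq


def generate_peak_fixture(spec: PlantSpec) -> PeakFixture:
    """Build a ranked peak set with planted elements and matching TSS table.

    Peaks receive strictly decreasing synthetic fold enrichments.  Each
    peak's background is drawn from the spec's base frequencies and
    redrawn until it contains no grammar element; planted elements are
    then inserted at a seeded position and strand, and the peak re-scanned
    to confirm the insertion created exactly the planted element and
    nothing else.  Every plant is recorded in the truth table and given a
    TSS at a seeded offset within 100 kb.
    """
    rng = np.random.default_rng(spec.seed)
    grammar = default_motif_set()
    freqs = np.asarray(spec.background, dtype=float)

    # assign ranks: explicit ones first, the rest drawn without replacement
    taken: set[int] = set()
    assignments: list[tuple[int, str]] = []  # (rank, subtype)
    deferred: list[str] = []
    for plant in spec.plants:
        if plant.ranks is not None:
            for r in plant.ranks:
                if not 1 <= r <= spec.n_peaks:
                    raise ValueError(f"rank {r} outside 1..{spec.n_peaks}")
                if r in taken:
                    raise ValueError(f"rank {r} assigned twice")
                taken.add(r)
                assignments.append((r, plant.subtype))
        else:
            deferred.extend([plant.subtype] * plant.count)
    pool = [r for r in range(1, min(spec.top_ranks, spec.n_peaks) + 1) if r not in taken]
    if len(deferred) > len(pool):
        raise ValueError("not enough free ranks in the top segment for all plants")
    drawn = rng.choice(pool, size=len(deferred), replace=False)
    # the first deferred plant goes in the highest available rank so the
    # fixture's very top peak carries an element, as the mined data does
    order = np.argsort(drawn)
    drawn_sorted = drawn[order]
    if deferred and 1 in pool and 1 not in drawn_sorted:
        drawn_sorted[0] = 1
    for rank, subtype in zip(drawn_sorted, [deferred[i] for i in order]):
        assignments.append((int(rank), subtype))
    by_rank = dict(assignments)

    defn_cache = {label: motif_from_label(label) for _, label in assignments}
    for label, defn in defn_cache.items():
        if defn.length > spec.peak_len:
            raise ValueError(f"element {label} longer than peak_len")

    enrichments = np.linspace(100.0, 2.0, spec.n_peaks)
    peaks: list[PeakRecord] = []
    chrom_parts: list[str] = []
    truth_rows: list[dict] = []
    tss: list[TssRecord] = []
    offset = 0
    for i in range(spec.n_peaks):
        rank = i + 1
        start = offset
        label = by_rank.get(rank)
        for _ in range(_MAX_RETRIES):
            seq = _random_background(rng, spec.peak_len, freqs, grammar)
            if label is None:
                break
            defn = defn_cache[label]
            element = _render_element(defn, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = element if strand == "+" else reverse_complement(element)
            pos = int(rng.integers(0, spec.peak_len - defn.length + 1))
            seq = seq[:pos] + inserted + seq[pos + defn.length :]
            hits = scan_sequence(seq, grammar)
            if len(hits) == 1 and hits[0].subtype == defn.subtype and hits[0].start == pos:
                g_start = start + pos
                truth_rows.append(
                    {
                        "rank": rank,
                        "subtype": defn.subtype,
                        "element_class": defn.element_class,
                        "strand": strand,
                        "chrom": _CHROM,
                        "start": g_start,
                        "end": g_start + defn.length,
                        "sequence": inserted,
                    }
                )
                mid = g_start + defn.length // 2
                sign = 1 if rng.random() < 0.5 else -1
                tss_pos = max(0, mid + sign * int(rng.integers(200, 50_000)))
                tss.append(TssRecord(f"gene{rank:05d}", _CHROM, tss_pos))
                break
        else:
            raise RuntimeError(f"could not plant element at rank {rank}")
        peaks.append(
            PeakRecord(_CHROM, start, start + spec.peak_len, float(enrichments[i]), rank)
        )
        chrom_parts.append(seq)
        chrom_parts.append("N" * _GAP)
        offset += spec.peak_len + _GAP

    genome = {_CHROM: "".join(chrom_parts)}
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "rank",
            "subtype",
            "element_class",
            "strand",
            "chrom",
            "start",
            "end",
            "sequence",
        ],
    ).sort_values("rank").reset_index(drop=True)
    return PeakFixture(tuple(peaks), genome, tuple(tss), truth)
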