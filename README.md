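# poudimer

Quantitative analysis of POU-factor/Sox2 DNA binding: mass-action
equilibria of monomer, homodimer and heterodimer complexes on Sox/Oct,
PORE and MORE elements; apparent-Kd estimation from band-shift (EMSA)
titrations; fluorescence correlation spectroscopy (FCS) model fitting
and confocal-volume calibration; and an exact MORE/PORE/Sox-Oct motif
grammar with ranked ChIP-Seq peak mining.

## The scientific problem

Embryonic stem cells and neural stem cells both express Sox2, yet their
POU partners differ: pluripotent cells use Oct4, which binds composite
Sox/Oct motifs (`CATTGTTATGCAAAT`) cooperatively with Sox2, while
neural stem cells express class III factors such as Oct6, which prefer
homodimerization on the palindromic MORE (`ATGCATATGCAT`) and are
indifferent to Sox2. Distinguishing these modes quantitatively requires
(i) solving the coupled binding equilibria, (ii) extracting apparent
dissociation constants (aKd, the total protein concentration giving 50%
bound probe) from titrations, (iii) absolute concentrations from FCS,
and (iv) counting exact MORE-subtype elements in ranked peak sets.
`poudimer` implements all four stages plus seeded synthetic-data
generators, so the full pipeline runs and is testable without any
external data.

At its core, each protein–DNA complex obeys mass action,

    [complex] = [D]_free · Π_p [P]_free^s_p · ω / Π_i Kd_i ,

with stepwise dissociation constants Kd_i (nM), stoichiometries s_p
(≤ 2 proteins per DNA) and a cooperativity factor ω dividing the final
step's Kd. Titrations are fitted with the empirical sigmoid
f(x) = fmax / (1 + (midpoint/x)^h) and the aKd read off at f = 0.5.
FCS curves follow the 3D-diffusion + triplet model
G(τ) = G∞ + (1/N)·[1 + T/(1−T)·e^(−τ/τT)]·Σᵢ fᵢ·(1+τ/τDᵢ)^(−1)·(1+τ/(S²τDᵢ))^(−1/2),
with V_eff = π^{3/2}·w0³·S and C = N/(N_A·V_eff).

See `docs/methods.md` for model assumptions, calibration strategy,
numerical choices and limitations.

## Worked example

```python
from poudimer import emsa, synth, systems
from poudimer.equilibrium import rank_complexes, solve_equilibrium
from poudimer.motifs import default_motif_set, scan_sequence

# 1. simulate a noisy Oct4 titration on the Sox/Oct probe at 132 nM Sox2
#    and recover the apparent Kd from the sigmoid fit
system = systems.heterodimer_system()          # calibrated to aKd 8 nM
series = synth.generate_titration(system, "Oct4",
                                  synth.TitrationDesign(seed=1), count="protein")
fit = emsa.fit_titration(series)
print(f"aKd = {fit.akd:.2f} nM  (fmax = {fit.fmax:.3f}, h = {fit.hill:.2f})")

# 2. who wins when Oct4, Oct6 and Sox2 compete for all three motifs?
state = solve_equilibrium(systems.competition_assay_system())
for cid, conc in rank_complexes(state)[:3]:
    print(f"{cid:30s} {conc:6.3f} nM")

# 3. scan a peak fragment for elements
for h in scan_sequence("CCTCATGCATATGCAT", default_motif_set()):
    print(h.subtype, h.start, h.end, h.strand, h.matched)
```

prints

```
aKd = 7.92 nM  (fmax = 1.004, h = 1.16)
Oct4_Sox2_heterodimer_SoxOct    2.244 nM
Sox2_monomer_SoxOct             1.206 nM
Oct4_homodimer_MORE             0.502 nM
MORE-C4 4 16 + ATGCATATGCAT
```

The recovered 7.92 nM sits on the 8.0 nM ground truth within the 5%
simulated noise; in the three-way competition the cooperative Oct4–Sox2
heterodimer on the Sox/Oct motif is the most abundant complex; and the
fragment contains exactly one conventional MORE (subtype C4) at
positions 4–16 on the plus strand.

A command-line interface mirrors the library:

```sh
poudimer synth titration --akd 25 --seed 4 --out titration.tsv
poudimer emsa-fit --in titration.tsv --out fit.json
poudimer synth peaks --seed 1 --outdir fixtures/
poudimer mine --peaks fixtures/peaks.bed --genome fixtures/genome.fa \
              --tss fixtures/tss.tsv --top 0.05 --out hits.tsv
```

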