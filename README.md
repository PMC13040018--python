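# epifab

Structural and kinetic analysis of an antibody that targets the EGFR
287–302 cystine loop — the epitope that is buried in normally expressed
EGFR, partially exposed on receptor-overexpressing tumor cells, and fully
exposed on the tumor-specific truncation variant EGFRvIII.  The package is
aimed at structural bioinformaticians and antibody engineers who want to
re-run or extend this kind of characterization: Fab/peptide interface
geometry, epitope accessibility across receptor conformations, and
surface-plasmon-resonance (SPR) affinity ranking of humanized candidates.

## What it computes

**Superposition.**  Least-squares rigid-body (Kabsch) superposition over a
declared atom pairing (Cα, backbone N/CA/C/O, or all common atoms; residues
matched by author number or by global sequence alignment), with
RMSD = √(⟨‖R·xᵢ + t − yᵢ‖²⟩) and det(R) = +1 guaranteed.

**Interface area.**  Shrake–Rupley solvent-accessible surface area (SASA)
with a 1.4 Å probe on a deterministic 960-point sphere lattice, and the
buried-surface decomposition of a complex,
ΔSASA(c) = SASA(c isolated) − SASA(c in complex),
which is additive over components by construction.

**Typed contacts.**  Heavy-atom geometric detection of hydrogen bonds
(N/O/S pairs ≤ 3.5 Å), salt bridges (Asp/Glu carboxylate O to Lys/Arg/His
cationic N ≤ 4.0 Å) and cation-π interactions (cationic N to aromatic ring
atom ≤ 4.5 Å), with CDR attribution from configured residue windows and
main-chain atoms starred in the rendered table.

**Epitope accessibility.**  A graft-and-clash model: superpose the bound
epitope β-hairpin onto its copy in a receptor ectodomain conformation,
carry the whole Fab along, and count van der Waals overlaps
(d < r₁ + r₂ − 0.4 Å) per receptor domain and chain.  An N-terminal chain
truncation builds the EGFRvIII-style receptor model (residues 1–273
removed, leaving the epitope-bearing remainder of domain II exposed).

**1:1 Langmuir kinetics.**  Closed-form sensorgram simulation
(R(t) = Rmax·kaC/(kaC+kd)·(1−e^−(kaC+kd)t) in association,
exponential kd decay in dissociation), global multi-concentration fitting
of (ka, kd, Rmax) via `LangmuirModel(...).fit()` →
`LangmuirResults` with standard errors and `summary()`, KD = kd/ka, and
affinity ranking of candidate tables.

Every geometry and kinetics operation is testable offline against the
`epifab.synthetic` generators (idealized disulfide-closed β-hairpins, mock
Fab grooves with planted typed contacts, clash scenes with exactly known
overlap counts, noisy sensorgram sets with known rate constants).

## Worked example

```python
from epifab import (KineticParams, load_reference_kinetics, rank_by_affinity,
                    make_sensorgram_set, fit_kinetics)

ranked = rank_by_affinity(load_reference_kinetics())
print(ranked[["label", "ka", "kd", "KD_nM"]].head(4).to_string(index=False))

truth = KineticParams(ka=2.44e5, kd=6.16e-4, rmax=100.0)   # candidate A10
traces, _ = make_sensorgram_set(
    truth, [0.25e-9, 1e-9, 2.5e-9, 10e-9, 25e-9], noise_sd=2.0, seed=1)
print(fit_kinetics(traces, seed=1).summary())
```

```
label       ka       kd    KD_nM
   B1 374000.0 0.000746 1.994652
   B2 363000.0 0.000892 2.457300
  A10 244000.0 0.000616 2.524590
   A1 338000.0 0.000855 2.529586
1:1 Langmuir global fit
======================================================
n traces              5
n observations        1505
converged             True
residual norm (RU)    78.5
------------------------------------------------------
parameter         estimate       std err
ka (1/Ms)        2.424e+05      1.49e+03
kd (1/s)         0.0006214      4.64e-06
Rmax (RU)            100.4         0.325
KD (nM)              2.564
```

The ranking recomputes KD = kd/ka for each humanized candidate from the
packaged rate-constant table — B1 carries the lowest equilibrium
dissociation constant (~2.0 nM); the fit recovers the A10 rate constants
from five noisy simulated sensorgrams to within ~2 %.

A command-line interface mirrors the library
(`epifab select/truncate/superpose/interface/contacts/graft/clashes/`
`egfrviii/kd-table/spr-sim/spr-fit/fixtures/reproduce`); every JSON report
embeds the full parameter provenance needed to re-run it.

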