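# spinrelax

Backbone **¹⁵N relaxation analysis** for protein dynamics: Lipari–Szabo
model-free fitting with an axially symmetric rotational diffusion tensor,
reduced spectral density mapping, mono-exponential decay fitting, chemical
shift perturbation (CSP) classification of HSQC titrations, and structural
open/closed metrics — together with a synthetic-data generator that emulates
a two-state (ligand-free vs. Mg²⁺-ADP-bound) adenylate kinase experiment.

## Who this is for

Solution-NMR groups measuring ¹⁵N *R*₁, *R*₂ and {¹H}-¹⁵N heteronuclear NOE
to characterise ps–ns backbone motion and µs–ms exchange, and anyone who
needs a fully scriptable, testable re-implementation of the classic
relaxation workflow (peak-intensity decays → rates → global tumbling →
per-residue motional parameters → spectral densities) without opaque GUI
tools.

## The model

Internal motion of each backbone N–H bond is described by the Lipari–Szabo
spectral density under axially symmetric global tumbling,

J(ω) = (2/5) Σₖ Aₖ [ S²τₖ/(1+(ωτₖ)²) + (1−S²)τ′ₖ/(1+(ωτ′ₖ)²) ],  k = 1..3,

with A₁ = (3cos²α−1)²/4, A₂ = 3sin²αcos²α, A₃ = (3/4)sin⁴α for an N–H
vector at angle α to the unique diffusion axis; 1/τ₁ = 6D⊥,
1/τ₂ = 5D⊥+D∥, 1/τ₃ = 2D⊥+4D∥ and 1/τ′ₖ = 1/τₖ + 1/τₑ. The observables are
the standard dipolar/CSA expressions

- *R*₁ = (d²/4)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + c²J(ω_N)
- *R*₂ = (d²/8)[4J(0) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
  + (c²/6)[4J(0) + 3J(ω_N)] + *R*ₑₓ
- NOE = 1 + (γ_H/γ_N)(d²/4)[6J(ω_H+ω_N) − J(ω_H−ω_N)]/*R*₁

with d = μ₀ħγ_Hγ_N/(4πr³_NH) and c = ω_NΔσ/√3. Five nested models
{S²}, {S², τₑ}, {S², *R*ₑₓ}, {S², τₑ, *R*ₑₓ} and the extended two-timescale
{S²f, S², τₛ} are fitted per residue and selected by F-test. Reduced
spectral density mapping inverts each rate triple into J(0), J(ω_N),
J(0.87ω_H) with no motional model. CSP values use
Δδ = √(Δδ_H² + Δδ_N²/25).

## Worked example

Simulate the ligand-free (apo) scenario — 194 residues, mobile helix pairs
at residues 39–72 and 120–152, 2% intensity noise at the published delay
schedules — then fit rates and the diffusion tensor:

```bash
spinrelax simulate --mode apo --seed 2 -o demo
spinrelax fitrates --t1 demo/t1_decays.tsv --t2 demo/t2_decays.tsv \
                   --noe demo/noe_pairs.tsv -o demo/rates.tsv
spinrelax tensor --rates demo/rates.tsv --orientations demo/orientations.tsv \
                 -o demo/tensor.json
```

which prints

```
wrote synthetic apo dataset (194 residues) to demo
fitted 194 residues -> demo/rates.tsv
tau_m = 13.735 ns, D_par/D_perp = 1.162 (chi2 = 316.5) -> demo/tensor.json
```

The fitted rate table starts

```
residue  R1        R1_err     R2       R2_err    NOE       NOE_err    flagged
1        0.891366  0.0229841  17.0774  0.547023  0.828695  0.0233005  False
2        0.919725  0.0224885  16.5142  0.563986  0.7701    0.0282064  False
```

Reading this: residue 1 relaxes longitudinally at 0.89 s⁻¹ and transversely
at 17.1 s⁻¹ with an NOE of 0.83 — typical rigid-backbone values for a
protein tumbling at ~14 ns — and the tensor fit recovers the generator's
global tumbling (13.93 ns, *D*∥/*D*⊥ = 1.19) to about 1.5% at this noise
level. `spinrelax rsdm --rates demo/rates.tsv` then prints per-fragment
spectral density averages, and `spinrelax report -c config.yaml` runs the
whole apo/holo comparison (model-free tables, ΔS² profile, titration class
counts, figures) from one YAML config; `spinrelax report --show-defaults`
prints every threshold and seed used.

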