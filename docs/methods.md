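# Methods

`rpcidnp` simulates the low-magnetic-field photo-CIDNP of a covalently
linked radical pair — a flavin radical anion tethered to a tryptophan
radical cation by an aliphatic chain — and analyses / fits the resulting
magnetic-field-dependence (MFE) curves. This note records the model, its
assumptions, the defaults and why they were chosen, and what the package
does and does not claim.

## The model

### Spin system

Each radical contributes one electron spin-1/2 with its own g-factor;
nuclei couple through isotropic hyperfine constants `a_k` (mT). All spin
interactions are written in field units (mT) and converted to angular
frequency with `gamma_e = 1.76086e8 rad s^-1 mT^-1`. The Hamiltonian is

    H = (g1/ge) B S1z + (g2/ge) B S2z
      + sum_k a_k (I_k . S_r(k))
      - J_ex(r) (S1 . S2)
      - (gamma_p/gamma_e) B sum_k I_kz

with the exchange interaction decaying exponentially with inter-radical
distance, `J_ex(r) = J0 exp(-alpha r)`. With the `-J S1.S2` convention
the singlet–triplet gap at fixed `r` is exactly `|J_ex|` (in mT), so for
negative `J` the S and T- levels cross at a polarizing field
`B = |J_ex|` — the level anticrossing (LAC) responsible for the
low-field emissive maximum. Conventions with `2J` exist in the
literature; every statement in this package refers to the form above.
Nuclear Zeeman terms are negligible below 100 mT but cost nothing.

### Linker motion

The inter-radical distance is a dynamical variable. Its equilibrium
distribution comes from a rotational-isomeric-state Monte Carlo of the
chain: fixed bond length (1.54 Å) and valence angle (112°), discrete
trans/gauche± dihedrals with a 2.1 kJ/mol gauche penalty at 293 K, and a
Gaussian libration of 12° rms about each rotamer minimum. The libration
term is what turns the discrete RIS distance spectrum into a continuous
distribution that a diffusion operator can act on; 12° is a typical
room-temperature torsional fluctuation amplitude. 12 effective bonds
approximate the decamethylene-type linker. A freely-jointed mode
(`bond_angle_deg=None`) and a pentane-effect exclusion flag exist for
validation against closed forms.

The distance axis is discretized into 40 cells between the contact wall
and 20 Å. Transport is a one-dimensional Smoluchowski generator with
nearest-neighbour hopping rates

    k(i -> j) = (D'/dr^2) sqrt(f_j / f_i)

which satisfies detailed balance (`W f_eq = 0`) by construction and
conserves probability exactly; the outer boundary is reflecting. Empty
cells are floored at `1e-6` before renormalization so the rates are
defined everywhere. `D' = 2.5e-6 cm^2/s` is the fitted effective
diffusion coefficient.

### The contact wall at 9.14 Å

The measured effective separation of the radical centres, 9.14 Å with
`J_ex = -5.12 mT`, is interpreted here as the **closest approach** of
the two π systems: chain conformers more compact than that press the
radical centres against a steric/electrostatic wall. Concretely, chain
samples with end-to-end distance below 9.14 Å are folded into the first
grid cell, and the distance-dependent interactions (exchange, dipolar)
of that cell are evaluated *at the wall* rather than at the cell
midpoint, because its occupants physically sit there. Recombination also
happens in this cell.

This choice is load-bearing. If the grid instead extends to 4 Å, the
conformer population at 4–8 Å carries exchange couplings of 10^1–10^5 mT,
and then *every* polarizing field up to ~10^5 mT finds a resonant S/T-
crossing somewhere on the grid: the simulated emissive extremum drifts
to tens of mT and even 7 T remains in the S/T- regime, contradicting
both the observed low-field extremum (~5 mT) and the high-field
spin-sorting (Kaptein) sign rules. With the wall at 9.14 Å, `|J| <= 5.12 mT`
everywhere, the LAC ceiling is 5.12 mT, and the model reproduces the
qualitative shape of the measured field dependence: an absorptive
low-field lobe for the ring protons, sign inversion below ~1 mT,
an emissive dip near 3 mT with a half-effect field of ~2 mT, decline
above ~10 mT, and hyperfine-sign-following relative polarizations at 7 T.
The wall position is exposed as configuration
(`distance_distribution(r_contact_A=...)`), not hard-coded.

### Reaction

Spin-selective recombination uses the Haberkorn form,
`-(k_rec/2) {P_S, rho}`, restricted to the contact cell, with
`k_rec = 4.7e7 Hz`. A uniform loss channel `-k_loss rho` (default
`1e4 s^-1`) stands in for the slow deprotonation / ground-state-recovery
pathway; it is the only model element representing the secondary radical
pair. Measured sensitivity at 5 mT: slowing the loss tenfold (toward the
ms recovery time) changes the per-proton polarization by 4%; speeding it
tenfold changes it by ~30% because the pair lifetime then becomes
comparable to the polarization build-up (the singlet yield drops from
0.99 to 0.89). Conclusions are therefore insensitive to `k_loss` on its
slow side only.

### Relaxation

Electron spin relaxation is a Bloch–Redfield kernel with Lorentzian
spectral density `J(w) = tau_c/(1 + w^2 tau_c^2)` and two stochastic
sources:

1. isotropic, uncorrelated local field fluctuations of rms `b_loc` per
   Cartesian component at each electron (default 0.3 mT — the residual
   of anisotropic hyperfine/g interactions modulated by tumbling; gives
   a low-field electron T1 of ~3.6 µs, typical for organic radicals);
2. the electron–electron dipolar coupling `d(r) = d0/r^3`
   (`d0 = 1.857e3 mT Å^3` from `(mu0/4pi) g muB`), modulated by
   rotational tumbling, evaluated per distance cell through its five
   orthonormal rank-2 components with variance `(6/25)(gamma_e d)^2`
   each.

Both share `tau_c = 50 ps` (rotational correlation time of a ~600 Da
dyad in methanol). The kernel is built in the lab frame as a
frequency-weighted double commutator, `R rho = -sigma^2 [A, [A~, rho]]`
with `A~` the spectral-density-weighted image of `A` in the cell
eigenbasis. This deliberately avoids the secular approximation: the
secular form is ill-defined exactly at the S/T- anticrossing, which is
the regime of interest. The kernel preserves trace and Hermiticity
exactly and reduces to the familiar secular rates away from
degeneracies; the single-spin longitudinal rate reproduces the textbook
`1/T1 = 2 gamma^2 b^2 J(w0)` to machine precision.

### Solution and observables

The full generator `L = -i H^x + W + K + R` acts on
(distance cell) ⊗ (Liouville space). The pair is triplet-born: the
initial condition is the equilibrium spatial distribution times an equal
incoherent mixture of T+, T0, T-, with nuclei at infinite temperature.
The geminate observables come from the time-integrated density,
`X = -L^{-1} rho(0)` (sparse LU; the natural ordering preserves the
narrow block-tridiagonal band and factors several times faster than
fill-reducing permutations here):

    P_n   = k_rec Tr[I_nz P_S X_contact P_S]   (negative = emissive)
    Phi_S = k_rec Tr[P_S X_contact]

An independent cross-check propagates `rho(t)` by exact exponential
integration: the propagator/integral pair `Phi(dt), Psi(dt)` is seeded
by a Taylor series at `dt0 ~ 0.01/||L||` and advanced by dyadic doubling
(`Phi(2dt) = Phi(dt)^2`, `Psi(2dt) = (I + Phi(dt)) Psi(dt)`). Adaptive
ODE steppers are hopeless here — the coherent part oscillates at up to
10^9 rad/s while the chemistry runs to milliseconds — whereas the
doubling scheme is exact for any stiffness and agrees with the
stationary solve to ~1e-8 on small systems. It is dense linear algebra,
deliberately disjoint from the sparse-LU path, and is restricted to
oracle-sized systems (~1 nucleus, ~10 cells).

### Per-proton reduction

A full simulation of the four-proton reduced dyad would require a
163 840-dimensional stationary solve (40 cells × 64² Liouville space).
Field curves are instead computed per proton: each target nucleus is
simulated together with its strongest-coupled partner (Hilbert dimension
16, ~10 240 unknowns, ~2 s per field point). This keeps every sweep on a
desk scale and retains the dominant hyperfine partner. Known cost: the
target proton's share of the conversion is overestimated when spectator
nuclei are dropped, which inflates weakly-coupled protons' normalized
amplitudes (see Limitations).

## Fixtures

The hyperfine sets are literature transcriptions for the lumiflavin
radical anion and the tryptophan cation radical (EPR/ENDOR/CIDNP
literature values; each entry carries a `source` annotation). The
reduced dyad keeps the four most informative tryptophan protons — the
two conformationally inequivalent β-CH2 protons (+1.61, +0.60 mT) and
the ring protons H2 (−0.50 mT) and H6 (−0.35 mT) — which caps the
Hilbert space at 64. g-factors: 2.0034 (flavin anion), 2.0025 (TrpH
cation). The full Weller input set additionally carries the flavin
nitrogens and methyl protons and the remaining Trp ring protons.

## Synthetic data

`generate_curves` produces normalized per-proton MFE curves from the
forward model plus i.i.d. additive Gaussian noise (default σ = 5% of the
reference maximum), seeded and bit-reproducible. It emulates the
normalized intensities of a field-cycling experiment; it does **not**
emulate raw NMR spectra, scalar-coupling polarization redistribution
among product protons, baseline drifts, or field-dependent detection
efficiency. Passing recovery tests therefore demonstrate statistical
identifiability of the model parameters under the stated noise model,
not robustness to real spectrometer systematics.

The parameter-recovery study re-estimates (J_ex, k_rec, D') from noisy
synthetic curves for the four dyad protons (each proton simulated alone,
12-cell grid, 10 log-spaced fields spanning 0.5–30 mT) by bounded
multi-start least squares in log10 space. These problem sizes are the
package's validation configuration, chosen to keep one replicate at
about a minute. J_0 and alpha are not jointly identifiable from field
curves — only `J_ex(r_ref)` is — so the exchange is fitted as `J_ex` at
the 9.14 Å reference with alpha held fixed.

## Numerical choices

- Row-major vectorization, `vec(A rho B) = (A ⊗ B^T) vec(rho)`.
- Diagonal of `W` built by compensated summation so column sums vanish
  identically; equilibrium annihilation `W f_eq = 0` holds to 1e-12 of
  the rate scale by the detailed-balance construction.
- `f_eq` floor 1e-6 (renormalized) before building hopping rates.
- Extremum extraction: exact quadratic through the three points around
  the largest-magnitude sample (valid on uneven grids); `B_1/2` by
  linear interpolation of the first half-extremum crossing on the
  low-field shoulder (the sign-inverting lobe makes "half of maximum"
  ambiguous otherwise).
- Lorentzian fits parameterize the FWHM and float the baseline; three
  deterministic starting widths (10%, 25%, 50% of the field span).
- Multi-start fitting uses a seeded Latin-hypercube over the log-bounds
  box after a midpoint start; asymptotic standard errors come from the
  residual Jacobian and are mapped back to natural scale by the delta
  method.

## Limitations

- The conformer distribution is a phantom-chain reconstruction: the real
  dyad's motional inputs are not fully constrained by published data.
  With the defaults the emissive extremum of the ring protons sits near
  3 mT — at the low edge of the measured 4–6 mT window — because the
  population just outside the wall (|J| of 1–3 mT) pulls the dip below
  the 5.12 mT LAC ceiling.
- The per-proton two-spin reduction inflates the normalized amplitude of
  weakly coupled protons: the simulated H2 dip reaches roughly −60% of
  the β-CH2 reference against a measured −17%. Diluting this
  requires the full multi-nucleus solve, which is beyond the intended
  desk scale.
- Polarization redistribution to H5/H7 by nuclear-spin LACs in the
  diamagnetic product, anisotropic hyperfine tensors, orientation
  (compass) dependence, and the explicit secondary deprotonated pair are
  out of scope; the loss channel is a single uniform rate.
- The Coulomb (zwitterion) conformational bias is available as an
  optional Boltzmann reweighting hook but is off by default: an
  unscreened continuum estimate in methanol overwhelms the distribution
  and is clearly unphysical without counterion/screening treatment.
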