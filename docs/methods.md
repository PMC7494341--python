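# Methods

## The model

`glitimer` simulates a four-variable incoherent feed-forward loop timing the
motor-neuron (MN) to serotonergic (5HTN) fate switch. GliA (`A`) and GliR
(`R`) are pure exponential decays from `A(0)=R(0)=1` — the clock. Tgfβ (`T`)
integrates activation by GliA, repression by GliR and its own positive
feedback; Phox2b (`P`) integrates activation by GliA and repression by Tgfβ.
Production and decay of `T` and `P` share one rate constant (`v_T`, `v_P`),
so both variables are confined to `[0,1]` and relax fast (quasi-steady on the
Gli decay timescale: `v_T/λ ≈ 58`, `v_P/λ ≈ 105`).

Each regulatory link is a weighted Hill factor `H±_w(x,h,ω) = (1−ω) + ω H±(x,h)`
with Hill coefficient 2 everywhere (stored in the config, pinned by tests).
A weight of 0 removes the link and its threshold is never read; thresholds
are therefore representable as absent.

**Form of the Tgfβ self-activation.** The self-activation enters as
`ω_TT·H⁺(T,h_TT)` — the link weight applied once, to a plain Hill term. An
alternative composition that applies the `(1−ω)+ωH` weighting *inside* the
already ω-weighted term leaks a constant basal production `ω_TT(1−ω_TT)`
(= 0.056 at `ω_TT = 0.94`) that floods the low-Tgfβ state: the hysteretic
parameter row then has no bistability at all and the wild-type network
activates Tgfβ within ~0.1 day, i.e. the defining behaviours of the circuit
disappear. A fully multiplicative composition
(`H⁺_w(A)·H⁻_w(R)·H⁺_w(T,·,ω_TT)`) preserves bistability of the reduced
hysteretic row but prevents Tgfβ activation in the full network (the
GliA gate caps the drive below the fold), collapsing the Tgfbr1-mutant
phenotype. The convex-combination form used here is the only one of the
three under which all qualitative behaviours of the circuit — hysteretic
bistability, wild-type Tgfβ activation, delayed switching of the
Tgfβ-receptor knockout — hold simultaneously.

A consequence worth stating: with the tabulated parameters the high-Tgfβ
branch satisfies `0.94·H⁺(T,0.3) = T` on its own, so it exists for *every*
GliR level. The bifurcation diagram of the hysteretic row therefore has a
single fold (the low branch disappears at GliR ≈ 0.24, `sweep_R` reports it
as the `up` fold) and no return fold — the switch is one-way in the strongest
sense. Diagrams for configurations whose drive is non-monotone in the swept
variable (e.g. the full network with A slaved to R) can contain two folds.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| λ_A, λ_R | GliA/GliR decay rates | 0.86 | 1/day |
| v_T, v_P | Tgfβ / Phox2b production-decay scale | 50, 90 | 1/day |
| ω_·, h_· | link weights and thresholds | per network variant | – |
| ε | kinetic (multiplicative) noise level | 0.2 | – |
| η | readout threshold-noise level | 1.0 | – |
| t_end, dt | horizon and step | 6, 10⁻³ | day |

Time is measured in days: a decay rate of 0.86/day gives a Gli half-life of
~0.8 days, which places the fate switch 2–3 days into the MN window, matching
the multi-day developmental timescale. The reference noise levels are
package conventions: ε = 0.2 yields a coefficient of variation of ~25–30% in
GliA over the switch window (the observed cell-to-cell variability of Gli
levels is of this order), and η = 1 defines the reference gamma readout
(shape 10, scale 0.04). Both are deliberately mid-range; sweeps cover
0.25–4× around them.

The five canonical parameter rows (direct, relay, self-activation,
hysteresis, full/WT) are exposed as presets and as bundled YAML configs.
Mutants derive from WT: `Tgfbr1_KO` sets ω_TP = 0; `Gli1_KO` starts at
A(0) = 0.7; `Gli1ON_Tgfbr1_KO` additionally clamps GliA by λ_A = 0 (the
simplest realisation of "GliA stays above threshold forever" — the rates
type admits zero decay for exactly this use).

## Numerics

*Deterministic runs* use fixed-step classical RK4 at `dt = 10⁻³` day
(`v_P·dt = 0.09`, comfortably stable; halving `dt` moves trajectories by
< 10⁻⁶). *Stochastic runs* use Euler–Maruyama with per-variable multiplicative
noise `ε x ΔW`; with `correlated_AR` the A and R equations share increments.
States are clipped at 0 after each stochastic step (0 is absorbing for the
exact process). In the degenerate case ε = 0 the stochastic entry points fall
back to the RK4 step so that deterministic results are identical across APIs.
Ensembles are vectorised across replicates and driven by a single
`numpy.random.default_rng(base_seed)` stream (replicate r consumes column r),
so an ensemble is reproducible from one seed and two runs with equal shapes
are exactly paired — all "coupling on vs off" and "correlated vs
uncorrelated" comparisons use such common random numbers.

*Initial conditions.* T(0) = 0 and P(0) at its quasi-steady value
`H⁺_w(A(0),h_AP,ω_AP)` (≈ 0.99 in WT): Phox2b starts high, Tgfβ off. Because
`v_T`, `v_P` ≫ λ, any other bounded choice relaxes within ~0.02 day and only
shifts absolute switch times negligibly.

*Readout.* The gamma CDF is evaluated with the regularised lower incomplete
gamma function. For ensembles and lattices the population likelihood is the
across-replicate mean of per-replicate likelihoods (average *after* the
nonlinearity, so cell-to-cell variability widens the population transition);
applying the readout to the median path is available for comparison
(`method="median"`). Crossing times use linear interpolation; on non-monotone
curves the *last* downward 0.95 crossing and the *first* downward 0.05
crossing give the widest (conservative) transition interval. Curves that
never exceed 0.95 or never fall below 0.05 yield absent crossings with
`no_mn_phase` / `no_switch` flags; the Gli1-ON:Tgfbr1-KO mutant is the
canonical `no_switch` case, and sweeps record such points as censored rather
than dropping them.

*Bifurcation analysis* freezes (A, R), scans `g(T) = production − T` on 10⁴
grid points in `[0,1]` and refines each sign change by bisection to 10⁻¹⁰;
`g(0) ≥ 0 ≥ g(1)` guarantees a root. Stability is the sign of `g'`; labels
are cross-checked in the tests by forward integration from perturbed initial
values. Fold locations are bisected to 10⁻⁶ in R and classified by which
branch pair merges. Doubling the scan resolution moves folds by < 10⁻⁴.

*Lattice.* Von Neumann 4-neighbourhood by default ("nearest neighbours" on a
square grid); Moore and radius-2 ring stencils are exposed because the
averaging range matters little (tests bound the Δt difference at 0.1 day).
The averaged field enters only the `H⁺(T_eff,h_TT)` and `H⁻_w(T_eff,h_TP)`
terms — never the linear decay — via the same `T_eff` argument the
single-cell right-hand side exposes, so no equation code is duplicated.
Boundaries are periodic; the stencil is symmetric, hence the spatial mean of
T is conserved by the averaging step and results are equivariant under grid
translations.

## Problem sizes

Default analysis sizes are 10³-replicate ensembles and 20×20 lattices; the
100×100 grid and 10⁴ replicates remain available through the API/CLI
arguments. The averaging mechanism is insensitive to grid size well above
the stencil radius, and Δt estimates at these sizes are stable to ~0.02–0.05
day across seeds, which is the Monte-Carlo allowance used in the paired
equality-type comparison of the correlated-noise analysis.

## Synthetic expression tables

The gene-screen generator emulates per-gene summary statistics of an
RNA-seq differentiation time course, not reads or counts: log2-FPKM class
templates (biphasic peaking at 2 or 3.5 DDC with ≥ 0.5 log2 rise and fall,
monotone up/down, flat) plus i.i.d. normal noise in log2 space; log2
fold-changes are the noiseless template contrasts plus noise; p-values are
1e-4 where the template truly changes (|log2FC| ≥ 0.25) and uniform on
(0.1, 1) otherwise. Two decoy classes violate exactly one printed rule each
(biotype; the cyclopamine fold-change gate). What passing tests show is that
the *filter logic* implements the printed inequalities exactly and that each
rule is individually load-bearing; they say nothing about upstream
differential-expression modelling (dispersion, library-size effects,
multiple-testing behaviour), which the generator does not emulate. The
filters apply raw p ≤ 0.05 gates as printed — any false-discovery-rate
control belongs upstream.

## Known limitations

- The hysteretic row's one-way switch means `sweep_R` reports one fold for
  that configuration; a down-fold only appears when the drive is
  non-monotone in the swept variable.
- Switch-time scaling with the Gli decay rate is exactly ∝ 1/λ only when the
  readout is driven by the exponential signal directly; in hysteretic
  variants the passage through the disappearing-fold bottleneck adds a lag
  scaling roughly as λ^(−2/3), so doubling λ halves the WT switch time to
  ~10%, not exactly.
- Without spatial averaging, correlated GliA/GliR noise *narrows* the
  population transition in this model (a single shared noise source keeps
  cells coherent); the correlated-vs-uncorrelated comparisons are therefore
  reported in the spatially coupled setting, where correlation delays the
  collective switch without improving its sharpness.
- Euler–Maruyama is first-order; no adaptive stepping. Parameters are taken
  as given — no inference from data is provided.
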