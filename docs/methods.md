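# Methods

## Model

Each organism i is a flux-balance problem over reaction fluxes ψᵢ: maximize
γᵢ·ψᵢ subject to internal steady state Γᵢ†ψᵢ = 0, exchange constraints
c¹ᵢ ≤ Γᵢ*ψᵢ ≤ c²ᵢ(y), and constant flux bounds d¹ᵢ ≤ ψᵢ ≤ d²ᵢ.  The
exchange matrix Γᵢ* is stored so that a positive exchange rate means
*uptake* (removal from the environment); the sign flip into dy/dt happens
in the dynamics only.  Each row of the upper exchange bound is a
non-decreasing function of the single corresponding environment metabolite
(constant, linear κ·y, or Michaelis–Menten Vmax·y/(K+y)); lower exchange
bounds are constant.  Community state is biomass x (gDW), metabolites y
(mmol), time in hours — a pure labelling convention, no conversions are
performed.

Community dynamics: dxᵢ/dt = xᵢ(γᵢ·ψᵢ), dy/dt = φ − Σᵢ xᵢΓᵢ*ψᵢ, with an
optional constant inflow φ (used e.g. for aerobic environments).  Inflow
enters the dynamics but never the interaction networks: it is environment,
not interaction.

## Piecewise-smooth integration

By the fundamental theorem of linear programming an FBA optimum can be
written as ψ = B⁻¹c̄(y) for a square invertible subsystem of active
constraint rows.  The package uses an *active-set* basis — n rows drawn
from the explicit stack [internal balances; exchange bounds; flux bounds]
in a fixed deterministic order — rather than any solver-internal simplex
basis, so the representation is backend-independent and ties are broken
reproducibly (Bland-style lowest row index first).

Holding all bases fixed, the community is a smooth ODE whose right-hand
side is bilinear in x and the bound values:

- dxᵢ/dt = xᵢ(Cᵢ + Σⱼ aᵢⱼ c²ᵢⱼ(yⱼ)) with Cᵢ = Σ_{constant rows r} zᵢ[r]·rhs_r
  and aᵢⱼ = Σ_{functional rows on j} zᵢ[r], where zᵢ = Bᵢ⁻ᵀγᵢ;
- dy_l/dt = φ_l − Σᵢ xᵢ(D_il + Σⱼ b_ijl c²ᵢⱼ(yⱼ)) with D and b the analogous
  sums over Mᵢ = Γᵢ*Bᵢ⁻¹.

The integrator (adaptive explicit Runge–Kutta, `solve_ivp` RK45 at
rtol 1e-10 / atol 1e-12) monitors one scalar event function: the minimum
over all non-basic constraint slacks of every organism and all metabolite
values, shifted by `active_tol`.  The segment dynamics are smooth and
non-stiff for bounded problems of this kind, so an explicit method with
the solver's root-finding on the event gives event times far below the
1e-6 accuracy the analytic fixtures are checked at.

At a transition (or at t = 0) each organism's LP is re-solved (HiGHS dual
simplex via `scipy.optimize.linprog`, which returns vertex solutions),
parsimoniously refined, and a basis is selected as follows:

1. enumerate all invertible active-row bases that reproduce the optimal
   vertex, always containing a maximal independent set of the equality
   rows, ordered by row-index tuple (at a non-degenerate vertex this list
   has one element);
2. estimate the community derivative ẏ jointly from the fresh LP exchange
   rates of all organisms;
3. keep candidates whose currently-tight non-basic constraints all have
   slack derivative ≥ −`deriv_tol` under the candidate's induced dynamics
   (first-order forward feasibility), and among those pick the one
   maximizing the minimum slack derivative — a local proxy for "stays
   optimal longest" — with ties to the lowest index.

If no candidate is forward-feasible the step is reduced instead: a
protective explicit Euler step (initial size 1e-2 h, halved on repeated
failure, at most 40 halvings) using the fresh FBA rates, then a new
selection attempt.  An infeasible per-organism LP zeroes that organism's
flux (no growth, no exchange) for the segment, with a log entry; the
underlying formulation does not dictate this case, and zero flux is the
conservative choice.

The per-organism derivative estimate is assembled jointly from all fresh
LP solutions rather than sequentially organism-by-organism; with mild
degeneracy the exchange rates after parsimonious refinement are unique
enough that the two conventions coincide on everything tested.

### Parsimonious refinement

Among optimal flux vectors the one minimizing Σ|ψ| is selected by variable
splitting (ψ = p − q, p,q ≥ 0; a pure LP), at t = 0 and after each
transition.  This removes futile-cycle flux and most optimum
non-uniqueness before a basis is extracted.  If the refined point is not a
vertex of the original constraint stack (its active rows can be rank
deficient), basis extraction falls back to the unrefined simplex vertex.

### Stationarity

A run ends early with status `stationary` when every growth rate stays
below `stationary_tol` (1e-6 /h) across a `stationary_window` (0.1 h) and
there is no inflow; otherwise it runs to `t_final`.

## Networks

Per segment, the coefficients map to edges:

| term | edge | weight stored |
|---|---|---|
| aᵢⱼ c²ᵢⱼ(yⱼ) in dxᵢ/dt | Yⱼ → Xᵢ (growth) | aᵢⱼ |
| D_il xᵢ in dy_l/dt | Xᵢ → Y_l (constant_exchange) | −D_il |
| b_ill xᵢ c²(y_l) | Xᵢ → Y_l (self_mediated) | −b_ill |
| b_ijl xᵢ c²(yⱼ), j ≠ l | Xᵢ → Y_l (cross_mediated, mediator Yⱼ) | −b_ijl |

Edges into metabolites are *effect-signed*: the stored weight is the
contribution to d(target)/dt per unit driver, so consumption is negative
and production positive, while the raw ODE coefficient is kept alongside
(`raw_coeff`).  This makes the species-species heuristic
w̃ᵢⱼ = Σ_l wᵢ_l w_lⱼ produce negative weights for competition and positive
for cross-feeding without per-use sign juggling.  In that heuristic, wᵢ_l
aggregates *all* Xᵢ → Y_l edges (constant, self- and cross-mediated;
mediated terms excludable by flag) and w_lⱼ aggregates growth edges.
Species-species networks are computed per segment and then time-averaged —
not computed from the time-averaged species-metabolite network; the two
orders differ and the per-segment order is the documented one.

The metabolite-metabolite network keeps one edge Yⱼ → Y_l per (organism,
mediated term), labelled with the contributing organism; self-loops are
emitted by default and excludable.  Weights are per-unit-biomass
coefficients (−b_ijl), not multiplied by xᵢ(t), since x varies within a
segment and edge weights must be segment constants.

Summary networks are duration-weighted: mean w̄ = Σ_k Δt_k w_k / ΣΔt_k and
population variance Σ_k Δt_k (w_k − w̄)²/ΣΔt_k, keying edges by (source,
target, term kind, mediator, organism) and counting an absent edge as 0.
Network differences are computed over shared edge keys as |w_A| − |w_B|
(signed) with non-shared edges reported separately; the per-taxon
connection shift is the mean of those signed strength differences over the
taxon's shared connections, and is an explicit error — not 0 — when no
connection is shared.

The FBA-direct baseline network is built from one (refined) solve per
organism: organism→metabolite edges weighted by the effect-signed exchange
rate, plus a marker edge metabolite→organism for every consumed
metabolite.  It exists to quantify what basis tracking adds: the marker
edges cannot distinguish rate-limiting metabolites, so the baseline always
carries at least as many metabolite→organism edges as the segment network
has growth edges.

## Synthetic fixtures

All acceptance-grade expectations come from hand-constructed communities
with closed-form behavior (fixture generation is deterministic and pure):

- **monod_linear** (κ = 1, yield ½): reactions (u, g), balance u − 2g = 0,
  uptake bound u ≤ κy.  Basis {balance, uptake} gives B = [[1,−2],[1,0]],
  B⁻¹ = [[0,1],[−½,½]], hence a = κ/2, b_self = κ, dx/dt = ½xy,
  dy/dt = −xy, conserving x + y/2.  From (x₀,y₀) = (0.1, 10) biomass tends
  to 5.1.
- **capped_growth** adds g ≤ 10.  Segment 1: ψ = (20, 10) constant,
  x = 0.1e^{10t}, y = 30 − 0.2(e^{10t} − 1); the uptake bound binds at
  y = 20, i.e. t* = ln(51)/10 ≈ 0.3931826; segment 2 is monod-like and
  biomass tends to 0.1 + 30/2 = 15.1.
- **diauxie**: uptakes u₁, u₂ share a transporter capacity u₁ + u₂ ≤ 10
  with yields 1 and ½.  While κy₁ > 10 growth is intrinsic (C = 10, no
  growth edges); when glucose becomes rate-limiting the spare capacity
  flows to substrate 2, creating the positive mediated glucose→substrate2
  edge (+1) and a glucose growth edge (½); a third segment begins when
  substrate 2 becomes rate-limiting too.
- **crossfeed_pair**: A converts glucose to growth plus one unit of
  secreted acetate per unit growth; B grows on acetate.  Path products
  give w̃_AB = (+½)(+½) = +¼ > 0.
- **competition_pair**: two identical monod organisms on one glucose pool;
  w̃ = −½ in both directions, symmetric to rounding.

A seeded random-community generator (1–3 organisms consuming random
subsets of 1–3 metabolites through linear-bounded uptakes, random yields
0.2–1, κ 0.3–2, optional secretion fraction 0.1–0.8, y₀ 1–10 mmol,
x₀ 0.05–0.5 gDW) exists for property tests — forward invariance and
basis/LP agreement — never for expected values.  These synthetic
communities exercise the machinery (degeneracy, events, secretion,
multi-organism coupling) but are far below genome scale and have only
linear kinetics by default, so passing tests demonstrate correctness of
the algorithms, not predictive fidelity for real communities — that is
limited by the quality of the input GSMs, exactly as for any
constraint-based method.

## Numerical choices

| name | default | role |
|---|---|---|
| active_tol | 1e-7 | residual below which a row counts as active; event threshold |
| feasibility_tol | 1e-7 | basis must reproduce the LP solution this closely |
| optimality_tol | 1e-7 | allowed objective drift under refinement |
| deriv_tol | 1e-9 | slack-derivative tolerance in forward selection |
| cond_max | 1e12 | condition-number cap for accepting a basis |
| rtol / atol | 1e-10 / 1e-12 | segment integration tolerances |
| time_tol | 1e-8 | event/endpoint time resolution |
| weight_eps | 1e-10 | edge-dropping threshold |
| κ default | 1 /h/gDW | uptake kinetics when a model specifies none |

Degenerate vertices are resolved by the fixed row order (balances, then
exchange bounds in environment order, then flux bounds in reaction order) —
degeneracy makes the ODEs and networks non-unique in principle, so a
deterministic rule is mandatory for reproducibility; two identical runs
produce byte-identical outputs (floats printed at 9 significant digits,
fixed column orders).  Negative metabolite values (at most integration
noise below active_tol) are clipped to zero before bound evaluation.
Rows with infinite right-hand sides are omitted from the constraint stack;
they can never be active.

Problem sizes in the test suite and acceptance script: fixtures of 1–2
organisms and 1–4 reactions over horizons of 3–5 h, 20 random communities
for invariance, 100 random networks for heuristic exactness, and a
200-point grid for trajectory comparison — sizes chosen so every
expectation has a pencil-and-paper or brute-force oracle.

## Known limitations

- The forward-basis rule (max–min slack derivative) is first-order and
  local in time; it matches the contract "remain feasible and optimal for
  small t > 0" but is not a global optimum of segment length.
- Parsimonious refinement is applied at segment starts only, not
  continuously; within a segment the tracked vertex may differ from the
  minimal-total-flux optimum if the optimum becomes non-unique mid-segment
  (a transition is triggered only by constraint violation).
- Exchange bounds must depend on one metabolite each; no joint uptake
  kinetics, no death rates, lag phases, spatial structure, or stochastic
  effects.
- Species-species weights are a pairwise heuristic over length-2 paths;
  higher-order interactions present in the species-metabolite system are
  not representable in it.
- SBML output stores kinetic uptake bounds in a package annotation; other
  tools will read the model with whatever constant bounds FBC carries.
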