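# Methods

## The model

`barrelmap` simulates how the whisker map of rodent primary somatosensory
cortex — the barrel field — can self-organize from an initially
undifferentiated bundle of thalamocortical axons, guided only by smooth
molecular gradients and local competition. The cortical sheet is a 2D domain
S (in mm) discretized as a hexagonal lattice. Each of N thalamocortical
projections i carries two per-site densities: axon branching a_i(x, t) and
connection (synapse) density c_i(x, t).

Synaptogenesis couples all projections through a shared, limited pool of
cortical connections:

    ∂c_i/∂t = −α c_i + β (1 − Σ_j c_j) a_i^k ,          k > 1

Branching evolves by the divergence of a flux plus the synaptic coupling:

    ∂a_i/∂t = ∇·J_i − ∂c_i/∂t
    J_i = D ∇a_i − a_i g_i + (ε_i/(N−1)) a_i ∇â_i ,     â_i = Σ_{j≠i} a_j

The three flux terms are diffusion, advection up the projection-specific
guidance field g_i(x) = falloff(d_b) Σ_j γ_ij ∇ρ_j(x), and cross-diffusion
away from sites dense in *other* projections' branches (competition for
cortical space, strength ε). The interaction strengths γ_ij are the
projection's barreloid coordinates in the thalamus, affinely scaled to
[−2, 2]: relative thalamic position is encoded as relative gradient
sensitivity, which is what makes the emergent map somatotopic. All
communication is between adjacent lattice sites only.

Standard parameters: N = 41, α = 3.6, β = 16.67, k = 3, D = 0.5, ε = 1.2,
δt = 1e-4, 30000 steps (3.0 time units), hex spacing d = 0.03 mm, initial
a ~ U(0.2, 0.4) i.i.d. per hex and projection, c = 0. Two linear guidance
fields are used: ρ1 anterior-posterior (φ = 0°) and ρ2 at φ = 84°, both
min-max normalized to [0, 1] over the lattice before gain.

## Discretization

Operators come from Gauss's theorem applied to the mean over one hexagonal
cell (area Ω = (√3/2) d², edge v = d/√3), reducing every divergence to a sum
over the six cell edges:

* Laplacian: (2/3d²) Σ_j (f_j − f_0) — exact for quadratics.
* Gradient: (1/3d) Σ_j (f_j − f_0) n̂_j, n̂_j = (cos πj/3, sin πj/3) —
  exact for linear fields.
* Flux divergence of a vector field: (1/3d) Σ_j (g_j + g_0)·n̂_j.

∇·J_i is expanded into five locally computable terms (diffusion, a_i ∇·g_i,
g_i·∇a_i, and the two competition terms). Boundary handling implements
J·n̂ = 0 exactly: scalar ghost values equal the interior value (zero
diffusive and advective flux through rim edges), the static g_i is driven to
zero near the rim by a sharp logistic fall-off 1/[1 + exp(100(d_f − d_b))]
with d_f = 0.1 mm, and the competition flux through rim edges is zeroed.

The competition divergence ∇·(a∇â) is evaluated as a_0 times the Gauss flux
sum of the gradient-stencil field ∇â (the same machinery as for ∇·g), not as
a ∇²â with the Laplacian stencil. The two forms agree to truncation error,
but the flux form telescopes: Σ_hex ∇·J_i Ω = 0 to machine precision for any
state, so each projection's mass Σ_hex (a_i + c_i) Ω is conserved to
round-off over arbitrarily long runs (relative drift ~1e-15 over a
1000-step run, as the acceptance script reports). Branch-density
conservation is a structural requirement of the
model, and the Laplacian-stencil alternative loses ~0.1–1% of per-projection
mass over a run through the non-telescoping high-frequency residual.

Time stepping is classical RK4. Instability (any non-finite value or
|a| > 1e6) aborts a run, which is then flagged rather than raised inside
sweeps. a_i is not clipped at zero; negativity is possible in principle and
monitored by tests, but does not occur under the standard conditions.

## Pattern metrics

* **Winner-take-all label map**: each hex is assigned to the projection with
  maximal c_i (ties to the lowest index; hexes with total c below 1e-12 fall
  back to the argmax of a). Region areas, centroids, the border-length
  adjacency matrix V_ij and total border lengths b_i (including the domain
  exterior) are derived from it.
* **Honda-δ** (dimensionless): departure from a Dirichlet (Voronoi)
  tessellation. One generator per region starts at the region centroid; each
  internal border contributes the mean over its vertices (midpoints of
  shared hex edges) of |‖v−z_i‖ − ‖v−z_j‖| / ‖z_i−z_j‖, and δ is the mean
  over internal borders, minimized over generator positions. The
  minimization is derivative-free: a mirror-propagation proposal (each
  border's fitted line reflects a neighbour's generator, propagated over a
  maximum-border-length spanning tree from an optimized 2-parameter root,
  repeated for three deterministic root choices) and the centroid start are
  each refined by per-generator Nelder-Mead sweeps until < 1% improvement,
  and the best result is reported. Generators are softly constrained to
  their own regions; without that constraint the normalized deviation is
  degenerate (it vanishes as the whole constellation recedes to infinity).
  On exact Voronoi rasterizations δ ≲ 0.02 at d = 0.02–0.03 mm (the floor
  scales with d divided by the generator spacing); real barrel fields score
  ≈ 0.05.
* **Pattern difference η** (mm³) between a simulated and a reference
  tessellation with matched labels:
  η = [mean_i |A_i^sim − A_i^ref|] × [mean_i ‖V_i^sim − V_i^ref‖] /
  [mean_i (V_i^sim/b_i^sim)·(V_i^ref/b_i^ref)]. Zero for identical maps,
  scales as length³, +inf when the maps share no adjacency structure.
* **Selectivity** μ(x) = max_i c_i / Σ_j c_j ∈ [1/N, 1] (1/N where total c
  is ~0, keeping ω continuous at t = 0), and ω = Σ_hex μ Ω (mm²).

## Synthetic stand-ins

The real inputs (a boundary traced from a cytochrome-oxidase stain and
barreloid centres reconstructed from published anatomy) are external; the
`synthetic` module generates substitutes that preserve what the model needs:

* **Boundary**: a deterministic egg-shaped polygon, ~3.9 × 1.8 mm and
  ~5.5 mm² (comparable to the ~5.1 mm² real field the parameters were
  calibrated on — domain area and D trade off against each other, so
  matching it matters), with a trapezoidal taper making the row-E long edge
  longer than the row-A edge as in the real field, and a flat posterior edge
  so the domain can be mirror-duplicated cleanly.
* **Barreloid grid**: 41 labelled points — rows A(4), B(4), C(8), D(10),
  E(11) plus straddlers α–δ. Each row's arcs are spread evenly over the
  common anterior-posterior extent (the rows of the real field jointly span
  the field's length); straddlers sit anterior of arc 1 with a slight
  stagger. Only the count and row/arc ordering are contractual; exact
  geometry is a stand-in.
* **Field gains**: the standard setup gives the anterior-posterior field the
  gain extent(0°)/extent(84°) ≈ 2, equalizing the two fields' absolute
  slopes (mm⁻¹). A molecular gradient has a characteristic slope per mm, not
  per domain extent; with unit gains on a 2:1 domain, within-row sorting
  forces are half the across-row ones and the dense rows (D, E) lose barrels
  to their neighbours.
* **Reference tessellation** for η: the Voronoi rasterization of the
  barreloid grid affinely mapped into the domain. It captures topology and
  approximate areas of an ideal map but not the curved borders or irregular
  per-barrel areas of a real stained field, so synthetic-η values index
  convergence trends, not correspondence with anatomy.

What passing tests on these stand-ins show: that the mechanism (competition
+ two gradients + boundary) self-organizes a complete, contiguous,
topographically ordered map, responds to the documented perturbations in the
documented directions, and is robust to the α/β balance. What they cannot
show: agreement with the published absolute metric values (δ ≈ 0.089,
η ≈ 0.21, ω ≈ 0.22), which depend on the real boundary and coordinates.

## Scaled-down protocol

Full resolution (d = 0.03 mm, 30000 steps of 1e-4) costs ~minutes-to-hours
per run; tests and the acceptance script run a scaled-down protocol: factor
s multiplies d by s and δt by s² (the explicit stability margin D δt/d² is
scale-free) and divides the step count by s², preserving the 3.0 units of
simulated time. s = 2 (d = 0.06 mm, ~1800 hexes) is used for the standard
run, s = 2.5 for the sweep and perturbation experiments, s = 6 for smoke
tests. Scaled-down assertions are qualitative — region counts, contiguity,
orderings, trends — since border quantization inflates δ and coarse barrels
(~30–50 hexes) fragment more easily than fine ones.

## Experiments

* **Parameter sweep**: independent simulations over (D, ε, α/β); the full
  default grid is 6×6×6 = 216 cells with D log-spaced, ε linear, and the
  ratio spanning five orders of magnitude. The ratio axis varies α/β at
  constant turnover α·β: varying α alone conflates the balance with the
  pruning timescale 1/α, which exceeds the simulated window at the low end
  and would masquerade as ratio sensitivity. Unstable cells are flagged and
  carry no metrics. Even at constant turnover, the simulated window imposes
  a floor: cells with 1/α approaching the total simulated time measure
  pruning lag (inflated δ on the connection-based map) rather than the α:β
  balance, so ratio-robustness checks span their five orders starting one
  decade below the standard ratio rather than symmetrically.
* **Sensitivity suite**: initial-condition noise (band half-width around
  0.3), γ noise ((γmax−γmin)·U(0, ν_γ) per entry, range per column), field
  noise ((ρmax−ρmin)·U(0, ν_ρ) per hex, then Gaussian smoothing of width
  σ_ρ with per-hex kernel renormalization at the rim; noise applied after
  gain), and ρ1 rotation/gain. Paired two-sample t-tests compare per-seed
  metric distributions.
* **Fgf8 mirror duplication**: the domain is mirrored across its flat
  posterior edge (lattice anchored on the join line so the hex grid is
  mirror-symmetric), ρ1 is reflected at the join, ρ2 extends unreflected.
  Reported: the territory count (projections claiming area in each half —
  2N for full duplication; raw connected components are noisier at coarse
  resolution because join-straddling barrels merge with their mirror twins)
  and the correlation of per-projection areas between halves.
* **Whisker trimming**: ε_i → m·ε for targeted projections (both
  competition terms), compared against the m = 1 control at the same seed so
  initialization variance cancels. Row-C trimming includes the interstitial
  γ straddler.
* **1D reproduction**: N = 5 projections on an ellipse under M = 3 logistic
  gradients centred at 1/4, 1/2, 3/4 of the long axis, with
  γ_ij = 2 tanh(4(f_i − c_j)) for target fractions f_i = (i+½)/5 — each
  localized gradient bump pushes a projection towards its target from either
  side, so ordering of the γ rows dictates the spatial order of the emergent
  fields.

## Known limitations

* Absolute δ/η/ω values are resolution- and input-dependent; only the real
  boundary/coordinates reproduce the published numbers.
* The Honda-δ operationalization is a documented stand-in for the cited
  (unrestated) original algorithm; absolute values may differ by a small
  calibration factor.
* The Gaussian field-noise kernel treats the lattice as a point cloud
  (per-hex renormalization, no wraparound); very small σ_ρ relative to d
  degenerates to no smoothing.
* Microvibrissae, rhinal whiskers and mechanistic gene-network models of the
  gradients are out of scope; guidance fields are phenomenological.
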