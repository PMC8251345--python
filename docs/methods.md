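# Methods

`torusfit` infers the oligomeric state of a ring-forming protein in solution
from small-angle X-ray scattering (SAXS), corroborated by mass-based and
crystallographic evidence. The motivating system is a bacterial
ribbon–helix–helix (RHH) antitoxin whose folded N-terminal domains
crystallize as a closed torus of eight dimers while the full-length protein
— carrying a ~30-residue intrinsically disordered C-terminal tail per chain
— populates smaller open arcs (decamers/dodecamers) in solution. The
package treats that inference as a reproducible computation: build candidate
ring models, attach tail ensembles, forward-model scattering, and let a
chi-square criterion select the size.

## Assembly model

A ring oligomer is generated from a single dimer and one rigid inter-dimer
transform: dimer *j* is `T^j` applied to dimer 0. A closed torus of
`k_closed = 8` dimers corresponds to `T` = 45° rotation about the ring
axis; arcs of *k* < 8 dimers use the identical transform, encoding the
assumption that the solution species keeps the crystal's inter-dimer
contact geometry. `ring_layout` places a centred dimer at the smallest ring
radius at which adjacent copies keep all bead–bead distances at or above a
clearance (4 Å by default), found by bisection — adjacent dimers then just
touch, as in a packed torus seam. `infer_adjacent_transform` inverts the
construction by least-squares (Kabsch) superposition of consecutive dimers;
for a ring built from one transform this recovers it exactly, and
`T^8 ≈ identity` verifies closure.

## Disordered tails

Tails are modelled at one bead per residue as self-avoiding random walks:
fixed 3.8 Å virtual bonds, virtual bond angle uniform in [70°, 150°], free
dihedral, and a 4.0 Å excluded-volume cutoff between all non-bonded beads
(tail–core, tail–tail across chains, tail–self). This is a deliberately
minimal coil prior: no force field, no sequence-specific statistics, no
side chains. Its role is to provide a plausible conformational spread whose
*selection* against the data does the fitting; the per-conformer
self-avoidance is also what makes crowding effects emerge (growth rejection
rates rise with ring occupancy).

Growth is retried at three levels: up to 30 placement attempts per bead, 25
restarts per chain, and whole-conformer restarts with a fresh random
substream. The last level is essential: a chain can dead-end because of
tails grown *earlier in the same conformer*, which no amount of chain-local
retrying can undo. Each conformer draws from an independent
`(seed, conformer, attempt)` substream, so ensembles are exactly
reproducible.

## Forward scattering

Scattering is computed with the Debye equation over bead centres,
`I(q) = Σᵢⱼ wᵢwⱼ sinc(q·rᵢⱼ)`, with unit weights by default (pure shape
scattering — no hydration shell or excluded-volume contrast, which at
bead resolution does not affect model *ranking*). The O(N²) pair sum is
accelerated through a pair-distance histogram (0.5 Å bins by default): the
kernel is evaluated at each bin's weighted mean distance with a
second-order within-bin variance correction, making the error
O((q·Δ)⁴) — about 2×10⁻⁵ relative at 0.5 Å bins and q ≤ 0.5 Å⁻¹, and
< 10⁻³ even in deep interference minima at 0.1 Å bins. A direct
double-loop implementation is kept as an independent reference.
`I(0) = (Σw)²` holds exactly by construction.

## One-dimensional analyses

* **Guinier.** `ln I` vs `q²` is fitted over a window iteratively truncated
  to `q·Rg ≤ 1.3` (≥ 5 points). By default the fit is quadratic in `q²`
  with `Rg` read from the `q → 0` slope ("extended Guinier"): a plain
  linear fit at this window overestimates the Rg of sharp-edged particles
  by ~1.9% (the ln-form-factor curvature of a homogeneous sphere), while
  the quadratic fit is exact on Guinier-law curves and recovers the sphere
  Rg to ~0.1%. The classic linear fit remains available (`order=1`).
* **Dimensionless Kratky.** `(qRg)² I/I0` vs `qRg` with the peak located by
  parabolic interpolation. Reference points computed by the package: an
  exact Guinier-law curve peaks at `(√3, 3/e) ≈ (1.732, 1.104)`; a
  Gaussian-density bead globule (the canonical compact globular reference,
  since a Gaussian density has an exactly Gaussian form factor) reproduces
  that peak numerically; a homogeneous *hard* sphere peaks measurably left
  of it, at `(1.61, 1.03)` — worth knowing before reading particle class
  off a Kratky maximum; a straight rod peaks near 3.
* **P(r).** From models: exact weighted pair-distance histograms, with Rg
  from exact second moments (the zero-distance self pairs enter the
  normalization so that the discrete identity `Rg_pr = Rg_coord` holds).
  From curves: a regularized indirect transform in a sine basis
  `sin(kπr/dmax)` (endpoint zeros built in) with a second-difference
  smoothness penalty; optional non-negativity by iterative clipping.
* **Molecular weight.** Porod-volume (`V_p = 2π²I0/Q`, mass ≈ V_p/1.66,
  with a `K/q_max` tail correction and an oscillation-averaged plateau
  check) and volume-of-correlation estimators. Both are concentration-free
  stand-ins for calibrated or Bayesian estimates and are labelled as such
  in results.

## Model selection

The misfit is `χ² = (1/n) Σ ((c·I_calc − I_exp)/δI_exp)²` on the
experimental grid (calculated curves interpolated linearly), truncated at
`q < 0.5 Å⁻¹`. Because experimental SAXS intensities are on an arbitrary
scale, the closed-form least-squares scale `c` is fitted by default; it can
be switched off, in which case `c = 1`. Normalization is `1/n`, not
`1/(n−1)`.

For each candidate size, 100 tail conformers are generated, each scored
individually, and the 10 best are intensity-averaged; the reported χ² is
that of the average. Ranking by per-conformer χ² replaces ranking by a
refinement energy whose data term dominates at this resolution. The size
scan runs this over chain counts {8, 10, 12, 14, 16} and reports the
argmin (ties toward the smaller assembly). Two-component mixtures are
fitted by scanning the fraction on a 0.05 grid with one parabolic
refinement; the best mixture is never worse than either pure endpoint.

## Mass evidence

Sequence masses use standard 5-significant-figure average (or
monoisotopic) residue masses plus one water; the bundled 80-residue
antitoxin sequence gives 8964.84 Da, matching its published chemical
composition (the corresponding "dimer ≈ 17 912 Da" figure circulating for
this protein is 17.7 Da short of 2 × 8964.84; the monomer value is treated
as authoritative). Subunit counts are ranked by residual against integer
multiples of the monomer mass, even multiples only by default (the RHH fold
is an obligate dimer); no tolerance filter is applied unless requested, so
a ranked list is always returned. Native-MS charge series are deconvolved
by clustering the implied masses `z·(m/z) − z·m_H` of all (peak, charge)
pairs and extracting, per cluster, the longest run of consecutive charge
states over distinct peaks. The run extraction matters: co-existing
oligomers of one monomer alias exactly onto each other's masses at rational
charge ratios (a decamer peak at z = 20 implies the tetramer mass at
z = 8), so naive clusters are contaminated. Interleaved series from two or
three species are resolved exactly on jitter-free input.

## Crystal evidence

Solvent-accessible surface areas use a numeric rolling-probe method
(Shrake–Rupley with a deterministic Fibonacci sphere, 960 points, 1.4 Å
probe); it agrees with an independent reference implementation to < 0.1%
on random atom sets. Interface burial is reported as the **total**
ΔSASA over both partners — `SASA(A) + SASA(B) − SASA(A∪B)` — with a
per-residue decomposition that sums to the total; divide by two for the
per-partner convention. Contact typing is distance-only (no hydrogen
positions at low resolution): N/O–N/O pairs ≤ 3.5 Å as hydrogen bonds,
basic side-chain N vs acidic side-chain O ≤ 4.0 Å as salt bridges, and the
carbon+sulfur share of buried area as a hydrophobicity proxy. The Matthews
coefficient is `V_M = V_cell/(Z·n_chains·m_chain)` with solvent fraction
`1 − 1.23/V_M`; a partial-specific-volume variant (`1 − 1.66054·v̄/V_M`,
v̄ = 0.742 cm³/g) is reported alongside. For the bundled crystal form
(C-centred orthorhombic cell 85.01 × 101.70 × 107.23 Å, multiplicity 8,
8 chains per asymmetric unit) the ordered 49-residue core gives 53.5%
solvent; full-length 80-residue chains would give 23.9%, flagging the
crystallized species as a truncation product.

## Synthetic data: what it emulates, and what it does not

The synthetic dimer is an abstract compact C2 bead bundle — a confined
self-avoiding walk plus its exact two-fold image — not a fold model. Only
its size, symmetry and rigidity matter to the scattering inference; real
coordinates enter through the same types. Walks whose final bead is buried
are rejected at generation time (terminal bead must sit in the outermost
bond-length shell with the last bond pointing outward), because the
disordered tail of the real protein exits at the domain surface and a
buried anchor leaves nowhere to grow.

Noise is additive Gaussian with σ affine in I
(`σᵢ = f·(Iᵢ + 0.01·I(0))` at noise fraction f, default 0.02) — the
simplest model consistent with normalized, buffer-subtracted SEC-SAXS
frames; Poisson counting, beam smearing, inter-frame drift and buffer
mismatch are deliberately not modelled. Native-MS peaks are point
positions `(nM + z·m_H)/z` with optional Gaussian m/z jitter; no peak
shapes, adducts or ion-mobility structure. MALS observations are Gaussian
around `n·M`. Consequently, a passing test suite demonstrates that the
*inference machinery* is correct and well-calibrated under its stated
statistical assumptions — not that those assumptions capture every artifact
of real beamline or spectrometer data.

Default study conditions: 49 structured residues per chain, 30-residue
C-terminal tails (N-terminal stubs of a few residues are omitted; the
entropic argument concerns the C-terminal region), a 6-dimer true assembly,
2% relative noise, 101 q-points on (0, 0.5] Å⁻¹, 100 conformers per
ensemble. Under these conditions the size scan recovers the true 12-chain
assembly in 20/20 replicates with the characteristic V-shaped χ² profile
(extremes at 8 and 16 chains strictly above the optimum), and a
noise-free closed 16-chain ring is recovered at the scan boundary.

## Numerical choices and degenerate inputs

* Histogram Debye: 0.5 Å bins for production, 0.1 Å when validating
  against the double loop; `sinc(0) = 1` handled analytically; q = 0
  permitted.
* Guinier: window search starts from the first 20 positive-q points;
  non-positive intensities in the window raise; a non-negative slope
  raises (no Guinier region).
* Kratky peak search restricted to `qRg ≤ 3` to avoid high-q upturns.
* χ²: experimental grid authoritative; missing σ is an error, not a
  default weight.
* Tail growth: angle limits [70°, 150°] guarantee next-nearest-neighbour
  distances ≥ 4.36 Å, so only longer-range pairs need explicit checks; a
  chain exhausting its restart budget raises an error naming the chain and
  conformer.
* Ring metrics require ≥ 3 dimers (axis otherwise undefined); the ring
  axis is stored exactly for constructed rings and estimated from dimer
  centroids (least-squares plane) otherwise, which is exact for ideal
  closed rings.
* Kabsch superposition rejects rank-deficient point sets and never returns
  a reflection.

## Known limitations

* The tail prior is generic; real tails with charge or proline bias would
  have different dimensions, shifting absolute (not relative) χ² values.
* Porod/Vc mass estimates on shape-scattering models are scale-consistent
  but not absolutely calibrated against real-contrast data.
* The mixture fit handles two components only; no ensemble reweighting.
* Whether tails may thread the central hole is not restricted (a config
  question left open by the crystal evidence); the ensembles generated
  here rarely do so spontaneously.
* Hydrogen-bond assignment is distance-only and will overcount at
  interfaces rich in close polar contacts.
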