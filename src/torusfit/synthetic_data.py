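"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis needs can be generated here, so nothing has to be
downloaded to run or test the pipeline:

* an abstract compact C2-symmetric bead dimer standing in for the folded
  ribbon-helix-helix dimer (only its size, symmetry and rigidity matter to
  the scattering inference -- real coordinates slot in through the same
  types);
* noisy SEC-SAXS-like observations of a model curve (additive Gaussian
  noise with sigma affine in I, the simplest model consistent with
  normalized, buffer-subtracted frames);
* native-MS peak lists for oligomer mixtures (point peaks at
  ``(n*M + z*m_p)/z``, no peak-shape modelling);
* SEC-MALS-like molecular-weight series.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assembly, saxs_core
from .assembly import BeadChain, BeadModel, OligomerModel, RigidTransform, TailSpec
from .errors import GrowthFailureError, InvalidArgumentError
from .mass_evidence import MassObservation, PROTON_MASS

__all__ = [
    "SyntheticSpec",
    "NoiseModel",
    "make_core_dimer",
    "simulate_saxs_observation",
    "simulate_native_ms_peaks",
    "simulate_mals_series",
    "reference_assembly",
    "simulate_saxs_experiment",
]

#: packing radius of the per-chain confinement sphere, Angstrom per bead^(1/3)
CHAIN_RADIUS_PER_CBRT_BEAD = 2.8


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic experiment.

    Defaults mirror the modelled system: 49 structured residues per chain
    (the crystallographically ordered span), a 30-residue disordered
    C-terminal tail, a 6-dimer (dodecameric) true assembly, 2% relative
    noise and a 0.5 inverse-Angstrom momentum-transfer cutoff.
    """

    seed: int
    residues_per_core_chain: int = 49
    tail_length: int = 30
    n_dimers_true: int = 6
    noise_fraction: float = 0.02
    q_max: float = 0.5
    q_min: float = 0.01
    n_q: int = 101
    n_conformers: int = 100

    def __post_init__(self):
        if self.tail_length < 0:
            raise InvalidArgumentError("tail_length must be >= 0")
        if self.q_max <= 0:
            raise InvalidArgumentError("q_max must be positive")

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)


@dataclass
class NoiseModel:
    """Per-point error model ``sigma_i = sigma_floor + sigma_scale * I_i``."""

    sigma_floor: float = 0.0
    sigma_scale: float = 0.02

    def sigma(self, I: np.ndarray) -> np.ndarray:
        s = self.sigma_floor + self.sigma_scale * np.asarray(I, dtype=float)
        if np.any(s < 0):
            raise InvalidArgumentError("noise model produced negative sigma")
        return s

    @classmethod
    def relative(cls, fraction: float, I0: float) -> "NoiseModel":
        """Mostly-relative noise with a small floor tied to ``I(0)``.

        ``sigma_i = fraction * (I_i + 0.01 * I0)``: the floor keeps errors
        positive in the high-q tail where I approaches zero.
        """
        return cls(sigma_floor=fraction * 0.01 * I0, sigma_scale=fraction)


# --------------------------------------------------------------------------
# core dimer
# --------------------------------------------------------------------------

def make_core_dimer(residues_per_chain: int, seed: int,
                    spec: TailSpec | None = None) -> BeadModel:
    """Generate an abstract compact C2 bead dimer.

    Chain A is a self-avoiding 3.8 A virtual-bond walk confined to a sphere
    whose radius scales with the cube root of the bead count (compactness);
    chain B is its exact image under a 180-degree rotation about z, and the
    centre of mass is moved to the origin (a shift along z, which preserves
    the two-fold).  The walk is rejected unless its final bead sits in the
    outermost bond-length shell of the confinement sphere with its last
    bond pointing outward -- the disordered tail of the real protein exits
    at the domain surface, and a buried chain terminus would leave nowhere
    for a tail to grow.  Deterministic for a fixed seed.
    """
    if residues_per_chain < 2:
        raise InvalidArgumentError("residues_per_chain must be >= 2")
    walk = spec or TailSpec(tail_length=residues_per_chain)
    r_chain = CHAIN_RADIUS_PER_CBRT_BEAD * residues_per_chain ** (1.0 / 3.0)
    centre_x = r_chain + walk.clash_cutoff / 2.0 + 0.1
    centre = np.array([centre_x, 0.0, 0.0])
    inside = lambda p: np.sum((p - centre) ** 2) <= r_chain**2

    rng = np.random.default_rng([seed, 0x0D1])
    chain = None
    for _ in range(walk.max_attempts):
        cand = assembly._grow_chain(rng, centre, None, residues_per_chain,
                                    walk, None, [], inside=inside)
        if cand is None:
            continue
        radial = cand[-1] - centre
        radius = np.linalg.norm(radial)
        last_bond = cand[-1] - cand[-2]
        outward = float(np.dot(last_bond, radial)) / (
            np.linalg.norm(last_bond) * max(radius, 1e-9))
        if radius >= r_chain - walk.bond_length and outward > 0.2:
            chain = cand
            break
    if chain is None:
        raise GrowthFailureError("A", 0, walk.max_attempts)

    c2 = RigidTransform.about_axis((0, 0, 1), np.pi)
    mate = c2.apply(chain)
    com = np.concatenate([chain, mate]).mean(axis=0)
    chain = chain - com
    mate = mate - com
    idx = np.arange(1, residues_per_chain + 1)
    return BeadModel([
        BeadChain("A", idx, chain),
        BeadChain("B", idx, mate),
    ])


def make_sphere_model(radius: float = 30.0, spacing: float = 1.5) -> tuple:
    """Uniform-density bead sphere on a cubic grid.

    Returns ``(coords, effective_radius)`` where the effective radius is
    the radius of the continuum sphere with the same volume as the bead
    set (``count * spacing^3``) -- the correct reference when comparing
    the Debye curve against the analytic sphere form factor.
    """
    if radius <= 0 or spacing <= 0:
        raise InvalidArgumentError("radius and spacing must be positive")
    g = np.arange(-radius, radius + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.sum(pts**2, axis=1) <= radius**2]
    r_eff = (len(pts) * spacing**3 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return pts, float(r_eff)


def make_gaussian_globule(Rg: float = 25.0, spacing: float = 2.5,
                          extent_sigmas: float = 4.0) -> tuple:
    """Soft compact globule: grid beads weighted by a Gaussian density.

    A Gaussian radial density has the exactly Guinier-law form factor
    ``I(q) = I0 exp(-q^2 Rg^2 / 3)`` at all ``q``, so this is the
    canonical globular reference particle: its dimensionless Kratky plot
    peaks at ``(sqrt(3), 3/e) ~ (1.73, 1.10)``.  Returns
    ``(coords, weights)``.
    """
    if Rg <= 0 or spacing <= 0:
        raise InvalidArgumentError("Rg and spacing must be positive")
    sigma = Rg / np.sqrt(3.0)
    rmax = extent_sigmas * sigma
    g = np.arange(-rmax, rmax + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r2 = np.sum(pts**2, axis=1)
    keep = r2 <= rmax**2
    pts, r2 = pts[keep], r2[keep]
    weights = np.exp(-r2 / (2.0 * sigma**2))
    return pts, weights


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------

def simulate_saxs_observation(true_curve: saxs_core.SAXSCurve,
                              noise: NoiseModel,
                              seed: int) -> saxs_core.SAXSCurve:
    """Noisy observation ``I_i = I_true,i + N(0, sigma_i)``.

    The sigma column of the returned curve holds the model errors, so a
    chi-square of the truth against its own observation has expectation 1.
    A noise model with zero floor and zero scale returns the input
    unchanged (exact zero-noise case).
    """
    if np.any(np.diff(true_curve.q) <= 0):
        raise InvalidArgumentError("true curve must have strictly increasing q")
    sigma = noise.sigma(true_curve.I)
    if np.all(sigma == 0):
        return saxs_core.SAXSCurve(q=true_curve.q.copy(), I=true_curve.I.copy(),
                                   sigma=None)
    if np.any(sigma <= 0):
        raise InvalidArgumentError("noise sigma must be positive for all points")
    rng = np.random.default_rng([seed, 0x5A5])
    I_obs = true_curve.I + rng.normal(0.0, sigma)
    return saxs_core.SAXSCurve(q=true_curve.q.copy(), I=I_obs, sigma=sigma)


def simulate_native_ms_peaks(
    mixture: dict[int, float],
    monomer_mass: float,
    charge_range: tuple[int, int],
    mz_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Point peaks of a native-MS spectrum of an oligomer mixture.

    For each species with ``n`` subunits (mass ``n * monomer_mass``) and
    each charge ``z`` in the inclusive ``charge_range``, one peak at
    ``(M + z * m_proton)/z`` plus Gaussian m/z jitter.  Returns a frame
    with columns ``n``, ``z``, ``mz``, ``fraction``.
    """
    if not mixture:
        raise InvalidArgumentError("mixture must not be empty")
    if monomer_mass <= 0:
        raise InvalidArgumentError("monomer_mass must be positive")
    z_lo, z_hi = charge_range
    if z_hi < z_lo:
        raise InvalidArgumentError("charge_range must be non-empty")
    fractions = np.array(list(mixture.values()), dtype=float)
    if not np.isclose(fractions.sum(), 1.0, atol=1e-6):
        raise InvalidArgumentError("mixture fractions must sum to 1")
    rng = np.random.default_rng([seed, 0x335])
    rows = []
    for n, frac in sorted(mixture.items()):
        M = n * monomer_mass
        for z in range(z_lo, z_hi + 1):
            mz = (M + z * PROTON_MASS) / z
            if mz_sd > 0:
                mz += rng.normal(0.0, mz_sd)
            rows.append({"n": n, "z": z, "mz": mz, "fraction": frac})
    return pd.DataFrame(rows)


def simulate_mals_series(
    n_true: int,
    monomer_mass: float,
    concentrations,
    mw_sd: float,
    seed: int = 0,
) -> list[MassObservation]:
    """SEC-MALS-like molecular weights, one per injected concentration.

    Each observation is Gaussian around ``n_true * monomer_mass``; MALS
    mass estimates are shape-independent, so no elution modelling is done.
    """
    if n_true < 1:
        raise InvalidArgumentError("n_true must be >= 1")
    concentrations = list(concentrations)
    if not concentrations:
        raise InvalidArgumentError("concentration list must not be empty")
    rng = np.random.default_rng([seed, 0x3A7])
    true_mass = n_true * monomer_mass
    out = []
    for _ in concentrations:
        mass = true_mass + (rng.normal(0.0, mw_sd) if mw_sd > 0 else 0.0)
        out.append(MassObservation(mass=mass, sd=mw_sd, source="mals"))
    return out


# --------------------------------------------------------------------------
# full synthetic experiment
# --------------------------------------------------------------------------

def reference_assembly(spec: SyntheticSpec) -> tuple[BeadModel, OligomerModel]:
    """The true dimer and its partial-ring placement for a synthetic study."""
    dimer = make_core_dimer(spec.residues_per_core_chain, spec.seed)
    ring = assembly.ring_layout(dimer, spec.n_dimers_true)
    return dimer, ring


def simulate_saxs_experiment(
    spec: SyntheticSpec,
    bin_width: float = 0.5,
) -> dict:
    """Generate a complete synthetic SEC-SAXS observation.

    Builds the true partial ring, grows a tail ensemble, averages the Debye
    curves of all conformers into the true scattering curve, and returns a
    noisy observation of it together with the ground-truth objects.
    """
    dimer, ring = reference_assembly(spec)
    tail_spec = TailSpec(tail_length=spec.tail_length)
    ensemble = assembly.grow_tails(ring, tail_spec, spec.n_conformers,
                                   seed=spec.seed)
    q = spec.q_grid
    curves = [saxs_core.debye_intensity(c, q, weights=ensemble.weights,
                                        bin_width=bin_width)
              for c in ensemble.conformers]
    truth = saxs_core.ensemble_average(curves)
    I0 = float(np.sum(ensemble.weights)) ** 2
    noise = NoiseModel.relative(spec.noise_fraction, I0)
    observation = simulate_saxs_observation(truth, noise, seed=spec.seed)
    return {
        "spec": spec,
        "dimer": dimer,
        "ring": ring,
        "ensemble": ensemble,
        "truth": truth,
        "observation": observation,
        "noise": noise,
    }
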