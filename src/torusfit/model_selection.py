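"""Chi-square scoring, ensemble selection and the oligomer-size scan.

The oligomeric state of a partial-ring assembly is selected by comparing
the ensemble-averaged Debye scattering of candidate sizes against an
experimental curve with the reduced chi-square

    chi^2 = (1/n) * sum_i ((c * I_calc,i - I_exp,i) / dI_exp,i)^2

(``n`` = number of experimental points; ``c`` an optional closed-form
least-squares intensity scale, on by default as is standard when the
experimental curve is on an arbitrary scale).  For each candidate size an
ensemble of tail conformers is generated, each conformer is scored, the
best ``keep`` of ``n_structures`` are intensity-averaged, and the size with
the lowest chi-square of its kept average wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assembly, saxs_core
from .assembly import BeadModel, OligomerModel, RigidTransform, TailEnsemble, TailSpec
from .errors import InvalidArgumentError, InvalidDataError
from .saxs_core import SAXSCurve

__all__ = [
    "ChiSquareFit",
    "SizeScanResult",
    "MixtureResult",
    "chi_square",
    "score_ensemble",
    "scan_oligomer_sizes",
    "mixture_fit",
]

DEFAULT_Q_CUTOFF = 0.5  # inverse Angstrom


@dataclass
class ChiSquareFit:
    """Reduced chi-square of a calculated curve against an experiment."""

    chi2: float
    scale_c: float
    n_points: int
    q_cutoff: float


@dataclass
class SizeScanResult:
    """Per-size misfit table of an oligomer-size scan."""

    per_size: dict[int, ChiSquareFit]
    best_n: int
    curves: dict[int, SAXSCurve] = field(default_factory=dict)

    @classmethod
    def from_fits(cls, per_size: dict[int, ChiSquareFit],
                  curves: dict[int, SAXSCurve] | None = None):
        # argmin with ties broken toward the smaller size
        best = min(sorted(per_size), key=lambda n: per_size[n].chi2)
        return cls(per_size=per_size, best_n=best, curves=curves or {})


@dataclass
class MixtureResult:
    """Best two-component mixture fit."""

    fraction_a: float
    chi2: float
    scale_c: float


def _restrict(curve: SAXSCurve, q_cutoff: float) -> SAXSCurve:
    keep = curve.q < q_cutoff
    return SAXSCurve(q=curve.q[keep], I=curve.I[keep],
                     sigma=None if curve.sigma is None else curve.sigma[keep])


def chi_square(
    calc: SAXSCurve,
    exp: SAXSCurve,
    fit_scale: bool = True,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> ChiSquareFit:
    """Reduced chi-square of ``calc`` against ``exp``.

    The experimental grid is authoritative: ``calc`` is linearly
    interpolated onto it, points at ``q >= q_cutoff`` are dropped first,
    and the normalization is ``1/n`` over the surviving points.  With
    ``fit_scale`` the closed-form least-squares scale
    ``c = sum(Ic Ie / s^2) / sum(Ic^2 / s^2)`` is applied, otherwise
    ``c = 1``.
    """
    if exp.sigma is None:
        raise InvalidDataError("experimental curve must carry errors (sigma)")
    exp = _restrict(exp, q_cutoff)
    if len(exp) < 2:
        raise InvalidArgumentError("fewer than 2 experimental points below q_cutoff")
    Ic = np.interp(exp.q, calc.q, calc.I)
    Ie, s = exp.I, exp.sigma
    if fit_scale:
        c = float(np.sum(Ic * Ie / s**2) / np.sum(Ic**2 / s**2))
    else:
        c = 1.0
    chi2 = float(np.mean(((c * Ic - Ie) / s) ** 2))
    return ChiSquareFit(chi2=chi2, scale_c=c, n_points=len(exp),
                        q_cutoff=q_cutoff)


def score_ensemble(
    ensemble: TailEnsemble,
    exp: SAXSCurve,
    keep: int = 10,
    fit_scale: bool = True,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    bin_width: float = 0.5,
) -> tuple[SAXSCurve, ChiSquareFit]:
    """Score a tail ensemble: keep the best conformers, fit their average.

    Each conformer's Debye curve is scored individually; the ``keep``
    lowest-chi-square conformers are intensity-averaged and the returned
    fit is the chi-square of that average.  Ranking by per-conformer
    chi-square stands in for ranking by a refinement energy whose
    data term dominates.
    """
    if keep < 1:
        raise InvalidArgumentError("keep must be >= 1")
    if keep > ensemble.n_conformers:
        raise InvalidArgumentError("keep cannot exceed the ensemble size")
    exp_r = _restrict(exp, q_cutoff)
    q = exp_r.q
    curves = [saxs_core.debye_intensity(c, q, weights=ensemble.weights,
                                        bin_width=bin_width)
              for c in ensemble.conformers]
    scores = np.array([
        chi_square(c, exp, fit_scale=fit_scale, q_cutoff=q_cutoff).chi2
        for c in curves
    ])
    order = np.argsort(scores, kind="stable")[:keep]
    avg = saxs_core.ensemble_average([curves[i] for i in order])
    fit = chi_square(avg, exp, fit_scale=fit_scale, q_cutoff=q_cutoff)
    return avg, fit


def scan_oligomer_sizes(
    dimer: BeadModel,
    transform: RigidTransform,
    sizes,
    tails: TailSpec,
    exp: SAXSCurve,
    seed: int,
    n_structures: int = 100,
    keep: int = 10,
    fit_scale: bool = True,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    bin_width: float = 0.5,
) -> SizeScanResult:
    """Chi-square scan over candidate oligomer sizes (chain counts).

    For each even chain count ``2k`` a ``k``-dimer partial ring is built
    from the placed dimer and the inter-dimer transform, a tail ensemble of
    ``n_structures`` conformers is grown (substream per size), and the
    kept-average chi-square recorded.  ``best_n`` is the argmin chain
    count (ties toward the smaller assembly).
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise InvalidArgumentError("sizes must not be empty")
    for s in sizes:
        if s % 2 != 0 or not 2 <= s <= 2 * assembly.MAX_DIMERS:
            raise InvalidArgumentError(
                f"sizes must be even chain counts in [2, {2 * assembly.MAX_DIMERS}]"
            )
    per_size: dict[int, ChiSquareFit] = {}
    curves: dict[int, SAXSCurve] = {}
    for s in sizes:
        k = s // 2
        ring = assembly.build_partial_ring(dimer, transform, k)
        ensemble = assembly.grow_tails(ring, tails, n_structures,
                                       seed=np.random.SeedSequence(
                                           [seed, s]).generate_state(1)[0] % (2**31))
        avg, fit = score_ensemble(ensemble, exp, keep=keep,
                                  fit_scale=fit_scale, q_cutoff=q_cutoff,
                                  bin_width=bin_width)
        per_size[s] = fit
        curves[s] = avg
    return SizeScanResult.from_fits(per_size, curves)


def mixture_fit(
    curve_a: SAXSCurve,
    curve_b: SAXSCurve,
    exp: SAXSCurve,
    grid_step: float = 0.05,
    fit_scale: bool = True,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> MixtureResult:
    """Best two-component fit ``I = f * I_a + (1 - f) * I_b``.

    ``f`` is scanned on a grid (endpoints included) and refined once by
    parabolic interpolation around the grid minimum; the overall intensity
    scale is handled by :func:`chi_square`.  The best mixture can never be
    worse than either pure endpoint.
    """
    if not curve_a.same_grid(curve_b):
        raise InvalidArgumentError("component curves must share a q grid")
    if exp.sigma is None:
        raise InvalidDataError("experimental curve must carry errors (sigma)")

    def chi(f: float) -> ChiSquareFit:
        mix = SAXSCurve(q=curve_a.q, I=f * curve_a.I + (1 - f) * curve_b.I)
        return chi_square(mix, exp, fit_scale=fit_scale, q_cutoff=q_cutoff)

    fractions = np.arange(0.0, 1.0 + 1e-9, grid_step)
    chis = np.array([chi(f).chi2 for f in fractions])
    i = int(np.argmin(chis))
    best_f = float(fractions[i])
    if 0 < i < fractions.size - 1:
        x0, x1, x2 = fractions[i - 1:i + 2]
        y0, y1, y2 = chis[i - 1:i + 2]
        denom = (y0 - 2 * y1 + y2)
        if denom > 0:
            h = x1 - x0
            cand = x1 + h * (y0 - y2) / (2 * denom)
            cand = float(np.clip(cand, 0.0, 1.0))
            if chi(cand).chi2 <= chis[i]:
                best_f = cand
    fit = chi(best_f)
    return MixtureResult(fraction_a=best_f, chi2=fit.chi2, scale_c=fit.scale_c)
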