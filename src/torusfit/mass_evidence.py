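"""Mass-based stoichiometry evidence.

Three independent lines of evidence constrain the subunit count of an
oligomer in solution: the chemical mass of the monomer from its sequence,
shape-independent molecular weights (SEC-MALS, SAXS-derived), and native
mass spectrometry, where a series of peaks at consecutive charge states
inverts to the intact mass.  For an obligate-dimer building block the
subunit count is assumed even unless stated otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, NoConsistentSeriesError

__all__ = [
    "MassObservation",
    "StoichiometryCall",
    "ChargeSeries",
    "sequence_mass",
    "oligomer_from_mass",
    "deconvolute_charges",
    "stoichiometry_report",
    "PROTON_MASS",
]

PROTON_MASS = 1.00728  # Da

# average residue masses, Da (standard 5-significant-figure tables)
_AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
_WATER_AVERAGE = 18.0153

# monoisotopic residue masses, Da
_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_WATER_MONO = 18.010565


@dataclass
class MassObservation:
    """One molecular-weight measurement with its uncertainty and origin."""

    mass: float
    sd: float = 0.0
    source: str = "mals"  # mals | saxs | ms

    def __post_init__(self):
        if self.mass <= 0:
            raise InvalidArgumentError("mass must be positive")
        if self.sd < 0:
            raise InvalidArgumentError("sd must be >= 0")


@dataclass
class StoichiometryCall:
    """A candidate subunit count for an observed mass."""

    n: int
    implied_mass: float
    residual: float
    ratio: float


@dataclass
class ChargeSeries:
    """A consistent charge-state series: one species in a native MS spectrum."""

    mass: float
    mass_sd: float
    charges: list[int]
    peaks: list[float]          # the m/z values assigned to this series
    peak_indices: list[int]


def sequence_mass(sequence: str, mode: str = "average") -> float:
    """Chemical mass of a one-letter amino-acid sequence plus one water.

    ``mode`` selects average or monoisotopic residue masses.  Unknown
    letters raise with the offending position named.
    """
    if not sequence:
        raise InvalidArgumentError("sequence must be non-empty")
    if mode == "average":
        table, water = _AVERAGE, _WATER_AVERAGE
    elif mode == "monoisotopic":
        table, water = _MONO, _WATER_MONO
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    total = water
    for i, aa in enumerate(sequence.upper()):
        try:
            total += table[aa]
        except KeyError:
            raise InvalidArgumentError(
                f"unknown residue {aa!r} at position {i + 1}"
            ) from None
    return total


def oligomer_from_mass(
    obs: MassObservation,
    monomer_mass: float,
    parity: str = "even",
    tolerance_sd: float | None = None,
    n_max: int = 32,
) -> list[StoichiometryCall]:
    """Rank candidate subunit counts for an observed mass.

    Candidates ``n = 1..n_max`` (even only with ``parity='even'``, encoding
    an obligate-dimer building block) are ranked by the absolute residual
    ``|observed - n * monomer_mass|``.  With ``tolerance_sd`` set and a
    positive observation sd, candidates whose residual exceeds
    ``tolerance_sd * sd`` are dropped (possibly leaving an empty list --
    an inconclusive observation, not an error).
    """
    if monomer_mass <= 0:
        raise InvalidArgumentError("monomer_mass must be positive")
    if parity not in ("any", "even"):
        raise InvalidArgumentError("parity must be 'any' or 'even'")
    step = 2 if parity == "even" else 1
    start = 2 if parity == "even" else 1
    ratio = obs.mass / monomer_mass
    calls = []
    for n in range(start, n_max + 1, step):
        implied = n * monomer_mass
        residual = abs(obs.mass - implied)
        if tolerance_sd is not None and obs.sd > 0 and \
                residual > tolerance_sd * obs.sd:
            continue
        calls.append(StoichiometryCall(n=n, implied_mass=implied,
                                       residual=residual, ratio=ratio))
    calls.sort(key=lambda c: (c.residual, c.n))
    return calls


def _best_consecutive_run(group):
    """Longest run of consecutive charges with distinct peaks in a cluster.

    ``group`` holds ``(implied mass, peak index, charge)`` tuples whose
    masses agree within tolerance.  Charges sharing a state keep the member
    closest to the cluster median mass; among equal-length runs the one
    with the smallest implied-mass spread wins.
    """
    med = float(np.median([m for m, _, _ in group]))
    by_z: dict[int, tuple] = {}
    for m, ip, z in group:
        if z not in by_z or abs(m - med) < abs(by_z[z][0] - med):
            by_z[z] = (m, ip, z)
    zs = sorted(by_z)
    best: list = []
    best_sd = np.inf
    i = 0
    while i < len(zs):
        j = i
        while j + 1 < len(zs) and zs[j + 1] == zs[j] + 1:
            j += 1
        run = [by_z[z] for z in zs[i:j + 1]]
        # runs must use distinct peaks
        if len({ip for _, ip, _ in run}) == len(run):
            sd = float(np.std([m for m, _, _ in run]))
            if len(run) > len(best) or (len(run) == len(best) and sd < best_sd):
                best, best_sd = run, sd
        i = j + 1
    return best


def deconvolute_charges(
    peaks,
    proton_mass: float = PROTON_MASS,
    z_max: int = 30,
    z_min: int = 2,
    mass_tol_rel: float = 2e-4,
    max_series: int = 4,
    min_series_peaks: int = 2,
) -> list[ChargeSeries]:
    """Assign charge states to m/z peaks and recover intact masses.

    Every (peak, charge) pair implies a neutral mass
    ``M = z * (m/z) - z * m_proton``; peaks belonging to one species at
    consecutive charges imply the *same* mass.  Implied masses are
    clustered within a relative tolerance, clusters are scored by how many
    distinct peaks they explain at distinct charges (spread of the implied
    masses breaks ties), and peaks are greedily assigned to the best
    clusters.  Handles interleaved series from co-existing oligomers.
    """
    peaks = np.asarray(list(peaks), dtype=float)
    if peaks.size < 2:
        raise InvalidArgumentError("need at least 2 peaks")
    if z_max < 2:
        raise InvalidArgumentError("z_max must be >= 2")

    cand = []  # (implied mass, peak index, z)
    for i, mz in enumerate(peaks):
        for z in range(z_min, z_max + 1):
            cand.append((z * mz - z * proton_mass, i, z))
    cand.sort(key=lambda t: t[0])
    masses = np.array([c[0] for c in cand])

    # cluster by sliding window within relative tolerance, then extract the
    # longest run of consecutive charge states from each cluster (peaks of
    # co-existing oligomers of one monomer alias exactly onto each other's
    # masses at rational charge ratios, so clusters may contain stragglers)
    clusters = []
    start = 0
    for i in range(1, len(cand) + 1):
        if i == len(cand) or masses[i] - masses[start] > mass_tol_rel * masses[start]:
            group = cand[start:i]
            run = _best_consecutive_run(group)
            if len(run) >= min_series_peaks:
                ms = np.array([m for m, _, _ in run])
                clusters.append({
                    "mass": float(ms.mean()),
                    "sd": float(ms.std()),
                    "members": {ip: z for _, ip, z in run},
                })
            start = i

    if not clusters:
        raise NoConsistentSeriesError(
            "no set of peaks maps to one mass at consecutive charges"
        )

    clusters.sort(key=lambda c: (-len(c["members"]), c["sd"]))
    assigned: set[int] = set()
    series: list[ChargeSeries] = []
    for c in clusters:
        members = {ip: z for ip, z in c["members"].items() if ip not in assigned}
        if len(members) < min_series_peaks:
            continue
        ms = np.array([z * peaks[ip] - z * proton_mass
                       for ip, z in members.items()])
        series.append(ChargeSeries(
            mass=float(ms.mean()), mass_sd=float(ms.std()),
            charges=[members[ip] for ip in sorted(members)],
            peaks=[float(peaks[ip]) for ip in sorted(members)],
            peak_indices=sorted(members),
        ))
        assigned.update(members)
        if len(series) >= max_series:
            break
    if not series:
        raise NoConsistentSeriesError(
            "no set of peaks maps to one mass at consecutive charges"
        )
    series.sort(key=lambda s: -len(s.charges))
    return series


def stoichiometry_report(
    calls_by_source: dict[str, list[list[StoichiometryCall]]],
    monomer_mass: float,
    top: int = 2,
) -> dict:
    """Consolidate per-source stoichiometry calls into a consensus histogram.

    ``calls_by_source`` maps a source label to a list of ranked call lists
    (one per observation from that source).  The consensus counts, over all
    observations, the subunit numbers appearing among each observation's
    ``top`` calls; sources contributing only empty call lists are recorded
    as skipped.
    """
    if not calls_by_source:
        raise InvalidArgumentError("need at least one source")
    consensus: Counter = Counter()
    per_source = {}
    skipped = []
    for source, obs_lists in calls_by_source.items():
        counter: Counter = Counter()
        for calls in obs_lists:
            for call in calls[:top]:
                counter[call.n] += 1
        if counter:
            per_source[source] = dict(sorted(counter.items()))
            consensus.update(counter)
        else:
            skipped.append(source)
    return {
        "monomer_mass": monomer_mass,
        "per_source": per_source,
        "consensus": dict(sorted(consensus.items())),
        "skipped_sources": skipped,
    }
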