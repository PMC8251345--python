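"""On-disk formats: SAXS ``.dat`` profiles, bead-model PDB, CSV tables.

SAXS curves use the de-facto 3-column ASCII dialect (q in inverse
Angstrom, I, sigma; ``#`` comment lines).  Bead models are written as PDB
with one CA pseudo-atom per residue so any molecular viewer can display
them; tail-ensemble conformers go into one multi-model PDB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assembly import BeadChain, BeadModel, OligomerModel, TailEnsemble
from .errors import InvalidDataError
from .mass_evidence import MassObservation
from .saxs_core import PrCurve, SAXSCurve

__all__ = [
    "read_saxs_dat", "write_saxs_dat", "write_pr_curve",
    "write_bead_pdb", "read_bead_pdb", "write_ensemble_pdb",
    "write_peaks_csv", "read_peaks_csv",
    "write_mals_csv", "read_mals_csv",
]

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def read_saxs_dat(path) -> SAXSCurve:
    """Read a 3-column (or 2-column) ASCII scattering profile."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise InvalidDataError(f"{path}: need at least two columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(q=data[:, 0], I=data[:, 1], sigma=sigma)


def write_saxs_dat(curve: SAXSCurve, path, header: str = "") -> None:
    cols = [curve.q, curve.I]
    names = "q[1/A] I(q)"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names += " sigma"
    head = (header + "\n" if header else "") + names
    np.savetxt(path, np.column_stack(cols), header=head, comments="# ")


def write_pr_curve(pr: PrCurve, path) -> None:
    np.savetxt(path, np.column_stack([pr.r, pr.P]),
               header=f"dmax={pr.dmax:.3f} Rg={pr.Rg_pr:.3f}\nr[A] P(r)",
               comments="# ")


# --------------------------------------------------------------------------
# bead models as PDB
# --------------------------------------------------------------------------

def _model_chains(model) -> list[BeadChain]:
    if isinstance(model, BeadModel):
        return model.chains
    if isinstance(model, OligomerModel):
        return model.chains
    raise InvalidDataError("expected a BeadModel or OligomerModel")


def _pdb_lines(chains: list[BeadChain]) -> list[str]:
    lines = []
    serial = 1
    for ic, chain in enumerate(chains):
        cid = _CHAIN_ALPHABET[ic % len(_CHAIN_ALPHABET)]
        for ridx, (x, y, z) in zip(chain.residue_index, chain.coords):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {cid}{int(ridx):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      ALA {cid}{int(chain.residue_index[-1]):4d}")
        serial += 1
    return lines


def write_bead_pdb(model, path) -> None:
    """One CA pseudo-atom per bead, one PDB chain per bead chain."""
    lines = _pdb_lines(_model_chains(model))
    with open(path, "w") as fh:
        fh.write("\n".join(lines + ["END"]) + "\n")


def read_bead_pdb(path) -> BeadModel:
    """Read a (pseudo-atom) PDB back into a BeadModel, one bead per CA."""
    chains: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            name = line[12:16].strip()
            if name != "CA":
                continue
            cid = line[21]
            if cid not in chains:
                chains[cid] = []
                order.append(cid)
            chains[cid].append((
                int(line[22:26]),
                float(line[30:38]), float(line[38:46]), float(line[46:54]),
            ))
    if not chains:
        raise InvalidDataError(f"{path}: no CA records found")
    out = []
    for cid in order:
        rows = chains[cid]
        out.append(BeadChain(
            chain_id=cid,
            residue_index=np.array([r[0] for r in rows]),
            coords=np.array([r[1:] for r in rows]),
        ))
    return BeadModel(out)


def write_ensemble_pdb(ensemble: TailEnsemble, path) -> None:
    """All conformers of a tail ensemble as a multi-model PDB."""
    core_chains = ensemble.base_model.chains
    n_core_per = [len(c) for c in core_chains]
    L = ensemble.spec.tail_length
    with open(path, "w") as fh:
        for im, conf in enumerate(ensemble.conformers, start=1):
            fh.write(f"MODEL     {im:4d}\n")
            chains = []
            off = 0
            for c, n in zip(core_chains, n_core_per):
                core = conf[off:off + n]
                off += n
                chains.append((c, core))
            tails = conf[sum(n_core_per):]
            full = []
            for j, (c, core) in enumerate(chains):
                tail = tails[j * L:(j + 1) * L]
                coords = np.concatenate([core, tail], axis=0)
                idx = np.concatenate([
                    c.residue_index,
                    np.arange(1, L + 1) + c.residue_index[-1],
                ])
                full.append(BeadChain(c.chain_id, idx, coords))
            fh.write("\n".join(_pdb_lines(full)) + "\nENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# CSV tables
# --------------------------------------------------------------------------

def write_peaks_csv(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


def read_peaks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "mz" not in df.columns:
        raise InvalidDataError(f"{path}: expected an 'mz' column")
    return df


def write_mals_csv(observations: list[MassObservation], path) -> None:
    pd.DataFrame([
        {"mass": o.mass, "sd": o.sd, "source": o.source}
        for o in observations
    ]).to_csv(path, index=False)


def read_mals_csv(path) -> list[MassObservation]:
    df = pd.read_csv(path)
    if "mass" not in df.columns:
        raise InvalidDataError(f"{path}: expected a 'mass' column")
    return [
        MassObservation(mass=row["mass"], sd=row.get("sd", 0.0) or 0.0,
                        source=str(row.get("source", "mals")))
        for _, row in df.iterrows()
    ]
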