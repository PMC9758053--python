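"""PDB reading/writing for backbone models (via gemmi).

Models are written as ATOM records with TER between chains, 1-based
residue numbering, occupancy 1.00 and B-factor 0.00.  On reading, missing
CB atoms are rebuilt from the ideal residue frame (glycine excepted only
in name -- the rebuilt CB is kept internally since layer logic needs it),
and CA-only traces are completed to full backbones.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from bundleforge.geometry import BACKBONE_ATOMS, BackboneModel, backbone_from_ca


class PDBFormatError(ValueError):
    """Malformed or unusable PDB content."""


def write_model(model: BackboneModel, path: str | Path) -> None:
    """Write the model as a single-model PDB file."""
    structure = gemmi.Structure()
    structure.name = "bundleforge"
    gm = gemmi.Model("1")
    for chain_id in model.chains:
        chain = gemmi.Chain(str(chain_id))
        mask = model.chain_mask(chain_id)
        for i in np.flatnonzero(mask):
            res = gemmi.Residue()
            res.name = str(model.res_names[i])
            res.seqid = gemmi.SeqId(int(model.res_ids[i]), " ")
            for k, name in enumerate(BACKBONE_ATOMS):
                if name == "CB" and res.name == "GLY":
                    continue
                xyz = model.coords[i, k]
                if not np.all(np.isfinite(xyz)):
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_model(path: str | Path) -> BackboneModel:
    """Read a (multi-chain) PDB backbone; completes missing backbone atoms.

    Residues lacking N/C/O/CB are rebuilt from the CA trace with the ideal
    alpha-helical residue frame; residues lacking CA are rejected.
    """
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise PDBFormatError(f"{path}: no models")
    gm = structure[0]
    chain_ids, res_ids, res_names, per_res = [], [], [], []
    for chain in gm:
        for res in chain:
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            if "CA" not in atoms:
                raise PDBFormatError(
                    f"{path}: residue {chain.name}/{res.seqid.num} has no CA"
                )
            chain_ids.append(chain.name)
            res_ids.append(res.seqid.num)
            res_names.append(res.name if res.name else "ALA")
            per_res.append(atoms)
    if not per_res:
        raise PDBFormatError(f"{path}: empty structure")
    n = len(per_res)
    coords = np.full((n, 5, 3), np.nan)
    for i, atoms in enumerate(per_res):
        for k, name in enumerate(BACKBONE_ATOMS):
            if name in atoms:
                coords[i, k] = atoms[name]
    model = BackboneModel(
        np.array(chain_ids, dtype="U4"),
        np.array(res_ids, dtype=int),
        np.array(res_names, dtype="U3"),
        np.nan_to_num(coords, nan=0.0),
    )
    # rebuild any missing backbone atoms chain by chain from the CA trace
    missing = np.isnan(coords).any(axis=(1, 2))
    if missing.any():
        for chain_id in model.chains:
            mask = model.chain_mask(chain_id)
            if not missing[mask].any():
                continue
            idx = np.flatnonzero(mask)
            if len(idx) < 4:
                raise PDBFormatError(
                    f"{path}: chain {chain_id} too short to rebuild backbone"
                )
            rebuilt = backbone_from_ca(coords[idx, 1, :])
            for k, name in enumerate(BACKBONE_ATOMS):
                need = np.isnan(coords[idx, k]).any(axis=1)
                model.coords[idx[need], k] = rebuilt[need, k]
    return model
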