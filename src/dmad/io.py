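"""Structure and table I/O.

PDB/mmCIF reading goes through gemmi: altlocs are resolved to the highest
occupancy (ties by label order), insertion codes are kept in residue
numbering order, hydrogens are optional.  Assemblies and morph frames are
written as (multi-model) PDB.  Bead models use the HETATM record with a
pseudo-element; on reading, unknown elements fall back to the packaged
radii table.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from dmad.builder import AssemblyModel, AtomSet
from dmad.errors import InputError

__all__ = [
    "read_structure",
    "write_atoms_pdb",
    "write_assembly_pdb",
    "write_trajectory_table",
    "write_manifest",
]

_FALLBACK_RADII = {"BD": 6.0, "X": 1.7}


def _element_radius(el: gemmi.Element, symbol: str) -> float:
    r = el.vdw_r
    if r and r > 0.0:
        return float(r)
    from dmad.energy import load_parameter_table

    table = load_parameter_table("vdw_default.tsv")
    return float(table.get(symbol, _FALLBACK_RADII.get(symbol, 1.7)))


def read_structure(path, keep_hydrogens: bool = False) -> dict[str, AtomSet]:
    """Read a PDB or mmCIF file into per-chain AtomSets (first model).

    Altlocs are resolved to the highest-occupancy conformer (label order
    breaks ties); waters are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"{path}: parse error: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy / first label
    st.remove_waters()
    if not keep_hydrogens:
        st.remove_hydrogens()
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    out: dict[str, AtomSet] = {}
    model = st[0]
    for chain in model:
        els, names, ridx, rnames, xyz, radii = [], [], [], [], [], []
        for res in chain:
            for atom in res:
                sym = atom.element.name if atom.element.name else "X"
                els.append(sym)
                names.append(atom.name)
                ridx.append(res.seqid.num)
                rnames.append(res.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(_element_radius(atom.element, sym))
        if not xyz:
            continue
        out[chain.name] = AtomSet(
            element=np.array(els, dtype=object),
            name=np.array(names, dtype=object),
            residue_index=np.array(ridx, dtype=int),
            residue_name=np.array(rnames, dtype=object),
            chain_id=np.full(len(xyz), chain.name, dtype=object),
            xyz=np.array(xyz, dtype=float),
            vdw_radius=np.array(radii, dtype=float),
        )
    if not out:
        raise InputError(f"{path}: no atoms found")
    return out


def _structure_from_atomsets(named: list[tuple[str, AtomSet]]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "dmad"
    model = gemmi.Model("1")
    for chain_name, atoms in named:
        chain = gemmi.Chain(chain_name[:2])
        res = None
        last_idx = None
        for i in range(len(atoms)):
            idx = int(atoms.residue_index[i])
            if res is None or idx != last_idx:
                res = gemmi.Residue()
                res.name = str(atoms.residue_name[i])
                res.seqid = gemmi.SeqId(idx, " ")
                res.het_flag = "H" if str(atoms.element[i]) == "BD" else "A"
                chain.add_residue(res)
                last_idx = idx
            at = gemmi.Atom()
            at.name = str(atoms.name[i])
            sym = str(atoms.element[i])
            at.element = gemmi.Element(sym if sym != "BD" else "C")
            at.pos = gemmi.Position(*atoms.xyz[i])
            at.occ = 1.0
            chain[-1].add_atom(at)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_atoms_pdb(atoms: AtomSet, path) -> None:
    """Write one AtomSet as a single-chain PDB file."""
    st = _structure_from_atomsets([(str(atoms.chain_id[0]), atoms)])
    st.write_pdb(str(path))


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_assembly_pdb(models: list[AssemblyModel], path) -> None:
    """Write contraction intermediates as a multi-model PDB trajectory."""
    st = gemmi.Structure()
    st.name = "dmad-traj"
    for mi, model_obj in enumerate(models, start=1):
        model = gemmi.Model(str(mi))
        keys = sorted(model_obj.subunits, key=lambda k: (k[2], k[0], k[1]))
        for ci, key in enumerate(keys):
            layer, strand, role = key
            tmpl = (
                model_obj.sheath_template if role == "sheath" else model_obj.tube_template
            )
            atoms = tmpl.with_xyz(model_obj.subunits[key])
            chain = gemmi.Chain(_CHAIN_ALPHABET[ci % len(_CHAIN_ALPHABET)])
            sub = _structure_from_atomsets([("X", atoms)])
            for res in sub[0][0]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def write_trajectory_table(traj, path) -> None:
    """Trajectory as a tab-separated table with a unit header."""
    from dmad.propagation import trajectory_to_frame

    df = trajectory_to_frame(traj)
    with open(path, "w") as fh:
        fh.write(
            "# dmad trajectory; lam dimensionless, r/z/b/s/d Angstrom, "
            "theta/kappa radians\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def write_manifest(path, **entries) -> None:
    """Machine-readable run manifest (parameters, versions, inputs)."""
    import dmad

    payload = {"dmad_version": dmad.__version__}
    payload.update(entries)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
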