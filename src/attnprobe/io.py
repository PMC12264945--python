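"""Readers and writers for the formats the pipeline touches.

Sequences come in as FASTA, secondary structures as .dbn (dot-bracket,
optionally with a FASTA-style header) or CT, coordinates as PDB/mmCIF.
Contact maps go out as TSV edge lists ("i<TAB>j", 0-based, i < j) or as
dense 0/1 text matrices.  Attention stacks are stored as .npz containers
(keys: weights, molecule_id, processed) written deterministically --
fixed zip timestamps -- so identical runs produce byte-identical files.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .contacts import ContactMap, Molecule, MoleculeKind, Residue, Structure3D
from .errors import LoadError, ParseError, ValidationError

_PROTEIN_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_RNA_NAMES = {"A": "A", "C": "C", "G": "G", "U": "U"}


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path, kind: MoleculeKind | str) -> list[Molecule]:
    kind = MoleculeKind(kind)
    return [
        Molecule(id=rec.id, sequence=str(rec.seq).upper(), kind=kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(molecules: list[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f">{mol.id}\n{mol.sequence}\n")


# ----------------------------------------------------- secondary structure

def read_dbn(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a .dbn file into (id, sequence, dot-bracket) records.

    Accepts both headered records (``>id`` / sequence / structure) and a
    bare two-line sequence/structure file.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    records: list[tuple[str, str, str]] = []
    i = 0
    anon = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            if i + 2 >= len(lines):
                raise ParseError(f"truncated .dbn record at line {i + 1}")
            rec_id, seq, db = lines[i][1:].split()[0], lines[i + 1], lines[i + 2]
            i += 3
        else:
            if i + 1 >= len(lines):
                raise ParseError(f"truncated .dbn record at line {i + 1}")
            rec_id, seq, db = f"record{anon}", lines[i], lines[i + 1]
            anon += 1
            i += 2
        if len(seq) != len(db):
            raise ParseError(
                f".dbn record {rec_id}: sequence length {len(seq)} != structure length {len(db)}"
            )
        records.append((rec_id, seq.upper(), db))
    return records


def write_dbn(records: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq, db in records:
            fh.write(f">{rec_id}\n{seq}\n{db}\n")


def read_ct(path: str | Path) -> tuple[str, str, set[tuple[int, int]]]:
    """Parse a CT file into (title, sequence, 0-based pair set)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"bad CT header: {lines[0]!r}") from exc
    title = " ".join(header[1:])
    seq: list[str] = []
    pairs: set[tuple[int, int]] = set()
    if len(lines) - 1 < n:
        raise ParseError(f"CT file declares {n} residues but has {len(lines) - 1} rows")
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        seq.append(base.upper())
        if partner > 0 and partner > idx:  # CT is 1-based
            pairs.add((idx - 1, partner - 1))
    return title, "".join(seq), pairs


def write_ct(
    title: str, sequence: str, pairs: set[tuple[int, int]], path: str | Path
) -> None:
    """Write a CT file (1-based indices per the format's convention)."""
    n = len(sequence)
    partner = [0] * n
    for i, j in pairs:
        partner[i], partner[j] = j + 1, i + 1
    with open(path, "w") as fh:
        fh.write(f"{n} {title}\n")
        for i, base in enumerate(sequence):
            fh.write(
                f"{i + 1} {base} {i} {(i + 2) if i + 1 < n else 0} {partner[i]} {i + 1}\n"
            )


# ------------------------------------------------------------ contact maps

def write_contact_map_edges(cmap: ContactMap, path: str | Path) -> None:
    """TSV edge list: one "i<TAB>j" line per contact, 0-based, i < j."""
    ii, jj = np.nonzero(np.triu(cmap.matrix, 1))
    with open(path, "w") as fh:
        fh.write(f"# n={cmap.n}\twindow={cmap.exclusion_window}\tcutoff={cmap.cutoff}\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i}\t{j}\n")


def read_contact_map_edges(path: str | Path) -> ContactMap:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise LoadError(f"{path}: missing edge-list header")
    meta = dict(kv.split("=", 1) for kv in lines[0][1:].split())
    n = int(meta["n"])
    window = int(meta.get("window", 0))
    cutoff_s = meta.get("cutoff", "None")
    cutoff = None if cutoff_s == "None" else float(cutoff_s)
    matrix = np.zeros((n, n), dtype=np.int8)
    for ln in lines[1:]:
        if not ln.strip():
            continue
        i, j = (int(x) for x in ln.split("\t"))
        matrix[i, j] = matrix[j, i] = 1
    return ContactMap(n=n, matrix=matrix, exclusion_window=window, cutoff=cutoff)


def write_contact_map_dense(cmap: ContactMap, path: str | Path) -> None:
    """Dense 0/1 text matrix, one space-separated row per line."""
    np.savetxt(path, cmap.matrix, fmt="%d")


def read_contact_map_dense(
    path: str | Path, window: int = 0, cutoff: float | None = None
) -> ContactMap:
    matrix = np.loadtxt(path, dtype=np.int8, ndmin=2)
    return ContactMap(
        n=matrix.shape[0], matrix=matrix, exclusion_window=window, cutoff=cutoff
    )


# ------------------------------------------------------------- coordinates

def read_structure(
    path: str | Path,
    kind: MoleculeKind | str,
    chain: str | None = None,
    molecule_id: str | None = None,
) -> Structure3D:
    """Read a PDB or mmCIF file into a :class:`Structure3D`.

    Uses the first model.  ``chain`` selects a chain id; if None the
    file must contain a single chain.  Hydrogens are dropped; residues
    with no heavy atoms are rejected during validation.
    """
    import biotite.structure as struc

    path = Path(path)
    kind = MoleculeKind(kind)
    if path.suffix.lower() in (".cif", ".mmcif"):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(f, model=1)
    else:
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(str(path))
        atoms = f.get_structure(model=1)

    chains = sorted(set(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise ValidationError(
                f"{path.name}: multiple chains {chains}; select one with chain="
            )
        chain = chains[0]
    elif chain not in chains:
        raise ValidationError(f"{path.name}: chain {chain!r} not found (have {chains})")

    atoms = atoms[(atoms.chain_id == chain) & (atoms.element != "H")]
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValidationError(f"{path.name}: chain {chain!r} has no polymer atoms")

    residues: list[Residue] = []
    seq: list[str] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        res_atoms = atoms[s:e]
        name = res_atoms.res_name[0]
        if kind is MoleculeKind.RNA:
            one = _RNA_NAMES.get(name)
        else:
            one = _PROTEIN_3TO1.get(name)
        if one is None:
            raise ValidationError(
                f"{path.name}: unsupported residue {name!r} for kind {kind.value} "
                "(modified residues are rejected)"
            )
        seq.append(one)
        residues.append(
            Residue(
                name=name,
                atoms={
                    an: res_atoms.coord[k]
                    for k, an in enumerate(res_atoms.atom_name)
                },
            )
        )
    mol = Molecule(id=molecule_id or path.stem, sequence="".join(seq), kind=kind)
    return Structure3D(molecule=mol, residues=residues)


def write_structure_pdb(structure: Structure3D, path: str | Path) -> None:
    """Write a :class:`Structure3D` as a single-chain PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = sum(len(r.atoms) for r in structure.residues)
    arr = struc.AtomArray(n_atoms)
    k = 0
    rna = structure.molecule.kind is MoleculeKind.RNA
    for idx, res in enumerate(structure.residues):
        for atom_name, coord in res.atoms.items():
            arr.coord[k] = np.asarray(coord, dtype=np.float32)
            arr.chain_id[k] = "A"
            arr.res_id[k] = idx + 1
            arr.res_name[k] = res.name
            arr.atom_name[k] = atom_name
            arr.element[k] = atom_name[0]
            arr.hetero[k] = False
            k += 1
    arr.set_annotation(
        "occupancy", np.ones(n_atoms, dtype=np.float32)
    )
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
    _ = rna  # kind only affects residue naming chosen by the caller


# --------------------------------------------------- attention .npz files

def _write_deterministic_npz(path: str | Path, arrays: dict[str, np.ndarray]) -> None:
    # np.savez stamps zip entries with wall-clock time; write the same
    # container format by hand with fixed timestamps so identical runs
    # yield byte-identical files.
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _stdio.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def save_attention_stack(stack, path: str | Path, provenance: dict | None = None) -> None:
    """Store an attention stack as .npz plus an optional JSON sidecar."""
    _write_deterministic_npz(
        path,
        {
            "weights": stack.weights,
            "molecule_id": np.asarray(stack.molecule_id),
            "processed": np.asarray(stack.processed),
        },
    )
    if provenance is not None:
        Path(str(path) + ".json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )


def load_attention_stack(path: str | Path):
    from .attention import AttentionStack

    try:
        with np.load(path) as data:
            weights = data["weights"]
            molecule_id = str(data["molecule_id"])
            processed = bool(data["processed"])
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise LoadError(f"cannot read attention container {path}: {exc}") from exc
    return AttentionStack(
        molecule_id=molecule_id, weights=weights, processed=processed
    )
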