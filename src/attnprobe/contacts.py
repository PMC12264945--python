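"""Binary contact maps from 3D coordinates or dot-bracket secondary structure.

A contact map is an N x N binary symmetric matrix marking residue pairs
that are spatially close (tertiary contacts within a distance cutoff,
default 9.5 A) or base-paired (secondary structure).  Near-diagonal
entries |i-j| <= w are excluded so downstream models learn long-range
structure rather than chain adjacency; the conventional windows are
w = 4 for nucleotides and w = 6 for amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    MissingCoordinateError,
    ParseError,
    RangeError,
    ShapeError,
    ValidationError,
)

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default exclusion windows (positions) per molecule kind
DEFAULT_WINDOW = {"rna": 4, "protein": 6}

#: default tertiary-contact distance cutoff in Angstrom
DEFAULT_CUTOFF = 9.5

# bracket tiers: '()', '[]', '{}', '<>', then letter pairs 'Aa'..'Za'
# (bpRNA pseudoknot convention); each tier is parsed with its own stack.
_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_CLOSE_OF = dict(zip(_OPENERS, _CLOSERS))
_OPEN_OF = dict(zip(_CLOSERS, _OPENERS))


class MoleculeKind(str, Enum):
    RNA = "rna"
    PROTEIN = "protein"


class AtomMode(str, Enum):
    """How the inter-residue distance is defined.

    MIN_HEAVY_ATOM: minimum over all heavy-atom pairs of the two residues
    (the most inclusive reading).  REPRESENTATIVE_ATOM: one atom per
    residue -- C3' for RNA, CB with CA fallback for proteins.
    """

    MIN_HEAVY_ATOM = "min_heavy_atom"
    REPRESENTATIVE_ATOM = "representative_atom"


@dataclass(frozen=True)
class Molecule:
    """A single RNA or protein chain."""

    id: str
    sequence: str
    kind: MoleculeKind

    def __post_init__(self):
        object.__setattr__(self, "kind", MoleculeKind(self.kind))
        if len(self.sequence) < 1:
            raise ValidationError(f"molecule {self.id}: empty sequence")
        alphabet = RNA_ALPHABET if self.kind is MoleculeKind.RNA else PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise ValidationError(
                f"molecule {self.id}: characters {sorted(bad)} outside the "
                f"{self.kind.value} alphabet (modified/unknown residues are rejected)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Residue:
    """One residue: name plus named atom coordinates in Angstrom."""

    name: str
    atoms: dict[str, np.ndarray]

    def heavy_atoms(self) -> dict[str, np.ndarray]:
        return {n: c for n, c in self.atoms.items() if not n.startswith("H")}


@dataclass
class Structure3D:
    """Ordered residue coordinates for one molecule."""

    molecule: Molecule
    residues: list[Residue]

    def __post_init__(self):
        if len(self.residues) != len(self.molecule):
            raise ValidationError(
                f"molecule {self.molecule.id}: {len(self.residues)} residues "
                f"but sequence length {len(self.molecule)}"
            )
        for idx, res in enumerate(self.residues):
            if not res.atoms:
                raise ValidationError(
                    f"molecule {self.molecule.id}: residue {idx} has no atoms"
                )


@dataclass(frozen=True)
class PairList:
    """A set of 0-based (i, j) index pairs with i < j."""

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        if any(i == j for i, j in norm):
            raise ValidationError("self-pair (i, i) is not allowed")
        object.__setattr__(self, "pairs", norm)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))


@dataclass
class ContactMap:
    """N x N binary symmetric matrix of structural contacts.

    ``exclusion_window`` records the band half-width w that has been
    zeroed out; ``cutoff`` records the distance cutoff for tertiary maps
    (None for secondary-structure maps).
    """

    n: int
    matrix: np.ndarray
    exclusion_window: int = 0
    cutoff: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (self.n, self.n):
            raise ShapeError(
                f"contact matrix shape {self.matrix.shape} != ({self.n}, {self.n})"
            )
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValidationError("contact matrix is not symmetric")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("contact matrix entries must be 0/1")
        i, j = np.indices(self.matrix.shape, sparse=True)
        band = np.abs(i - j) <= self.exclusion_window
        if self.matrix[band].any():
            raise ValidationError(
                f"nonzero entry inside exclusion band |i-j| <= {self.exclusion_window}"
            )

    @property
    def density(self) -> float:
        """Contact density over eligible upper-triangle pairs."""
        ii, jj = eligible_pairs(self.n, self.exclusion_window)
        if ii.size == 0:
            return 0.0
        return float(self.matrix[ii, jj].mean())

    def contact_count(self) -> int:
        """Number of contacts above the diagonal."""
        return int(np.triu(self.matrix, 1).sum())


def eligible_pairs(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index pairs (i, j) with j - i > window."""
    ii, jj = np.triu_indices(n, k=window + 1)
    return ii, jj


def coords_to_contact_map(
    structure: Structure3D,
    cutoff: float = DEFAULT_CUTOFF,
    atom_mode: AtomMode | str = AtomMode.MIN_HEAVY_ATOM,
) -> ContactMap:
    """Binary tertiary contact map from 3D coordinates.

    ``matrix[i, j] = 1`` iff the inter-residue distance (per
    ``atom_mode``) is <= ``cutoff`` Angstrom.  The exclusion band is NOT
    applied here (window recorded as 0); use :func:`apply_exclusion_band`.
    """
    atom_mode = AtomMode(atom_mode)
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    n = len(structure.residues)
    coords: list[np.ndarray] = []
    owner: list[int] = []
    for idx, res in enumerate(structure.residues):
        if atom_mode is AtomMode.MIN_HEAVY_ATOM:
            atoms = res.heavy_atoms()
            if not atoms:
                raise MissingCoordinateError(idx)
            pts = list(atoms.values())
        else:
            pts = [_representative_atom(res, idx, structure.molecule.kind)]
        coords.extend(np.asarray(p, dtype=float) for p in pts)
        owner.extend([idx] * len(pts))

    xyz = np.vstack(coords)
    owner_arr = np.asarray(owner)
    dmat = cdist(xyz, xyz)
    # reduce the atom-level distance matrix to per-residue-pair minima
    res_d = np.full((n, n), np.inf)
    np.minimum.at(res_d, (owner_arr[:, None], owner_arr[None, :]), dmat)
    matrix = (res_d <= cutoff).astype(np.int8)
    np.fill_diagonal(matrix, 0)
    return ContactMap(n=n, matrix=matrix, exclusion_window=0, cutoff=float(cutoff))


def _representative_atom(res: Residue, idx: int, kind: MoleculeKind) -> np.ndarray:
    names = ("C3'",) if kind is MoleculeKind.RNA else ("CB", "CA")
    for name in names:
        if name in res.atoms:
            return np.asarray(res.atoms[name], dtype=float)
    raise MissingCoordinateError(
        idx, f"residue {idx} lacks a representative atom ({'/'.join(names)})"
    )


def dotbracket_to_pairs(db: str) -> PairList:
    """Parse dot-bracket notation into base pairs.

    Each bracket tier ('()', '[]', '{}', '<>', 'Aa'..'Zz') is matched
    with its own stack, so pseudoknots encoded with extra tiers are
    handled.  Raises :class:`ParseError` on unbalanced or unsupported
    characters.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _CLOSE_OF:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _OPEN_OF:
            stack = stacks.get(_OPEN_OF[ch], [])
            if not stack:
                raise ParseError(f"unmatched closing bracket {ch!r}", position=pos)
            pairs.add((stack.pop(), pos))
        else:
            raise ParseError(f"unsupported character {ch!r}", position=pos)
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(
                f"unmatched opening bracket {opener!r}", position=stack[-1]
            )
    return PairList(frozenset(pairs))


def pairs_to_dotbracket(pairs: PairList, n: int) -> str:
    """Render pairs back to dot-bracket, assigning pseudoknot tiers greedily.

    Nested inputs come back with '()' only, so
    ``pairs_to_dotbracket(dotbracket_to_pairs(s), len(s)) == s`` for any
    nested string ``s``.
    """
    for i, j in pairs:
        if j >= n:
            raise RangeError(f"pair index {j} >= length {n}")
    out = ["."] * n
    tiers: list[list[tuple[int, int]]] = []
    for i, j in sorted(pairs):
        for tier in tiers:
            if all(not _crosses((i, j), p) for p in tier):
                tier.append((i, j))
                break
        else:
            if len(tiers) >= len(_OPENERS):
                raise RangeError("more pseudoknot tiers than supported bracket types")
            tiers.append([(i, j)])
    for level, tier in enumerate(tiers):
        for i, j in tier:
            out[i] = _OPENERS[level]
            out[j] = _CLOSERS[level]
    return "".join(out)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def pairs_to_contact_map(pairs: PairList, n: int) -> ContactMap:
    """Render a pair list as a symmetric binary matrix."""
    matrix = np.zeros((n, n), dtype=np.int8)
    for i, j in pairs:
        if j >= n:
            raise RangeError(f"pair index {j} >= length {n}")
        matrix[i, j] = matrix[j, i] = 1
    return ContactMap(n=n, matrix=matrix, exclusion_window=0, cutoff=None)


def apply_exclusion_band(cmap: ContactMap, window: int) -> ContactMap:
    """Zero out entries with |i-j| <= window and record the window.

    Idempotent: applying an equal or smaller window again is a no-op.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    matrix = cmap.matrix.copy()
    i, j = np.indices(matrix.shape, sparse=True)
    matrix[np.abs(i - j) <= window] = 0
    return replace(
        cmap, matrix=matrix, exclusion_window=max(window, cmap.exclusion_window)
    )


def dotbracket_to_contact_map(db: str, window: int | None = None) -> ContactMap:
    """Convenience: dot-bracket string to band-filtered contact map."""
    cmap = pairs_to_contact_map(dotbracket_to_pairs(db), len(db))
    if window is not None:
        cmap = apply_exclusion_band(cmap, window)
    return cmap
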