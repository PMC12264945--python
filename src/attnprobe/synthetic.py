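"""Synthetic molecules, structures and attention stacks with planted signal.

The generator stands in for two things no test should have to download:
curated structure sets and pretrained language-model inference.  It
emulates

* nested RNA secondary structures (recursive stem-loop placement, stem
  length 3-6, hairpin loop >= 3), optionally with one crossing
  pseudoknot stem on the '[' bracket tier and a few sparse long-range
  tertiary contacts;

* attention stacks in which a designated subset of "aware" heads mixes
  the true contact pattern with row-wise Dirichlet noise at a signal
  fraction alpha (alpha = 1: each residue's attention mass spread
  uniformly over its true contacts; alpha = 0: pure noise), while the
  remaining heads follow a locality kernel exp(-|i-j|/2) plus noise.
  Every row is renormalized to sum to 1, matching the provider contract
  for raw attention.

With alpha high the planted heads behave like the structurally aware
attention observed in protein language models; with alpha = 0 the stack
is structurally blind, the RNA-like regime.  All randomness flows
through a single integer seed, and a corpus serializes to plain-text
formats plus .npz attention containers with a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .attention import AttentionStack
from .contacts import (
    ContactMap,
    Molecule,
    MoleculeKind,
    PairList,
    Residue,
    Structure3D,
    apply_exclusion_band,
    dotbracket_to_pairs,
    pairs_to_contact_map,
)
from .errors import GenerationError, ValidationError
from .io import (
    save_attention_stack,
    write_contact_map_edges,
    write_dbn,
    write_fasta,
)

_COMPLEMENTS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_molecules: int = 50
    length_range: tuple[int, int] = (40, 80)
    n_layers: int = 6
    n_heads: int = 12
    aware_heads: tuple[tuple[int, int], ...] = ((1, 3), (3, 7), (5, 1))
    alpha: float = 0.8
    pseudoknot_prob: float = 0.1
    n_tertiary_extras: int = 2
    window: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        for l, h in self.aware_heads:
            if not (0 <= l < self.n_layers and 0 <= h < self.n_heads):
                raise ValidationError(
                    f"aware head ({l}, {h}) outside the {self.n_layers}x{self.n_heads} grid"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aware_heads"] = [list(p) for p in self.aware_heads]
        d["length_range"] = list(self.length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["aware_heads"] = tuple(tuple(p) for p in d["aware_heads"])
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


@dataclass
class Corpus:
    """Aligned (molecule, secondary structure, contact map, attention) tuples."""

    spec: SyntheticSpec
    molecules: list[Molecule]
    secondaries: list[str]
    maps: list[ContactMap]
    stacks: list[AttentionStack]

    def __len__(self) -> int:
        return len(self.molecules)


# ------------------------------------------------------ secondary structure

def gen_secondary(
    n: int,
    rng: np.random.Generator,
    stem_min: int = 3,
    stem_max: int = 6,
    loop_min: int = 3,
    pseudoknot_prob: float = 0.0,
) -> str:
    """Random valid dot-bracket string of length n (n >= 10).

    Built by recursive stem-loop placement; with probability
    ``pseudoknot_prob`` one crossing stem is added on the '[' tier.
    """
    if n < 10:
        raise GenerationError(f"secondary structure needs n >= 10, got {n}")
    db = _nested(n, rng, stem_min, stem_max, loop_min)
    if rng.random() < pseudoknot_prob:
        db = _add_pseudoknot(db, rng)
    return db


def _nested(n, rng, stem_min, stem_max, loop_min):
    min_hairpin = 2 * stem_min + loop_min
    if n < min_hairpin:
        return "." * n
    if n >= 2 * min_hairpin and rng.random() < 0.35:
        cut = int(rng.integers(min_hairpin, n - min_hairpin + 1))
        return _nested(cut, rng, stem_min, stem_max, loop_min) + _nested(
            n - cut, rng, stem_min, stem_max, loop_min
        )
    if rng.random() < 0.05:
        return "." * n
    s = int(rng.integers(stem_min, min(stem_max, (n - loop_min) // 2) + 1))
    slack = n - 2 * s - loop_min
    f5 = int(rng.integers(0, min(3, slack) + 1))
    f3 = int(rng.integers(0, min(3, slack - f5) + 1))
    inner = n - 2 * s - f5 - f3  # >= loop_min by construction
    # keep >= loop_min unpaired positions against the closing strand
    interior = _nested(inner - loop_min, rng, stem_min, stem_max, loop_min)
    return "." * f5 + "(" * s + interior + "." * loop_min + ")" * s + "." * f3


def _add_pseudoknot(db: str, rng: np.random.Generator) -> str:
    """Add one stem on the '[' tier crossing an existing pair, if possible."""
    chars = list(db)
    pairs = sorted(dotbracket_to_pairs(db))
    order = rng.permutation(len(pairs))
    for k in order:
        i, j = pairs[k]
        inside = [p for p in range(i + 1, j) if chars[p] == "."]
        outside = [p for p in range(j + 1, len(db)) if chars[p] == "."]
        m = min(3, len(inside), len(outside))
        if m >= 2:
            for a in range(m):
                chars[inside[a]] = "["
                chars[outside[m - 1 - a]] = "]"
            return "".join(chars)
    return db  # no room for a knot in this structure


# --------------------------------------------------------- tertiary contacts

def gen_tertiary_map(
    db: str,
    n_extras: int,
    rng: np.random.Generator,
    window: int = 4,
) -> ContactMap:
    """Secondary pairs plus sparse long-range tertiary extras, band-filtered.

    Extras satisfy j - i > window, avoid existing contacts and touch
    each residue at most twice.
    """
    n = len(db)
    cmap = apply_exclusion_band(
        pairs_to_contact_map(dotbracket_to_pairs(db), n), window
    )
    if n_extras == 0:
        return cmap
    matrix = cmap.matrix.copy()
    usage = np.zeros(n, dtype=int)
    ii, jj = np.triu_indices(n, k=window + 1)
    free = np.nonzero(matrix[ii, jj] == 0)[0]
    order = rng.permutation(free)
    added = 0
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if usage[i] < 2 and usage[j] < 2:
            matrix[i, j] = matrix[j, i] = 1
            usage[i] += 1
            usage[j] += 1
            added += 1
            if added == n_extras:
                break
    if added < n_extras:
        raise GenerationError(
            f"could only place {added}/{n_extras} tertiary extras for n={n}"
        )
    return ContactMap(n=n, matrix=matrix, exclusion_window=window, cutoff=None)


# ---------------------------------------------------------- toy coordinates

def gen_coords(
    matching: PairList,
    n: int,
    window: int = 4,
    molecule_id: str = "synthetic",
) -> Structure3D:
    """Toy 3D structure whose 9.5 A contact map equals the matching.

    Residues sit on a line at 20 A spacing; for every matched pair
    (i, j) residue j is translated to 3 A from residue i.  Because all
    other inter-residue distances stay >= 17 A, the contact map at the
    9.5 A cutoff (after band filtering with ``window``) is exactly the
    band-filtered matching.
    """
    seen: set[int] = set()
    for i, j in matching:
        if j >= n:
            raise GenerationError(f"pair index {j} >= length {n}")
        if i in seen or j in seen:
            raise GenerationError("matching reuses a residue index")
        seen.update((i, j))
        if j - i <= window:
            raise GenerationError(
                f"pair ({i}, {j}) lies inside the exclusion band (window {window})"
            )
    base = np.zeros((n, 3))
    base[:, 0] = 20.0 * np.arange(n)
    for i, j in matching:
        base[j] = base[i] + np.array([3.0, 0.0, 0.0])
    residues = [
        Residue(
            name="A",
            atoms={
                "C4'": base[k],
                "P": base[k] + np.array([0.4, 0.3, 0.0]),
                "C3'": base[k] + np.array([-0.3, 0.4, 0.0]),
            },
        )
        for k in range(n)
    ]
    mol = Molecule(id=molecule_id, sequence="A" * n, kind=MoleculeKind.RNA)
    return Structure3D(molecule=mol, residues=residues)


# --------------------------------------------------------- attention stacks

def gen_attention_stack(
    cmap: ContactMap,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    molecule_id: str = "synthetic",
) -> AttentionStack:
    """Raw attention stack with the contact pattern planted in aware heads.

    Aware head rows: alpha * C(i, .)/deg(i) + (1 - alpha) * Dirichlet
    noise (a contact-free row parks its signal mass on the diagonal, so
    it drops out under band-excluded scoring).  Unaware heads: locality
    kernel exp(-|i-j|/2) mixed with the same noise.  Every row sums to 1.
    """
    n = cmap.n
    c = cmap.matrix.astype(np.float64)
    deg = c.sum(axis=1)
    signal = np.where(deg[:, None] > 0, c / np.maximum(deg, 1.0)[:, None], np.eye(n))
    i, j = np.indices((n, n), sparse=True)
    kernel = np.exp(-np.abs(i - j) / 2.0)
    kernel = kernel / kernel.sum(axis=1, keepdims=True)
    aware = set(spec.aware_heads)

    weights = np.empty((spec.n_layers, spec.n_heads, n, n))
    for l in range(spec.n_layers):
        for h in range(spec.n_heads):
            noise = rng.gamma(1.0, size=(n, n))
            noise /= noise.sum(axis=1, keepdims=True)
            if (l, h) in aware:
                a = spec.alpha * signal + (1.0 - spec.alpha) * noise
            else:
                a = 0.6 * kernel + 0.4 * noise
            weights[l, h] = a / a.sum(axis=1, keepdims=True)
    return AttentionStack(molecule_id=molecule_id, weights=weights, processed=False)


# ------------------------------------------------------------------ corpus

def _paired_sequence(db: str, rng: np.random.Generator) -> str:
    seq = [str(b) for b in rng.choice(list("ACGU"), size=len(db))]
    for i, j in dotbracket_to_pairs(db):
        a, b = _COMPLEMENTS[int(rng.integers(len(_COMPLEMENTS)))]
        seq[i], seq[j] = a, b
    return "".join(seq)


def gen_corpus(spec: SyntheticSpec) -> Corpus:
    """Fully deterministic corpus of aligned molecule/map/stack triplets."""
    rng = np.random.default_rng(spec.seed)
    molecules, secondaries, maps, stacks = [], [], [], []
    lo, hi = spec.length_range
    for m in range(spec.n_molecules):
        mol_id = f"syn{m:04d}"
        n = int(rng.integers(lo, hi + 1))
        db = gen_secondary(n, rng, pseudoknot_prob=spec.pseudoknot_prob)
        cmap = gen_tertiary_map(db, spec.n_tertiary_extras, rng, window=spec.window)
        seq = _paired_sequence(db, rng)
        molecules.append(Molecule(id=mol_id, sequence=seq, kind=MoleculeKind.RNA))
        secondaries.append(db)
        maps.append(cmap)
        stacks.append(gen_attention_stack(cmap, spec, rng, molecule_id=mol_id))
    return Corpus(
        spec=spec, molecules=molecules, secondaries=secondaries, maps=maps,
        stacks=stacks,
    )


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Serialize a corpus: FASTA, .dbn, contact-map TSVs, .npz stacks, manifest."""
    out = Path(out_dir)
    (out / "contacts").mkdir(parents=True, exist_ok=True)
    (out / "attention").mkdir(parents=True, exist_ok=True)
    write_fasta(corpus.molecules, out / "sequences.fasta")
    write_dbn(
        [
            (mol.id, mol.sequence, db)
            for mol, db in zip(corpus.molecules, corpus.secondaries)
        ],
        out / "secondary.dbn",
    )
    for mol, cmap, stack in zip(corpus.molecules, corpus.maps, corpus.stacks):
        write_contact_map_edges(cmap, out / "contacts" / f"{mol.id}.tsv")
        save_attention_stack(stack, out / "attention" / f"{mol.id}.npz")
    manifest = {
        "spec": corpus.spec.to_dict(),
        "molecule_ids": [m.id for m in corpus.molecules],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def load_corpus(in_dir: str | Path) -> Corpus:
    from .io import load_attention_stack, read_contact_map_edges, read_dbn

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    spec = SyntheticSpec.from_dict(manifest["spec"])
    dbn = {rec_id: (seq, db) for rec_id, seq, db in read_dbn(src / "secondary.dbn")}
    molecules, secondaries, maps, stacks = [], [], [], []
    for mol_id in manifest["molecule_ids"]:
        seq, db = dbn[mol_id]
        molecules.append(Molecule(id=mol_id, sequence=seq, kind=MoleculeKind.RNA))
        secondaries.append(db)
        maps.append(read_contact_map_edges(src / "contacts" / f"{mol_id}.tsv"))
        stacks.append(load_attention_stack(src / "attention" / f"{mol_id}.npz"))
    return Corpus(
        spec=spec, molecules=molecules, secondaries=secondaries, maps=maps,
        stacks=stacks,
    )
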