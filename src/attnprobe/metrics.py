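"""Contact-map scoring: per-molecule macro-F1 and MCC, dataset means.

Predicted and true maps are flattened over the eligible upper-triangle
pairs (j - i > window) into binary vectors and compared per molecule;
dataset-level performance is the unweighted arithmetic mean of the
per-molecule scores.  Macro-F1 is the unweighted mean of the contact-
and non-contact-class F1 (an empty class scores 0); MCC is defined as 0
when its denominator vanishes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, matthews_corrcoef

from .contacts import (
    AtomMode,
    ContactMap,
    Structure3D,
    apply_exclusion_band,
    coords_to_contact_map,
    dotbracket_to_contact_map,
    eligible_pairs,
)
from .errors import AlignmentError


@dataclass
class MoleculeScore:
    molecule_id: str
    f1_macro: float
    mcc: float
    n_eligible_pairs: int
    n_true_contacts: int
    degenerate: bool = False


@dataclass
class EvalReport:
    """Per-molecule scores plus dataset-level means."""

    scores: list[MoleculeScore]
    mean_f1_macro: float
    mean_mcc: float
    skipped: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "molecule_id": s.molecule_id,
                    "f1_macro": s.f1_macro,
                    "mcc": s.mcc,
                    "n_eligible_pairs": s.n_eligible_pairs,
                    "n_true_contacts": s.n_true_contacts,
                    "degenerate": s.degenerate,
                }
                for s in sorted(self.scores, key=lambda s: s.molecule_id)
            ]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "mean_f1_macro": self.mean_f1_macro,
            "mean_mcc": self.mean_mcc,
            "n_scored": len(self.scores),
            "skipped": self.skipped,
            "molecules": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def binary_macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Macro-F1 over the two classes {0, 1}; an absent class scores 0."""
    return float(
        f1_score(y_true, y_pred, average="macro", labels=[0, 1], zero_division=0)
    )


def binary_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when the denominator is 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


def score_molecule(
    pred: ContactMap, truth: ContactMap, window: int
) -> MoleculeScore:
    """Flatten both maps over eligible pairs and score the prediction."""
    if pred.n != truth.n:
        raise AlignmentError(
            f"prediction length {pred.n} != truth length {truth.n}"
        )
    ii, jj = eligible_pairs(truth.n, window)
    y_true = truth.matrix[ii, jj]
    y_pred = pred.matrix[ii, jj]
    degenerate = len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2
    return MoleculeScore(
        molecule_id="",
        f1_macro=binary_macro_f1(y_true, y_pred),
        mcc=binary_mcc(y_true, y_pred),
        n_eligible_pairs=int(ii.size),
        n_true_contacts=int(y_true.sum()),
        degenerate=degenerate,
    )


def score_dataset(
    preds: dict[str, ContactMap],
    truths: dict[str, ContactMap],
    window: int | None = None,
) -> EvalReport:
    """Score every molecule and average; order-invariant.

    ``window`` defaults to each truth map's own exclusion window.
    Molecules with zero eligible pairs are skipped and listed.
    """
    missing = sorted(set(truths) - set(preds))
    if missing:
        raise AlignmentError(f"missing predictions for molecules: {missing}")
    scores: list[MoleculeScore] = []
    skipped: dict[str, str] = {}
    for mol_id in sorted(truths):
        truth = truths[mol_id]
        w = truth.exclusion_window if window is None else window
        ii, _ = eligible_pairs(truth.n, w)
        if ii.size == 0:
            skipped[mol_id] = f"no eligible pairs at window {w}"
            continue
        s = score_molecule(preds[mol_id], truth, w)
        s.molecule_id = mol_id
        scores.append(s)
    if not scores:
        raise AlignmentError("no molecule could be scored")
    return EvalReport(
        scores=scores,
        mean_f1_macro=float(np.mean([s.f1_macro for s in scores])),
        mean_mcc=float(np.mean([s.mcc for s in scores])),
        skipped=skipped,
        params={"window": window},
    )


def benchmark_external(
    predictions: dict[str, Structure3D | str],
    truths: dict[str, ContactMap],
    cutoff: float = 9.5,
    window: int = 4,
    atom_mode: AtomMode | str = AtomMode.MIN_HEAVY_ATOM,
) -> EvalReport:
    """Score external structure predictions against truth contact maps.

    Each prediction is either a :class:`Structure3D` (converted with the
    same distance cutoff as the truths) or a dot-bracket string
    (converted through the secondary-structure pipeline); the same
    exclusion window is applied to both sides.  Unconvertible molecules
    are skipped with a reason rather than failing the whole benchmark.
    """
    preds: dict[str, ContactMap] = {}
    skipped: dict[str, str] = {}
    for mol_id in sorted(truths):
        if mol_id not in predictions:
            skipped[mol_id] = "no external prediction"
            continue
        raw = predictions[mol_id]
        try:
            if isinstance(raw, str):
                cmap = dotbracket_to_contact_map(raw, window=window)
            else:
                cmap = apply_exclusion_band(
                    coords_to_contact_map(raw, cutoff=cutoff, atom_mode=atom_mode),
                    window,
                )
        except Exception as exc:  # per-molecule skip, not global failure
            skipped[mol_id] = f"conversion failed: {exc}"
            continue
        preds[mol_id] = cmap
    report = score_dataset(preds, {m: truths[m] for m in preds}, window=window)
    report.skipped.update(skipped)
    report.params = {
        "cutoff": cutoff,
        "window": window,
        "atom_mode": AtomMode(atom_mode).value,
        "note": "contact-map-level comparison; 3D superposition metrics "
        "(RMSD/TM-score) would require structural alignment and are not computed",
    }
    return report


def plot_overlay(
    truth: ContactMap, pred: ContactMap, path, title: str = ""
) -> None:
    """Truth in the upper triangle, prediction in the lower triangle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    canvas = np.triu(truth.matrix, 1) + np.tril(pred.matrix, -1) * 2
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(canvas, cmap="Blues", interpolation="nearest")
    ax.set_title(title or "truth (upper) vs prediction (lower)")
    ax.set_xlabel("residue j")
    ax.set_ylabel("residue i")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
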