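"""Attention-map normalization and attention-structure agreement.

A transformer produces, for a sequence of N residues, an L x H stack of
N x N attention maps (L layers, H heads).  Two questions are asked of
such a stack:

* *Probing*: what fraction p(f) of a head's attention mass falls on
  residue pairs that are true structural contacts?  p(f) is a weighted
  mean of the contact indicator f(i, j) with weights given by the
  (optionally thresholded) attention a_ij, pooled over a molecule set.
  A head scoring near 1 attends almost exclusively to contacts; a head
  scoring at the contact density of the eligible pairs is uninformative.

* *Featurization*: before attention weights are used as pairwise
  classification features they are symmetrized, a_ij <- (a_ij + a_ji)/2,
  and refined with the Average Product Correction,
  APC(a)_ij = a_ij - rowsum_i * colsum_j / total, which removes
  per-position background attention trends (the same correction used on
  coevolutionary coupling matrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .contacts import ContactMap
from .errors import AlignmentError, DegenerateInputError, ShapeError, ValidationError


class MaskPolicy(str, Enum):
    """Which (i, j) pairs enter the agreement sums.

    ALL: every entry of the N x N map (the literal reading of the
    summation).  BAND_EXCLUDED: pairs with |i-j| <= w are removed from
    numerator and denominator, matching the contact maps' exclusion band
    so purely local heads cannot dominate.
    """

    ALL = "all"
    BAND_EXCLUDED = "band_excluded"


@dataclass
class AttentionStack:
    """L x H x N x N attention weights for one molecule.

    ``processed=False`` means raw attention (provider output, rows of
    each map summing to 1 if the provider row-normalizes);
    ``processed=True`` means symmetrized + APC-corrected maps.
    """

    molecule_id: str
    weights: np.ndarray
    processed: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ShapeError(
                f"attention weights must be (L, H, N, N), got {self.weights.shape}"
            )
        if not self.processed and (self.weights < 0).any():
            raise ValidationError(
                f"stack {self.molecule_id}: negative attention weight"
            )

    @property
    def n_layers(self) -> int:
        return self.weights.shape[0]

    @property
    def n_heads(self) -> int:
        return self.weights.shape[1]

    @property
    def n(self) -> int:
        return self.weights.shape[2]

    def validate_row_normalized(self, atol: float = 1e-6) -> None:
        """Check the provider contract that every row of every raw map sums to 1."""
        if self.processed:
            return
        sums = self.weights.sum(axis=3)
        bad = np.argwhere(np.abs(sums - 1.0) > atol)
        if bad.size:
            l, h, i = bad[0]
            raise ValidationError(
                f"stack {self.molecule_id}: row {i} of head (layer {l}, head {h}) "
                f"sums to {sums[l, h, i]:.6g}, expected 1"
            )


@dataclass
class HeadScoreGrid:
    """Per-head agreement scores p(f) over a molecule set."""

    scores: np.ndarray  # (L, H) in [0, 1]
    theta: float | None
    n_molecules: int
    mask_policy: MaskPolicy
    zero_denominator: np.ndarray = field(default=None)  # (L, H) bool flags

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.n_molecules < 1:
            raise ValidationError("HeadScoreGrid requires n_molecules >= 1")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValidationError("agreement scores must lie in [0, 1]")
        if self.zero_denominator is None:
            self.zero_denominator = np.zeros_like(self.scores, dtype=bool)

    @property
    def n_layers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_heads(self) -> int:
        return self.scores.shape[1]

    def max_over_heads(self) -> float:
        """Best agreement achieved by any head (a one-number model summary)."""
        return float(self.scores.max())


def symmetrize(a: np.ndarray) -> np.ndarray:
    """(A + A^T) / 2.  Idempotent; exact for symmetric input."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError(f"symmetrize expects a square matrix, got {a.shape}")
    return (a + a.T) / 2.0


def apc(a: np.ndarray) -> np.ndarray:
    """Average Product Correction: a_ij - rowsum_i * colsum_j / total.

    Annihilates any rank-1 matrix u v^T exactly.  Raises
    :class:`DegenerateInputError` when the total sum is 0.
    """
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError(f"apc expects a square matrix, got {a.shape}")
    total = a.sum()
    if total == 0:
        raise DegenerateInputError("APC undefined: matrix sums to 0")
    return a - np.outer(a.sum(axis=1), a.sum(axis=0)) / total


def process_stack(stack: AttentionStack) -> AttentionStack:
    """Symmetrize then APC-correct every (layer, head) map, in that order."""
    if stack.processed:
        raise ValidationError(f"stack {stack.molecule_id} is already processed")
    out = np.empty_like(stack.weights)
    degenerate: list[tuple[int, int]] = []
    for l in range(stack.n_layers):
        for h in range(stack.n_heads):
            try:
                out[l, h] = apc(symmetrize(stack.weights[l, h]))
            except DegenerateInputError:
                degenerate.append((l, h))
    if degenerate:
        raise DegenerateInputError(
            f"stack {stack.molecule_id}: all-zero attention in heads "
            f"(layer, head) = {degenerate}"
        )
    return AttentionStack(
        molecule_id=stack.molecule_id, weights=out, processed=True
    )


def _eligibility_mask(n: int, window: int, policy: MaskPolicy) -> np.ndarray:
    if policy is MaskPolicy.ALL:
        return np.ones((n, n), dtype=bool)
    i, j = np.indices((n, n), sparse=True)
    return np.abs(i - j) > window


def agreement_scores(
    stacks: list[AttentionStack],
    maps: list[ContactMap],
    theta: float | None = None,
    mask_policy: MaskPolicy | str = MaskPolicy.BAND_EXCLUDED,
    use_processed: bool = False,
) -> HeadScoreGrid:
    """Per-head attention-contact agreement p(f) pooled over molecules.

    For each (layer, head),

        p(f) = sum_x sum_(i,j) f(i,j) * l(a_ij) / sum_x sum_(i,j) l(a_ij)

    where f is the contact indicator and l(a) = a * 1[a > theta] when a
    threshold is set, or simply a when ``theta`` is None (the
    threshold-free variant; the two coincide for theta=0 on strictly
    positive attention).  The eligible (i, j) set follows
    ``mask_policy``.  Heads with zero denominator score 0 and are
    flagged in ``zero_denominator``.

    By default scores are computed on raw attention; pass
    ``use_processed=True`` to score symmetrized/APC maps instead.
    """
    mask_policy = MaskPolicy(mask_policy)
    if theta is not None and not (0 <= theta < 1):
        raise ValueError(f"theta must be in [0, 1) or None, got {theta}")
    if len(stacks) != len(maps):
        raise AlignmentError(
            f"{len(stacks)} stacks but {len(maps)} contact maps"
        )
    if not stacks:
        raise AlignmentError("empty molecule set")

    shape = (stacks[0].n_layers, stacks[0].n_heads)
    num = np.zeros(shape)
    den = np.zeros(shape)
    for stack, cmap in zip(stacks, maps):
        if stack.n != cmap.n:
            raise AlignmentError(
                f"molecule {stack.molecule_id}: stack length {stack.n} != "
                f"contact map length {cmap.n}"
            )
        if stack.processed != use_processed:
            raise ValidationError(
                f"molecule {stack.molecule_id}: processed={stack.processed} "
                f"but use_processed={use_processed}"
            )
        mask = _eligibility_mask(cmap.n, cmap.exclusion_window, mask_policy)
        w = stack.weights * mask  # (L, H, N, N)
        if theta is not None:
            w = np.where(w > theta, w, 0.0)
        f = (cmap.matrix > 0) & mask
        num += (w * f).sum(axis=(2, 3))
        den += w.sum(axis=(2, 3))

    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} head(s) had zero attention mass on eligible "
            "pairs; scored as 0",
            stacklevel=2,
        )
    scores = np.divide(num, den, out=np.zeros_like(num), where=~zero)
    return HeadScoreGrid(
        scores=scores,
        theta=theta,
        n_molecules=len(stacks),
        mask_policy=mask_policy,
        zero_denominator=zero,
    )


def rank_heads(grid: HeadScoreGrid, k: int) -> list[tuple[int, int, float]]:
    """Top-k heads by agreement score, ties broken by (layer, head)."""
    total = grid.n_layers * grid.n_heads
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}], got {k}")
    entries = [
        (l, h, float(grid.scores[l, h]))
        for l in range(grid.n_layers)
        for h in range(grid.n_heads)
    ]
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return entries[:k]


def write_head_scores_tsv(grid: HeadScoreGrid, path) -> None:
    """Export the score grid as TSV columns (layer, head, score)."""
    with open(path, "w") as fh:
        fh.write("layer\thead\tscore\n")
        for l in range(grid.n_layers):
            for h in range(grid.n_heads):
                fh.write(f"{l}\t{h}\t{grid.scores[l, h]:.10g}\n")


def plot_head_scores(grid: HeadScoreGrid, path) -> None:
    """Render the L x H score grid as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.4 * grid.n_heads, 1 + 0.4 * grid.n_layers))
    im = ax.imshow(grid.scores, cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xlabel("head")
    ax.set_ylabel("layer")
    title = "attention-contact agreement p(f)"
    if grid.theta is not None:
        title += f" (theta={grid.theta})"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="p(f)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
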