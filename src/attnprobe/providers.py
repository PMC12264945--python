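"""The attention-provider contract.

Anything that can turn a sequence into an L x H x N x N attention stack
-- a pretrained language model adapter, a cache of exported tensors, or
the synthetic generator -- implements :class:`AttentionProvider`.
Providers must return residue-by-residue maps: special/beginning-of-
sequence token rows and columns are stripped before the stack leaves
the provider, and raw rows sum to 1.

The file-backed provider below is the reference implementation: it
serves stacks previously exported to .npz containers, validating the
stack invariants on load.  Real language-model adapters are an optional
extra built on the same contract; nothing in the core pipeline needs
one.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

from .attention import AttentionStack
from .contacts import Molecule
from .errors import ValidationError
from .io import load_attention_stack


@dataclass(frozen=True)
class ProviderCapability:
    n_layers: int
    n_heads: int
    max_length: int


class AttentionProvider(ABC):
    """Serves attention stacks for molecules."""

    @property
    @abstractmethod
    def capability(self) -> ProviderCapability: ...

    @abstractmethod
    def attention_for(self, molecule: Molecule) -> AttentionStack: ...


class FileAttentionProvider(AttentionProvider):
    """Serves stacks stored as ``<dir>/<molecule_id>.npz`` containers."""

    def __init__(self, directory: str | Path):
        self._dir = Path(directory)
        paths = sorted(self._dir.glob("*.npz"))
        if not paths:
            raise ValidationError(f"no .npz attention containers in {self._dir}")
        self._paths = {p.stem: p for p in paths}
        probe = load_attention_stack(paths[0])
        self._capability = ProviderCapability(
            n_layers=probe.n_layers,
            n_heads=probe.n_heads,
            max_length=max(load_attention_stack(p).n for p in paths),
        )

    @property
    def capability(self) -> ProviderCapability:
        return self._capability

    def molecule_ids(self) -> list[str]:
        return sorted(self._paths)

    def attention_for(self, molecule: Molecule) -> AttentionStack:
        path = self._paths.get(molecule.id)
        if path is None:
            raise ValidationError(f"no stored attention for molecule {molecule.id}")
        stack = load_attention_stack(path)
        if stack.n != len(molecule):
            raise ValidationError(
                f"stored stack for {molecule.id} has length {stack.n}, "
                f"query sequence has {len(molecule)}"
            )
        if (
            stack.n_layers != self._capability.n_layers
            or stack.n_heads != self._capability.n_heads
        ):
            raise ValidationError(
                f"stack for {molecule.id} has grid "
                f"{stack.n_layers}x{stack.n_heads}, provider declares "
                f"{self._capability.n_layers}x{self._capability.n_heads}"
            )
        if not stack.processed:
            stack.validate_row_normalized()
        return stack
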