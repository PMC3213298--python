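"""Registry of the benchmark dimer datasets the method was characterised on.

Only the bookkeeping lives here (complex and chain counts for two-chain
complexes); the structures themselves are external resources.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DimerDataset", "TRANS135", "OBLIG94", "REGISTRY"]


@dataclass(frozen=True)
class DimerDataset:
    """A dataset of two-chain complexes."""

    name: str
    n_complexes: int
    binding_type: str  # transient | obligate

    @property
    def n_chains(self) -> int:
        return 2 * self.n_complexes


TRANS135 = DimerDataset("Trans135", 135, "transient")
OBLIG94 = DimerDataset("Oblig94", 94, "obligate")

REGISTRY = {d.name: d for d in (TRANS135, OBLIG94)}
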