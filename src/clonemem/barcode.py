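"""The expressed lineage-barcode layout.

The barcode vector carries a 48-bp random barcode downstream of a constant
anchor 7-mer.  The 48-mer itself is not fully random: every 4 random bases
are followed by a fixed invariant 2-mer, i.e. the oligo pattern

    NNNNCTNNNNACNNNNTCNNNNGTNNNNTGNNNNCANNNNATNNNNGC

(eight blocks of 4 N + one 2-mer = 48 bp).  The invariant 2-mers let the
parser reject off-target PCR products.  The template type carries anchor,
stagger sequence and offsets as data so parser and simulator share a single
source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"


@dataclass(frozen=True)
class BarcodeTemplate:
    anchor: str = "TAGACAT"
    stagger: tuple[str, ...] = ("CT", "AC", "TC", "GT", "TG", "CA", "AT", "GC")
    umi_length: int = 10
    block_random: int = 4  # random bases preceding each invariant 2-mer

    @property
    def barcode_length(self) -> int:
        return len(self.stagger) * (self.block_random + 2)

    @property
    def invariant_offsets(self) -> tuple[int, ...]:
        """0-based offsets of each invariant 2-mer within the 48-mer."""
        step = self.block_random + 2
        return tuple(self.block_random + i * step for i in range(len(self.stagger)))

    @property
    def random_positions(self) -> tuple[int, ...]:
        """0-based offsets of the N (random) bases within the 48-mer."""
        invariant = set()
        for off in self.invariant_offsets:
            invariant.update((off, off + 1))
        return tuple(i for i in range(self.barcode_length) if i not in invariant)

    def pattern(self) -> str:
        """The barcode as an oligo pattern with N at random positions."""
        out = ["N"] * self.barcode_length
        for off, two_mer in zip(self.invariant_offsets, self.stagger):
            out[off], out[off + 1] = two_mer[0], two_mer[1]
        return "".join(out)

    def render(self, rng: np.random.Generator) -> str:
        """Draw one valid 48-bp barcode (random N bases, correct stagger)."""
        chars = list(self.pattern())
        draws = rng.integers(0, 4, size=len(self.random_positions))
        for pos, b in zip(self.random_positions, draws):
            chars[pos] = BASES[b]
        return "".join(chars)

    def check_invariants(self, barcode: str) -> bool:
        """True iff every invariant 2-mer sits at its fixed offset."""
        if len(barcode) != self.barcode_length:
            return False
        return all(
            barcode[off : off + 2] == two_mer
            for off, two_mer in zip(self.invariant_offsets, self.stagger)
        )


DEFAULT_TEMPLATE = BarcodeTemplate()
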