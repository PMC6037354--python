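"""Genome build description: chromosome names and physical lengths.

Coordinates throughout the package are 1-based inclusive base pairs
(PLINK convention); UCSC BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome label and its physical length in base pairs."""

    name: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length_bp must be > 0")


class Genome:
    """Ordered collection of autosomes with unique names.

    The total autosomal length is the denominator of genome-wide F_ROH.
    """

    def __init__(self, chromosomes: Iterable[ChromosomeSpec]):
        chroms = list(chromosomes)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._chroms = chroms
        self._by_name = {c.name: c for c in chroms}

    @classmethod
    def from_lengths(cls, lengths: dict[str, int] | Iterable[tuple[str, int]]) -> "Genome":
        items = lengths.items() if isinstance(lengths, dict) else lengths
        return cls(ChromosomeSpec(str(n), int(l)) for n, l in items)

    @classmethod
    def cattle_like(cls, n_chromosomes: int = 29,
                    longest_mb: float = 160.0, shortest_mb: float = 42.0) -> "Genome":
        """Synthetic autosome set with lengths ramping linearly down,
        emulating the scale of the bovine genome (29 autosomes)."""
        if n_chromosomes == 1:
            lengths = [longest_mb]
        else:
            step = (longest_mb - shortest_mb) / (n_chromosomes - 1)
            lengths = [longest_mb - i * step for i in range(n_chromosomes)]
        return cls(ChromosomeSpec(str(i + 1), int(round(l * 1e6)))
                   for i, l in enumerate(lengths))

    def __iter__(self) -> Iterator[ChromosomeSpec]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._chroms]

    def length(self, name: str) -> int:
        return self._by_name[name].length_bp

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self._chroms)
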