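"""Genome layout: ordered chromosome names and lengths.

All coordinates in the package are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in base pairs.

    Parameters
    ----------
    lengths
        Mapping from chromosome name to length (bp). Insertion order is the
        canonical chromosome order used for sorting interval sets and
        binned tracks.
    """

    lengths: Mapping[str, int]
    _order: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "lengths", dict(self.lengths))
        object.__setattr__(
            self, "_order", {name: i for i, name in enumerate(self.lengths)}
        )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_index(self, chrom: str) -> int:
        return self._order[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column (name, length) chrom.sizes TSV."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed chrom.sizes line: {line!r}")
                name = fields[0]
                if name in lengths:
                    raise ValueError(f"duplicate chromosome {name!r}")
                lengths[name] = int(fields[1])
        return cls(lengths)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")
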