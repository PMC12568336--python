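"""Genome description shared by every stage.

A :class:`GenomeSpec` is an ordered set of chromosomes with lengths and an
optional blacklist (chromosomes whose pairs are dropped at parse time, e.g.
the mitochondrial and Y chromosomes of a mouse assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    """An invalid configuration value (bad length, threshold, path...)."""


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths (bp) and an optional blacklist.

    Parameters
    ----------
    names
        Chromosome names in genome order.
    lengths
        Mapping name -> length in bp; every length must be positive.
    blacklist
        Subset of ``names`` whose records are excluded from analysis.
    """

    names: tuple[str, ...]
    lengths: dict[str, int]
    blacklist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigError("chromosome names must be unique")
        if set(self.lengths) != set(self.names):
            raise ConfigError("lengths must be given for exactly the named chromosomes")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        if not self.blacklist <= set(self.names):
            raise ConfigError("blacklist must be a subset of chromosome names")

    @property
    def analysis_names(self) -> tuple[str, ...]:
        """Chromosome names kept for analysis (blacklist removed), in order."""
        return tuple(n for n in self.names if n not in self.blacklist)

    def order(self, name: str) -> int:
        """Genome-order index of a chromosome (used for pair-side sorting)."""
        return self.names.index(name)

    def length(self, name: str) -> int:
        return self.lengths[name]

    def n_bins(self, name: str, resolution: int) -> int:
        """Number of fixed-size bins covering a chromosome."""
        if resolution <= 0:
            raise ConfigError(f"resolution must be positive, got {resolution}")
        length = self.lengths[name]
        return -(-length // resolution)

    def to_chromsizes(self) -> str:
        """Two-column chrom.sizes text."""
        return "".join(f"{n}\t{self.lengths[n]}\n" for n in self.names)

    @classmethod
    def from_chromsizes(cls, text: str, blacklist: frozenset[str] = frozenset()) -> "GenomeSpec":
        names: list[str] = []
        lengths: dict[str, int] = {}
        for line in text.strip().splitlines():
            if not line.strip():
                continue
            name, length = line.split()[:2]
            names.append(name)
            lengths[name] = int(length)
        return cls(tuple(names), lengths, blacklist)
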