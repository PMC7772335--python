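"""In-memory container for haploid genotype data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeDataset"]


@dataclass
class HaplotypeDataset:
    """Haploid 0/1 genotypes at biallelic sites with population labels.

    Genotypes are coded 0 (ancestral / reference) and 1 (derived /
    alternate); ``polarization`` records whether the 0/1 coding is truly
    ancestral/derived ("derived") or merely REF/ALT ("unpolarized").
    Coordinates are 0-based half-open internally; ``pos`` stores the
    0-based site position.
    """

    samples: list[str]
    populations: np.ndarray  # (n_samples,) population label per sample
    genotypes: np.ndarray  # (n_sites, n_samples) int8 in {0, 1}
    contig: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 0-based
    polarization: str = "derived"
    rec_rate: np.ndarray | None = None  # (n_sites,) cM/Mb, when annotated
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.populations = np.asarray(self.populations)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.samples):
            raise ValueError("genotypes must be (n_sites, n_samples)")
        if len(self.contig) != self.n_sites or len(self.pos) != self.n_sites:
            raise ValueError("contig/pos length must match the number of sites")
        if self.rec_rate is not None:
            self.rec_rate = np.asarray(self.rec_rate, dtype=float)
            if len(self.rec_rate) != self.n_sites:
                raise ValueError("rec_rate length must match the number of sites")
        for ctg in np.unique(self.contig.astype(str)):
            p = self.pos[self.contig == ctg]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within contig {ctg}"
                )

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def sample_size(self, population: str) -> int:
        return int(np.sum(self.populations == population))

    def derived_counts(self, population: str) -> np.ndarray:
        """Per-site derived-allele count in one population."""
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return self.genotypes[:, mask].sum(axis=1)

    def take_sites(self, index: np.ndarray) -> "HaplotypeDataset":
        """New dataset restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return HaplotypeDataset(
            samples=list(self.samples),
            populations=self.populations.copy(),
            genotypes=self.genotypes[index],
            contig=self.contig[index],
            pos=self.pos[index],
            polarization=self.polarization,
            rec_rate=None if self.rec_rate is None else self.rec_rate[index],
            provenance=dict(self.provenance),
        )

    def drop_monomorphic(self) -> "HaplotypeDataset":
        tot = self.genotypes.sum(axis=1)
        keep = (tot > 0) & (tot < self.n_samples)
        return self.take_sites(np.flatnonzero(keep))
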