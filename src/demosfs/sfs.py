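"""Site-frequency-spectrum containers: joint (2D) and marginal (1D) spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import HaplotypeDataset

__all__ = ["JointSFS", "SFS1D", "build_joint_sfs", "marginal_sfs", "fold_sfs"]


def _corner_mask(n1: int, n2: int) -> np.ndarray:
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


@dataclass
class JointSFS:
    """(n1+1) x (n2+1) matrix of site counts by derived-allele frequency.

    Entry (i, j) counts sites with i derived copies in population 1 and
    j in population 2.  The monomorphic corners (0, 0) and (n1, n2) are
    always masked; a folded spectrum additionally masks the high-total-
    frequency half.
    """

    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray | None = None
    pop_names: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        base = _corner_mask(self.n1, self.n2)
        if self.mask is None:
            self.mask = base
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | base
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts")
        self.counts = np.where(self.mask, 0.0, self.counts)

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(
            self.counts.copy(), self.folded, self.mask.copy(), self.pop_names
        )

    def fold(self) -> "JointSFS":
        """Fold onto minor-total-frequency classes: entries with
        i + j > (n1 + n2) / 2 are added to (n1 - i, n2 - j) and masked."""
        if self.folded:
            return self.copy()
        n1, n2 = self.n1, self.n2
        ntot = n1 + n2
        counts = np.zeros_like(self.counts)
        mask = _corner_mask(n1, n2)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if self.mask[i, j]:
                    continue
                if 2 * (i + j) > ntot:
                    counts[n1 - i, n2 - j] += self.counts[i, j]
                    mask[i, j] = True
                else:
                    counts[i, j] += self.counts[i, j]
        return JointSFS(counts, folded=True, mask=mask, pop_names=self.pop_names)

    def marginal(self, pop: int) -> "SFS1D":
        """1D spectrum for population 1 or 2, summing over the other axis.

        Only defined for unfolded spectra (folding does not commute with
        marginalizing); fold the marginal afterwards if needed.
        """
        if self.folded:
            raise ValueError("marginals of a folded joint SFS are ill-defined; "
                             "take the marginal before folding")
        if pop not in (1, 2):
            raise ValueError("pop must be 1 or 2")
        counts = np.where(self.mask, 0.0, self.counts)
        xi = counts.sum(axis=1) if pop == 1 else counts.sum(axis=0)
        n = self.n1 if pop == 1 else self.n2
        # sites monomorphic in this population (but segregating overall)
        # land in classes 0 and n; they are not segregating sites here
        xi = xi.copy()
        xi[0] = 0.0
        xi[n] = 0.0
        return SFS1D(xi, folded=False)

    def plot(self, ax=None, log=True):
        """Heatmap of the joint spectrum (masked cells blanked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = np.ma.masked_where(self.mask, self.counts)
        from matplotlib.colors import LogNorm

        norm = LogNorm(vmin=max(z.min(), 0.5)) if log and z.max() > 0 else None
        im = ax.pcolormesh(z.T, norm=norm)
        ax.set_xlabel(f"derived count, {self.pop_names[0]} (n={self.n1})")
        ax.set_ylabel(f"derived count, {self.pop_names[1]} (n={self.n2})")
        ax.figure.colorbar(im, ax=ax, label="sites")
        return ax


@dataclass
class SFS1D:
    """1D site-frequency spectrum: counts for derived classes 0..n."""

    counts: np.ndarray
    folded: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) < 3:
            raise ValueError("counts must be a 1D array of length n+1 >= 3")

    @property
    def n(self) -> int:
        return len(self.counts) - 1

    @property
    def segregating(self) -> np.ndarray:
        """Counts for classes 1..n-1."""
        return self.counts[1:-1]

    @property
    def S(self) -> float:
        return float(self.segregating.sum())

    def fold(self) -> "SFS1D":
        """Map class i onto min(i, n - i); idempotent."""
        if self.folded:
            return SFS1D(self.counts.copy(), folded=True)
        n = self.n
        out = np.zeros_like(self.counts)
        for i in range(n + 1):
            out[min(i, n - i)] += self.counts[i]
        return SFS1D(out, folded=True)


def _site_counts(ds: HaplotypeDataset, pop1: str, pop2: str):
    i = ds.derived_counts(pop1)
    j = ds.derived_counts(pop2)
    return i, j, ds.sample_size(pop1), ds.sample_size(pop2)


def build_joint_sfs(
    ds: HaplotypeDataset, pop1: str | None = None, pop2: str | None = None
) -> JointSFS:
    """Accumulate the joint SFS of a complete-call haploid dataset.

    Sites monomorphic across both populations fall in the masked corners
    and do not contribute.  Every site increments exactly one cell, so
    the unmasked total equals the number of contributing SNPs.
    """
    names = ds.population_names
    if pop1 is None or pop2 is None:
        if len(names) != 2:
            raise ValueError(
                "dataset has {} populations; pass pop1/pop2 explicitly".format(
                    len(names)
                )
            )
        pop1, pop2 = names
    i, j, n1, n2 = _site_counts(ds, pop1, pop2)
    if np.any(i > n1) or np.any(j > n2):
        raise ValueError("derived count exceeds population sample size")
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (i, j), 1.0)
    counts[0, 0] = 0.0
    counts[n1, n2] = 0.0
    return JointSFS(counts, folded=False, pop_names=(pop1, pop2))


def marginal_sfs(jsfs: JointSFS, pop: int) -> SFS1D:
    """Functional alias for :meth:`JointSFS.marginal`."""
    return jsfs.marginal(pop)


def fold_sfs(sfs):
    """Fold a 1D or joint SFS (idempotent)."""
    return sfs.fold()
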