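"""Summary statistics: Watterson's theta, nucleotide diversity, Tajima's D,
Hudson's F_ST, the SFS-shape chi-squared test, and genotype PCA.

All SFS-based statistics accept either an :class:`~demosfs.sfs.SFS1D` /
:class:`~demosfs.sfs.JointSFS` object or a raw count array.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .datasets import HaplotypeDataset
from .sfs import SFS1D, JointSFS

__all__ = [
    "watterson_theta",
    "nucleotide_diversity",
    "tajimas_d",
    "hudson_fst",
    "sfs_chisq_test",
    "pca_genotypes",
]


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _as_xi(sfs, n: int | None):
    """Normalize to (full-length counts over classes 0..n, n)."""
    if isinstance(sfs, SFS1D):
        return sfs.counts, sfs.n
    xi = np.asarray(sfs, dtype=float)
    if xi.ndim != 1:
        raise ValueError("expected a 1D SFS")
    if n is None:
        n = len(xi) - 1
    if len(xi) == n + 1:
        return xi, n
    if len(xi) == n - 1:  # segregating classes 1..n-1 only
        return np.concatenate([[0.0], xi, [0.0]]), n
    raise ValueError(f"SFS length {len(xi)} incompatible with n={n}")


def watterson_theta(S: float, n: int, L: float = 1.0) -> float:
    """Watterson's estimator theta_w = S / (a_n L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if L <= 0:
        raise ValueError("L must be > 0")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (_harmonic(n) * L)


def nucleotide_diversity(sfs, n: int | None = None, L: float = 1.0) -> float:
    """Per-site pairwise diversity pi = sum_i i (n - i) xi_i / C(n, 2) / L.

    The weight i (n - i) is symmetric under folding, so folded spectra
    give the same value.
    """
    xi, n = _as_xi(sfs, n)
    if n < 2:
        raise ValueError("n must be >= 2")
    if L <= 0:
        raise ValueError("L must be > 0")
    i = np.arange(n + 1)
    return float((i * (n - i) * xi).sum() / (n * (n - 1) / 2) / L)


def tajimas_d(sfs, n: int | None = None) -> float:
    """Tajima's D from an SFS (standard normalization constants).

    Undefined (raises) when the spectrum holds no segregating sites.
    """
    xi, n = _as_xi(sfs, n)
    if n < 2:
        raise ValueError("n must be >= 2")
    S = float(xi[1:n].sum())
    if S <= 0:
        raise ValueError("Tajima's D is undefined for S = 0")
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = nucleotide_diversity(xi, n=n, L=1.0)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def hudson_fst(jsfs_or_freqs, n1: int | None = None, n2: int | None = None) -> float:
    """Hudson's F_ST in ratio-of-averages form.

    ``F_ST = 1 - mean(H_w) / mean(H_b)``, where per site the
    sample-size-corrected within-population heterozygosity is
    ``p1 (1 - p1) n1 / (n1 - 1) + p2 (1 - p2) n2 / (n2 - 1)`` and the
    between-population heterozygosity is ``p1 (1 - p2) + p2 (1 - p1)``;
    the two sums run over all usable sites before the ratio is taken.

    Accepts a :class:`JointSFS` (weights = cell counts) or two arrays of
    per-site derived counts with explicit sample sizes.
    """
    if isinstance(jsfs_or_freqs, JointSFS):
        j = jsfs_or_freqs
        n1, n2 = j.n1, j.n2
        i_idx, j_idx = np.meshgrid(
            np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij"
        )
        w = np.where(j.mask, 0.0, j.counts).ravel()
        ci = i_idx.ravel().astype(float)
        cj = j_idx.ravel().astype(float)
    else:
        ci = np.asarray(jsfs_or_freqs[0], dtype=float)
        cj = np.asarray(jsfs_or_freqs[1], dtype=float)
        if n1 is None or n2 is None:
            raise ValueError("sample sizes n1 and n2 are required")
        w = np.ones_like(ci)
    if n1 < 2 or n2 < 2:
        raise ValueError("both sample sizes must be >= 2 for Hudson's F_ST")
    p1 = ci / n1
    p2 = cj / n2
    h_within = p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)
    h_between = p1 * (1 - p2) + p2 * (1 - p1)
    denom = float((w * h_between).sum())
    if denom == 0.0:
        raise ValueError("no usable polymorphic sites for F_ST")
    return 1.0 - float((w * h_within).sum()) / denom


def _class_counts(sfs, n: int | None):
    if isinstance(sfs, SFS1D):
        return sfs.segregating
    if n is not None:
        xi, n = _as_xi(sfs, n)
        return xi[1:-1]
    # raw arrays without an explicit n are taken as class counts as-is
    return np.asarray(sfs, dtype=float)


def sfs_chisq_test(sfs_a, sfs_b, n: int | None = None, min_expected: float = 5.0):
    """Pearson chi-squared comparison of two SFS shapes.

    Builds the 2 x (n-1) contingency table of frequency-class counts and
    pools classes from the high-frequency end until every expected cell
    count reaches ``min_expected``.  Returns ``(statistic, df, p)``.
    """
    a = np.asarray(_class_counts(sfs_a, n), dtype=float)
    b = np.asarray(_class_counts(sfs_b, n), dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two spectra must have identical class structure")
    table = np.vstack([a, b])

    def expected(tbl):
        row = tbl.sum(axis=1, keepdims=True)
        col = tbl.sum(axis=0, keepdims=True)
        tot = tbl.sum()
        if tot == 0:
            raise ValueError("degenerate table: no observations")
        return row * col / tot

    while table.shape[1] > 2:
        exp = expected(table)
        if exp.min() >= min_expected:
            break
        table = np.hstack([table[:, :-2], table[:, -2:].sum(axis=1, keepdims=True)])
    exp = expected(table)
    if table.shape[1] < 2 or np.any(exp.sum(axis=0) == 0) or np.any(
        exp.sum(axis=1) == 0
    ):
        raise ValueError("degenerate contingency table after pooling")
    if exp.min() < min_expected:
        warnings.warn(
            "expected cell counts below threshold even after pooling",
            stacklevel=2,
        )
    stat = float(((table - exp) ** 2 / np.where(exp > 0, exp, 1.0)).sum())
    df = table.shape[1] - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def pca_genotypes(ds: HaplotypeDataset, n_components: int = 2, scale: bool = False):
    """Principal components of the sample-by-site genotype matrix.

    Columns (sites) are mean-centred (optionally scaled by
    ``sqrt(p (1 - p))``) and decomposed by SVD; scores are deterministic
    up to the fixed sign convention (largest-magnitude loading positive).

    Returns ``(scores, explained_variance_ratio)`` with ``scores`` of
    shape (n_samples, n_components).
    """
    if ds.n_samples < 2 or ds.n_sites < 1:
        raise ValueError("need at least 2 samples and 1 site for PCA")
    x = ds.genotypes.T.astype(float)  # samples x sites
    p = x.mean(axis=0)
    x = x - p
    if scale:
        s = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        x = x / s
    max_comp = min(ds.n_samples, ds.n_sites)
    if n_components > max_comp:
        warnings.warn(
            f"only {max_comp} components available; truncating", stacklevel=2
        )
        n_components = max_comp
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|u| entry of each component positive
    for c in range(len(sv)):
        i = np.argmax(np.abs(u[:, c]))
        if u[i, c] < 0:
            u[:, c] = -u[:, c]
    scores = u[:, :n_components] * sv[:n_components]
    var = sv**2
    evr = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
    return scores, evr
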