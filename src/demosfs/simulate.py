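"""Structured-coalescent simulation and the synthetic-data generator.

Two routes implement the same genealogical process:

* :func:`simulate_genealogy` — pure-Python, returns a full
  :class:`Genealogy` (needed for tree-level statistics, mutation
  dropping with genotypes, newick export, cross-coalescence rates);
* :func:`expected_jsfs` / :func:`simulate_sfs_counts` — the numba batch
  kernel in :mod:`demosfs._kernel`, which only accumulates branch-category
  lengths (and optional mutation counts) and is orders of magnitude
  faster.  The test suite cross-checks the two routes against each other
  and against the closed-form single-population SFS theta/i.

Loci are unlinked and internally non-recombining, matching the composite
treatment of sites in the SFS likelihood.  The synthetic-data generator
emulates the study design: two populations of 14 haploid genomes,
intronic-like biallelic SNPs in three recombination-rate classes, with
an optional external-branch mutation-rate multiplier in the lowest class
as a minimal surrogate for linked negative selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .datasets import HaplotypeDataset
from .models import ModelSpec, ScaledParams, eu_growth_rate, validate_params

__all__ = [
    "Genealogy",
    "SimConfig",
    "simulate_genealogy",
    "branch_category_lengths",
    "drop_mutations",
    "simulate_dataset",
    "expected_jsfs",
    "simulate_sfs_counts",
    "ExpectedJSFS",
    "constant_population_params",
    "RECOMB_CLASS_BREAKS",
]

_BIG = 1.0e30

#: recombination-class boundaries in cM/Mb (half-open, last class closed)
RECOMB_CLASS_BREAKS = (0.0, 1.5, 3.0, 14.5)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        raise ValueError("an explicit seed or numpy Generator is required")
    return np.random.default_rng(rng)


def constant_population_params() -> tuple[ModelSpec, ScaledParams]:
    """NOMIG parameterization equivalent to a single constant-size population
    (all relative sizes 1), convenient for calibration runs."""
    from .models import make_model_spec

    return make_model_spec("NOMIG"), ScaledParams(
        nu_af=1.0, nu_bot=1.0, nu_eu=1.0, T_exp=1.0, T_split=0.5
    )


@dataclass
class Genealogy:
    """A coalescent tree over n1 + n2 labelled leaves.

    Leaves are nodes ``0 .. n-1`` (the first ``n1`` from population 1) at
    time 0; internal nodes follow in coalescence order; node ``2n-2`` is
    the root.  Times are scaled (units of 2 N_ANC generations).
    """

    n1: int
    n2: int
    time: np.ndarray  # (2n-1,)
    parent: np.ndarray  # (2n-1,) int, -1 at root
    children: np.ndarray  # (2n-1, 2) int, -1 for leaves
    leaf_population: np.ndarray  # (n,) int8: 0 = pop1, 1 = pop2
    migrations: list = field(default_factory=list)  # (time, node, from, to)

    @property
    def n_leaves(self) -> int:
        return self.n1 + self.n2

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def leaf_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node number of descendant leaves in each population."""
        n = self.n_leaves
        c1 = np.zeros(self.n_nodes, dtype=np.int64)
        c2 = np.zeros(self.n_nodes, dtype=np.int64)
        c1[:n] = self.leaf_population == 0
        c2[:n] = self.leaf_population == 1
        for v in range(n, self.n_nodes):  # children always precede parents
            a, b = self.children[v]
            c1[v] = c1[a] + c1[b]
            c2[v] = c2[a] + c2[b]
        return c1, c2

    def leaf_sets(self) -> list[np.ndarray]:
        """Per-node boolean mask over leaves of its descendant set."""
        n = self.n_leaves
        out = [np.zeros(n, dtype=bool) for _ in range(self.n_nodes)]
        for i in range(n):
            out[i][i] = True
        for v in range(n, self.n_nodes):
            a, b = self.children[v]
            out[v] = out[a] | out[b]
        return out

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        ell = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        ell[nz] = self.time[self.parent[nz]] - self.time[nz]
        return ell

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def coalescence_times(self) -> np.ndarray:
        return self.time[self.n_leaves :]

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            p = self.parent[v]
            ell = 0.0 if p < 0 else self.time[p] - self.time[v]
            if self.children[v][0] < 0:
                pop = "A" if self.leaf_population[v] == 0 else "B"
                return f"{pop}{v}:{ell:.6g}"
            a, b = self.children[v]
            return f"({rec(a)},{rec(b)}):{ell:.6g}"

        return rec(self.root).rsplit(":", 1)[0] + ";"


def branch_category_lengths(g: Genealogy) -> np.ndarray:
    """Matrix T[i][j]: total branch length subtending i pop1 and j pop2 leaves.

    The root contributes nothing (its "branch" has no length), so the
    (n1, n2) and (0, 0) corners are structurally zero.
    """
    c1, c2 = g.leaf_counts()
    ell = g.branch_lengths()
    out = np.zeros((g.n1 + 1, g.n2 + 1))
    np.add.at(out, (c1, c2), ell)
    return out


def _check_sim_inputs(spec: ModelSpec, params: ScaledParams, n1: int, n2: int):
    v = validate_params(spec, params)
    if v:
        raise ValueError("invalid demographic parameters: " + "; ".join(v))
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages in total")


def _kernel_args(spec: ModelSpec, params: ScaledParams) -> tuple:
    """Map a scenario onto the flat kernel parameterization."""
    if spec.name == "NOMIG":
        m_eu, m_af, t_mig = 0.0, 0.0, params.T_split
    elif spec.name == "RASYMIG":
        m_eu, m_af, t_mig = params.M_AtoE, params.M_EtoA, params.T_mig
    else:
        m_eu, m_af, t_mig = params.M_AtoE, params.M_EtoA, params.T_split
    return (
        params.nu_af,
        params.nu_bot,
        params.nu_eu,
        params.T_exp,
        params.T_split,
        m_eu,
        m_af,
        t_mig,
    )


def simulate_genealogy(
    spec: ModelSpec,
    params: ScaledParams,
    n1: int,
    n2: int,
    rng,
) -> Genealogy:
    """Draw one structured-coalescent genealogy backwards in time.

    Competing exponential events (within-population coalescence at rate
    C(k,2)/nu(t), per-lineage backward migration) are sampled epoch by
    epoch; the exponentially growing European population uses exact
    inversion of its cumulative coalescence intensity.  At ``T_split``
    all European lineages merge into the (African) ancestral population;
    at ``T_exp`` the ancestral size reverts to 1.
    """
    rng = _as_rng(rng)
    _check_sim_inputs(spec, params, n1, n2)
    nu_af, nu_bot, nu_eu, t_exp, t_split, m_eu, m_af, t_mig = _kernel_args(
        spec, params
    )
    beta = eu_growth_rate(params) if nu_eu != nu_bot else 0.0

    n = n1 + n2
    time = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    leaf_population = np.array([0] * n1 + [1] * n2, dtype=np.int8)
    migrations: list[tuple[float, int, int, int]] = []

    # active lineages: (node_id, pop)
    nodes = list(range(n))
    pops = [0] * n1 + [1] * n2
    next_node = n
    t = 0.0

    def exp_wait(rate: float) -> float:
        return _BIG if rate <= 0 else rng.exponential(1.0 / rate)

    while len(nodes) > 1:
        k = len(nodes)
        k_af = pops.count(0)
        k_eu = k - k_af

        if t < t_split:
            size_af = nu_af
            mig_on = t < t_mig
            boundary = t_mig if (mig_on and t_mig < t_split) else t_split
        elif t < t_exp:
            size_af, mig_on, boundary = nu_af, False, t_exp
        else:
            size_af, mig_on, boundary = 1.0, False, _BIG

        w_caf = exp_wait(0.5 * k_af * (k_af - 1) / size_af)
        if t < t_split and k_eu >= 2:
            c = 0.5 * k_eu * (k_eu - 1)
            e = rng.exponential()
            if beta == 0.0:
                w_ceu = e * nu_eu / c
            else:
                arg = math.exp(beta * t) + e * nu_eu * beta / c
                w_ceu = _BIG if arg <= 0 else max(math.log(arg) / beta - t, 1e-300)
        else:
            w_ceu = _BIG
        w_maf = exp_wait(k_af * m_af) if mig_on else _BIG
        w_meu = exp_wait(k_eu * m_eu) if mig_on else _BIG

        w, ev = min(
            (w_caf, 0), (w_ceu, 1), (w_maf, 2), (w_meu, 3), key=lambda x: x[0]
        )

        if t + w >= boundary:
            t = boundary
            if boundary == t_split:
                pops = [0] * k
            continue
        t += w

        if ev in (0, 1):
            p = 0 if ev == 0 else 1
            idx = [i for i in range(k) if pops[i] == p]
            ia, ib = rng.choice(len(idx), size=2, replace=False)
            ia, ib = idx[ia], idx[ib]
            v = next_node
            next_node += 1
            time[v] = t
            children[v] = (nodes[ia], nodes[ib])
            parent[nodes[ia]] = v
            parent[nodes[ib]] = v
            for i in sorted((ia, ib), reverse=True):
                del nodes[i]
                del pops[i]
            nodes.append(v)
            pops.append(p)
        else:
            src = 0 if ev == 2 else 1
            idx = [i for i in range(k) if pops[i] == src]
            i = idx[rng.integers(len(idx))]
            migrations.append((t, nodes[i], src, 1 - src))
            pops[i] = 1 - src

    return Genealogy(
        n1=n1,
        n2=n2,
        time=time,
        parent=parent,
        children=children,
        leaf_population=leaf_population,
        migrations=migrations,
    )


@dataclass(frozen=True)
class Site:
    """One infinite-sites mutation: the branch it fell on and the derived
    counts (i, j) in the two populations."""

    node: int
    i: int
    j: int


def drop_mutations(
    g: Genealogy, theta_locus: float, rng, inflation_f: float = 1.0
) -> list[Site]:
    """Drop infinite-sites mutations on a genealogy.

    Each branch of length ``ell`` receives Poisson(theta_locus * ell / 2)
    mutations; external (leaf-subtending) branches have their rate
    multiplied by ``inflation_f`` (>= 1), the singleton-excess surrogate.
    """
    if theta_locus < 0:
        raise ValueError("theta_locus must be >= 0")
    if inflation_f < 1:
        raise ValueError("inflation_f must be >= 1")
    rng = _as_rng(rng)
    if theta_locus == 0:
        return []
    c1, c2 = g.leaf_counts()
    ell = g.branch_lengths()
    lam = 0.5 * theta_locus * ell
    lam[: g.n_leaves] *= inflation_f
    counts = rng.poisson(lam)
    sites: list[Site] = []
    for v in np.flatnonzero(counts):
        sites.extend([Site(int(v), int(c1[v]), int(c2[v]))] * int(counts[v]))
    return sites


@dataclass
class SimConfig:
    """Study-design configuration for the synthetic-data generator.

    Defaults emulate the study: two populations of 14 haploid genomes,
    loci spread over three recombination classes, no selection surrogate.
    """

    spec: ModelSpec
    params: ScaledParams
    n1: int = 14
    n2: int = 14
    n_loci: int = 500
    theta_locus: float = 5.0
    recomb_class_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    singleton_inflation_f: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check_sim_inputs(self.spec, self.params, self.n1, self.n2)
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if self.theta_locus < 0:
            raise ValueError("theta_locus must be >= 0")
        if abs(sum(self.recomb_class_fractions) - 1.0) > 1e-9:
            raise ValueError("recomb_class_fractions must sum to 1")
        if any(f < 0 for f in self.recomb_class_fractions):
            raise ValueError("recomb_class_fractions must be >= 0")
        if self.singleton_inflation_f < 1:
            raise ValueError("singleton_inflation_f must be >= 1")


def simulate_dataset(cfg: SimConfig) -> HaplotypeDataset:
    """Generate a haploid dataset of unlinked loci under a demographic model.

    Each locus lives on its own pseudo-contig with strictly increasing
    synthetic positions; a recombination rate (cM/Mb) is drawn uniformly
    within the locus's class interval; loci in the lowest class get the
    external-branch singleton inflation.  Polarization is "derived"
    (the simulator knows the ancestral state).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n1 + cfg.n2
    samples = [f"pop1_{i:02d}" for i in range(cfg.n1)] + [
        f"pop2_{i:02d}" for i in range(cfg.n2)
    ]
    populations = np.array(["pop1"] * cfg.n1 + ["pop2"] * cfg.n2)

    geno_rows: list[np.ndarray] = []
    contigs: list[str] = []
    positions: list[int] = []
    rates: list[float] = []
    classes = rng.choice(3, size=cfg.n_loci, p=cfg.recomb_class_fractions)
    for locus in range(cfg.n_loci):
        cls = int(classes[locus])
        lo, hi = RECOMB_CLASS_BREAKS[cls], RECOMB_CLASS_BREAKS[cls + 1]
        rate = float(rng.uniform(lo, hi))
        f = cfg.singleton_inflation_f if cls == 0 else 1.0
        g = simulate_genealogy(cfg.spec, cfg.params, cfg.n1, cfg.n2, rng)
        sites = drop_mutations(g, cfg.theta_locus, rng, inflation_f=f)
        if not sites:
            continue
        leaf_sets = g.leaf_sets()
        ctg = f"locus{locus:05d}"
        for s_idx, site in enumerate(sites):
            geno_rows.append(leaf_sets[site.node].astype(np.int8))
            contigs.append(ctg)
            positions.append(s_idx)
            rates.append(rate)

    genotypes = (
        np.array(geno_rows, dtype=np.int8)
        if geno_rows
        else np.zeros((0, n), dtype=np.int8)
    )
    return HaplotypeDataset(
        samples=samples,
        populations=populations,
        genotypes=genotypes,
        contig=np.array(contigs, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        polarization="derived",
        rec_rate=np.array(rates) if rates else np.zeros(0),
        provenance={
            "generator": "demosfs.simulate.simulate_dataset",
            "model": cfg.spec.name,
            "params": cfg.params.as_dict(),
            "n_loci": cfg.n_loci,
            "theta_locus": cfg.theta_locus,
            "recomb_class_fractions": list(cfg.recomb_class_fractions),
            "singleton_inflation_f": cfg.singleton_inflation_f,
            "seed": cfg.seed,
        },
    )


@dataclass
class ExpectedJSFS:
    """Monte-Carlo expected joint SFS per unit theta, with standard errors."""

    per_theta: np.ndarray  # (n1+1, n2+1)
    se: np.ndarray
    n_reps: int

    @property
    def total(self) -> float:
        return float(self.per_theta.sum())


def _kernel_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    return int(_as_rng(rng).integers(2**31 - 1))


def expected_jsfs(
    spec: ModelSpec,
    params: ScaledParams,
    n1: int,
    n2: int,
    n_reps: int,
    rng,
) -> ExpectedJSFS:
    """Monte-Carlo expectation of the joint SFS per unit theta.

    Entry (i, j) is the mean over ``n_reps`` genealogies of half the
    branch length subtending i pop1 / j pop2 leaves; multiplying by a
    per-locus theta gives the expected SFS of one locus.  Monomorphic
    corners are structurally zero.
    """
    _check_sim_inputs(spec, params, n1, n2)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    len_sum = np.zeros((n1 + 1, n2 + 1))
    len_sumsq = np.zeros((n1 + 1, n2 + 1))
    sfs_counts = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    _kernel.simulate_batch(
        n1,
        n2,
        *_kernel_args(spec, params),
        n_reps,
        _kernel_seed(rng),
        0.0,
        1.0,
        len_sum,
        len_sumsq,
        sfs_counts,
    )
    mean_t = len_sum / n_reps
    var_t = np.maximum(len_sumsq / n_reps - mean_t**2, 0.0)
    se_t = np.sqrt(var_t / n_reps)
    return ExpectedJSFS(per_theta=mean_t / 2.0, se=se_t / 2.0, n_reps=n_reps)


def simulate_sfs_counts(
    spec: ModelSpec,
    params: ScaledParams,
    n1: int,
    n2: int,
    n_loci: int,
    theta_locus: float,
    rng,
    inflation_f: float = 1.0,
) -> np.ndarray:
    """Pooled joint-SFS counts from ``n_loci`` unlinked loci (fast path).

    Equivalent in distribution to pooling :func:`drop_mutations` over
    independently simulated genealogies, but runs in the batch kernel.
    """
    _check_sim_inputs(spec, params, n1, n2)
    if theta_locus < 0:
        raise ValueError("theta_locus must be >= 0")
    if inflation_f < 1:
        raise ValueError("inflation_f must be >= 1")
    len_sum = np.zeros((n1 + 1, n2 + 1))
    len_sumsq = np.zeros((n1 + 1, n2 + 1))
    sfs_counts = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    _kernel.simulate_batch(
        n1,
        n2,
        *_kernel_args(spec, params),
        n_loci,
        _kernel_seed(rng),
        float(theta_locus),
        float(inflation_f),
        len_sum,
        len_sumsq,
        sfs_counts,
    )
    return sfs_counts
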