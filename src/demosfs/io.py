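"""Readers and writers: haploid VCF + panel, BED masks, recombination maps,
and dadi-dialect text SFS files.

Coordinates are converted to the internal 0-based half-open convention
on read (VCF POS is 1-based; BED is already 0-based half-open).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import HaplotypeDataset
from .intervals import IntervalTrack
from .sfs import JointSFS

logger = logging.getLogger(__name__)

__all__ = [
    "read_haploid_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "read_bed",
    "read_recmap",
    "read_sfs",
    "write_sfs",
]


def read_panel(path) -> dict[str, str]:
    """Two-column text file mapping sample id -> population label."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample population'")
        out[parts[0]] = parts[1]
    return out


def write_panel(ds: HaplotypeDataset, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(ds.samples, ds.populations):
            fh.write(f"{s}\t{p}\n")


def read_haploid_vcf(path, panel_path) -> HaplotypeDataset:
    """Load biallelic SNPs with haploid (or homozygous-diploid) calls.

    Heterozygous diploid calls mark a site as unusable and it is dropped
    (with a logged count) — random phasing would distort the SFS and the
    haploid study design implies complete homozygous calls.  Ancestral
    alleles come from the AA INFO tag when present; otherwise REF is
    treated as ancestral and the dataset is flagged "unpolarized".
    Multiallelic and indel records are skipped; sites monomorphic across
    all samples after coding are dropped.
    """
    from cyvcf2 import VCF

    panel = read_panel(panel_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in panel]
    if missing:
        raise ValueError(f"samples missing from panel file: {missing}")
    populations = np.array([panel[s] for s in samples])

    rows, contigs, positions, rrates = [], [], [], []
    n_multi = n_het = n_missing = n_mono = 0
    any_aa = False
    any_rr = False
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_multi += 1
            continue
        alleles = []
        usable = True
        het = False
        for entry in var.genotypes:
            calls = entry[:-1]  # last element is phasing flag
            calls = [c for c in calls if c != -2]  # -2 pads haploid calls
            if any(c == -1 for c in calls):
                usable = False
                break
            if len(calls) == 2 and calls[0] != calls[1]:
                het = True
                break
            alleles.append(calls[0])
        if het:
            n_het += 1
            continue
        if not usable:
            n_missing += 1
            continue
        g = np.array(alleles, dtype=np.int8)
        aa = var.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa == var.ALT[0].upper():
                g = 1 - g  # ALT is ancestral: flip to derived coding
                any_aa = True
            elif aa == var.REF.upper():
                any_aa = True
            # unknown AA strings: keep REF-as-ancestral coding
        tot = int(g.sum())
        if tot == 0 or tot == len(g):
            n_mono += 1
            continue
        rows.append(g)
        contigs.append(var.CHROM)
        positions.append(var.POS - 1)  # to 0-based
        rr = var.INFO.get("RR")
        if rr is not None:
            any_rr = True
            rrates.append(float(rr))
        else:
            rrates.append(np.nan)
    if n_multi or n_het or n_missing or n_mono:
        logger.info(
            "VCF %s: skipped %d multiallelic/non-SNP, %d heterozygous, "
            "%d missing-call, %d monomorphic sites",
            path, n_multi, n_het, n_missing, n_mono,
        )
    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return HaplotypeDataset(
        samples=samples,
        populations=populations,
        genotypes=genotypes,
        contig=np.array(contigs, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        rec_rate=np.array(rrates) if any_rr else None,
        polarization="derived" if any_aa else "unpolarized",
        provenance={
            "source": str(path),
            "panel": str(panel_path),
            "skipped": {
                "multiallelic": n_multi,
                "heterozygous": n_het,
                "missing": n_missing,
                "monomorphic": n_mono,
            },
        },
    )


def write_vcf(ds: HaplotypeDataset, path) -> None:
    """Write haploid genotypes as a minimal VCF (synthetic REF/ALT bases).

    The AA INFO tag records the ancestral allele when the dataset is
    polarized, so a write -> read round trip preserves the 0/1 coding.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demosfs\n")
        for ctg in pd.unique(ds.contig.astype(str)):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write(
            '##INFO=<ID=RR,Number=1,Type=Float,'
            'Description="Local recombination rate (cM/Mb)">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for i in range(ds.n_sites):
            info = []
            if ds.polarization == "derived":
                info.append("AA=A")
            if ds.rec_rate is not None:
                info.append(f"RR={ds.rec_rate[i]:.6g}")
            gts = "\t".join(str(int(x)) for x in ds.genotypes[i])
            fh.write(
                f"{ds.contig[i]}\t{ds.pos[i] + 1}\t.\tA\tT\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def _read_intervals(path, with_value: bool, what: str):
    ctg: list[str] = []
    st: list[int] = []
    en: list[int] = []
    val: list[float] = []
    need = 4 if with_value else 3
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < need:
            raise ValueError(f"{path}:{lineno}: {what} needs >= {need} columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} must be < end {end}")
        if with_value:
            try:
                val.append(float(parts[3]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: 4th column must be numeric"
                ) from exc
        ctg.append(parts[0])
        st.append(start)
        en.append(end)
    return (
        np.array(ctg, dtype=object),
        np.array(st, dtype=np.int64),
        np.array(en, dtype=np.int64),
        np.array(val) if with_value else None,
    )


def read_bed(path) -> IntervalTrack:
    """BED intervals (0-based half-open); overlaps are merged."""
    ctg, st, en, _ = _read_intervals(path, False, "BED")
    return IntervalTrack(contig=ctg, start=st, end=en)


def read_recmap(path) -> IntervalTrack:
    """Windowed recombination map: contig, start, end, rate (cM/Mb).

    Overlapping windows are rejected (the rate would be ambiguous).
    """
    ctg, st, en, val = _read_intervals(path, True, "recombination map")
    if len(ctg) == 0:
        raise ValueError(f"{path}: empty recombination map")
    return IntervalTrack(contig=ctg, start=st, end=en, value=val)


def write_sfs(jsfs: JointSFS, path) -> None:
    """dadi-dialect text SFS: dimension header with folding flag, row-major
    counts, then a 0/1 mask line (1 = masked)."""
    n1, n2 = jsfs.n1, jsfs.n2
    with open(path, "w") as fh:
        fold = "folded" if jsfs.folded else "unfolded"
        fh.write(f'{n1 + 1} {n2 + 1} {fold} "{jsfs.pop_names[0]}" '
                 f'"{jsfs.pop_names[1]}"\n')
        fh.write(" ".join(f"{x:.10g}" for x in jsfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in jsfs.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    """Read the dadi-dialect text SFS written by :func:`write_sfs`."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated SFS file")
    header = lines[0].split()
    dims = []
    rest = []
    for tok in header:
        if tok.isdigit() and not rest:
            dims.append(int(tok))
        else:
            rest.append(tok)
    if len(dims) != 2:
        raise ValueError(f"{path}: expected two dimensions, got {dims}")
    folded = any(t.strip('"') == "folded" for t in rest)
    pop_names = tuple(t.strip('"') for t in rest if t.strip('"') not in
                      ("folded", "unfolded"))
    if len(pop_names) != 2:
        pop_names = ("pop1", "pop2")
    data = np.array(lines[1].split(), dtype=float)
    if len(data) != dims[0] * dims[1]:
        raise ValueError(
            f"{path}: {len(data)} counts do not fill a {dims[0]}x{dims[1]} matrix"
        )
    counts = data.reshape(dims)
    mask = None
    if len(lines) >= 3:
        m = np.array(lines[2].split(), dtype=int)
        if len(m) != dims[0] * dims[1]:
            raise ValueError(f"{path}: mask line length mismatch")
        mask = m.reshape(dims).astype(bool)
    return JointSFS(counts, folded=folded, mask=mask, pop_names=pop_names)
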