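"""Genomic interval tracks (0-based half-open), masking, and the
recombination-class partition."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import HaplotypeDataset
from .simulate import RECOMB_CLASS_BREAKS

logger = logging.getLogger(__name__)

__all__ = ["IntervalTrack", "apply_masks", "partition_by_recomb", "annotate_recomb"]


@dataclass
class IntervalTrack:
    """Sorted, non-overlapping intervals per contig, optionally valued.

    Coordinates are 0-based half-open (BED-native).  Construction
    normalizes: sorts by (contig, start) and merges overlapping or
    book-ended intervals for unvalued tracks; overlapping intervals in a
    valued track (e.g. a recombination map) are ambiguous and rejected.
    """

    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray | None = None

    def __post_init__(self):
        self.contig = np.asarray(self.contig, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.value is not None:
            self.value = np.asarray(self.value, dtype=float)
            if len(self.value) != len(self.start):
                raise ValueError("value length must match interval count")
        if np.any(self.start >= self.end):
            bad = int(np.flatnonzero(self.start >= self.end)[0])
            raise ValueError(
                f"malformed interval {self.contig[bad]}:{self.start[bad]}-"
                f"{self.end[bad]} (start must be < end)"
            )
        order = np.lexsort((self.start, self.contig.astype(str)))
        self.contig = self.contig[order]
        self.start = self.start[order]
        self.end = self.end[order]
        if self.value is not None:
            self.value = self.value[order]
            for i in range(1, len(self.start)):
                if (
                    self.contig[i] == self.contig[i - 1]
                    and self.start[i] < self.end[i - 1]
                ):
                    raise ValueError(
                        "overlapping intervals in a valued track are ambiguous: "
                        f"{self.contig[i]}:{self.start[i]}"
                    )
        else:
            self._merge_in_place()

    def _merge_in_place(self):
        if len(self.start) == 0:
            return
        ctg, st, en = [], [], []
        for c, s, e in zip(self.contig, self.start, self.end):
            if ctg and ctg[-1] == c and s <= en[-1]:
                en[-1] = max(en[-1], e)
            else:
                ctg.append(c)
                st.append(s)
                en.append(e)
        self.contig = np.asarray(ctg, dtype=object)
        self.start = np.asarray(st, dtype=np.int64)
        self.end = np.asarray(en, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.start)

    def _per_contig(self):
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]] = {}
        for c in np.unique(self.contig.astype(str)):
            m = self.contig == c
            out[c] = (
                self.start[m],
                self.end[m],
                None if self.value is None else self.value[m],
            )
        return out

    def covers(self, contig: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does any interval contain each (contig, pos)?"""
        per = self._per_contig()
        pos = np.asarray(pos)
        hit = np.zeros(len(pos), dtype=bool)
        for c, (st, en, _) in per.items():
            sel = np.asarray(contig, dtype=object) == c
            if not sel.any():
                continue
            p = pos[sel]
            i = np.searchsorted(st, p, side="right") - 1
            ok = (i >= 0) & (p < en[np.clip(i, 0, len(en) - 1)])
            hit[sel] = ok
        return hit

    def lookup(self, contig: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Values at each (contig, pos); NaN where uncovered."""
        if self.value is None:
            raise ValueError("track has no values")
        per = self._per_contig()
        pos = np.asarray(pos)
        out = np.full(len(pos), np.nan)
        for c, (st, en, val) in per.items():
            sel = np.asarray(contig, dtype=object) == c
            if not sel.any():
                continue
            p = pos[sel]
            i = np.searchsorted(st, p, side="right") - 1
            ok = (i >= 0) & (p < en[np.clip(i, 0, len(en) - 1)])
            v = np.full(len(p), np.nan)
            v[ok] = val[i[ok]]
            out[sel] = v
        return out


def apply_masks(
    ds: HaplotypeDataset,
    masks: list[IntervalTrack] | None,
    keep: list[IntervalTrack] | None = None,
) -> HaplotypeDataset:
    """Remove sites inside any mask; if ``keep`` tracks are given (e.g.
    intron annotation), also remove sites outside all of them."""
    drop = np.zeros(ds.n_sites, dtype=bool)
    for track in masks or []:
        drop |= track.covers(ds.contig, ds.pos)
    if keep:
        kept = np.zeros(ds.n_sites, dtype=bool)
        for track in keep:
            kept |= track.covers(ds.contig, ds.pos)
        drop |= ~kept
    n_removed = int(drop.sum())
    if n_removed:
        logger.info("masking removed %d of %d sites", n_removed, ds.n_sites)
    out = ds.take_sites(np.flatnonzero(~drop))
    out.provenance.setdefault("mask_removed", 0)
    out.provenance["mask_removed"] += n_removed
    return out


def annotate_recomb(ds: HaplotypeDataset, recmap: IntervalTrack) -> HaplotypeDataset:
    """Attach per-site recombination rates (cM/Mb) from a windowed map."""
    rates = recmap.lookup(ds.contig, ds.pos)
    if np.any(np.isnan(rates)):
        i = int(np.flatnonzero(np.isnan(rates))[0])
        raise ValueError(
            f"site {ds.contig[i]}:{ds.pos[i]} is not covered by the "
            "recombination map"
        )
    out = ds.take_sites(np.arange(ds.n_sites))
    out.rec_rate = rates
    return out


def partition_by_recomb(
    ds: HaplotypeDataset,
    recmap: IntervalTrack | None = None,
    breaks: tuple[float, ...] = RECOMB_CLASS_BREAKS,
) -> list[HaplotypeDataset]:
    """Split a dataset into recombination-rate classes.

    Classes are half-open [lo, hi) — a boundary rate is assigned to the
    class above it — except the last, which is closed at its upper edge.
    Returns one dataset per class (some possibly empty); every input
    site appears in exactly one output.
    """
    if ds.rec_rate is None:
        if recmap is None:
            raise ValueError("dataset has no recombination annotation and no "
                             "map was provided")
        ds = annotate_recomb(ds, recmap)
    rates = ds.rec_rate
    lo, hi = breaks[0], breaks[-1]
    if np.any(rates < lo) or np.any(rates > hi):
        i = int(np.flatnonzero((rates < lo) | (rates > hi))[0])
        raise ValueError(
            f"site {ds.contig[i]}:{ds.pos[i]} has rate {rates[i]} outside "
            f"[{lo}, {hi}]"
        )
    inner = np.asarray(breaks[1:-1])
    cls = np.searchsorted(inner, rates, side="right")
    return [ds.take_sites(np.flatnonzero(cls == c)) for c in range(len(breaks) - 1)]
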