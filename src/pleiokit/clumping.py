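"""Genomic risk loci from summary statistics plus an LD reference panel.

Implements the four-tier clumping hierarchy: greedy-by-p selection of
independent significant SNPs (pairwise r^2 < 0.6 within 1 Mb), lead SNPs
among them (pairwise r^2 < 0.1), candidate SNPs (any panel variant at
r^2 >= 0.6 with an independent significant SNP), and risk loci obtained
by merging leads closer than 250 kb, with locus borders spanned by the
candidate SNPs.  The same machinery clumps any per-variant significance
score (e.g. conjunctional FDR values) in place of p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypePanel, SummaryStats, ValidationError

__all__ = ["ClumpParams", "Locus", "UniqueRegion", "ld_r2",
           "clump_independent", "define_loci", "cross_trait_unique_loci"]


@dataclass
class ClumpParams:
    """Thresholds of the clumping hierarchy.

    ``r2_independent`` is the dependence threshold: two significant SNPs
    are dependent iff r^2 >= 0.6 (so independence requires r^2 < 0.6,
    matching the candidate-SNP rule at the boundary).
    """

    p_threshold: float = 5e-8
    r2_independent: float = 0.6
    r2_lead: float = 0.1
    window_bp: int = 1_000_000
    merge_bp: int = 250_000
    r2_candidate: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.r2_lead < self.r2_independent <= 1):
            raise ValidationError("need 0 < r2_lead < r2_independent <= 1")
        if not (0 < self.p_threshold < 1):
            raise ValidationError("p_threshold must be in (0, 1)")


@dataclass
class Locus:
    """A genomic risk locus (1-based inclusive coordinates)."""

    chrom: int
    start: int
    end: int
    lead_ids: list
    independent_ids: list
    candidate_ids: list
    top_p: float

    @property
    def lead(self) -> str:
        return self.lead_ids[0]

    def overlaps(self, other: "Locus") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass
class UniqueRegion:
    """A cross-trait region formed by overlapping per-trait loci."""

    chrom: int
    start: int
    end: int
    traits: list = field(default_factory=list)


class _PanelLd:
    """Cached standardized dosages for repeated r^2 lookups."""

    def __init__(self, panel: GenotypePanel):
        self.panel = panel
        self.z = panel.standardized()
        self.n = panel.n_samples
        v = panel.variants
        self.chrom = v["chrom"].to_numpy()
        self.pos = v["pos"].to_numpy()
        self.index_by_snp = {s: j for j, s in enumerate(v["snp"])}

    def r2(self, i: int, j: int) -> float:
        zi, zj = self.z[:, i], self.z[:, j]
        if np.isnan(zi).all() or np.isnan(zj).all():
            raise ValidationError("zero-variance dosage column")
        r = float(zi @ zj) / self.n
        return r * r

    def r2_many(self, i: int, cols: np.ndarray) -> np.ndarray:
        r = (self.z[:, i] @ self.z[:, cols]) / self.n
        return r * r


def ld_r2(panel: GenotypePanel, i, j) -> float:
    """Squared Pearson correlation of two dosage columns.

    ``i``/``j`` may be column indices or variant ids.
    """
    ld = _PanelLd(panel)
    if isinstance(i, str):
        i = ld.index_by_snp[i]
    if isinstance(j, str):
        j = ld.index_by_snp[j]
    return ld.r2(i, j)


def _sorted_significant(frame: pd.DataFrame, value_col: str,
                        threshold: float) -> pd.DataFrame:
    sig = frame[frame[value_col] < threshold]
    return sig.sort_values([value_col, "chrom", "pos"],
                           kind="mergesort").reset_index(drop=True)


def clump_independent(ss: SummaryStats, panel: GenotypePanel,
                      params: ClumpParams | None = None,
                      values=None, value_col: str = "p") -> list:
    """Greedy-by-significance selection of independent significant SNPs.

    Variants below the significance threshold are visited in ascending
    order of the score (ties broken by chromosome then position); a
    variant is accepted iff its r^2 with every already-accepted variant
    within ``window_bp`` is below ``r2_independent``.  Variants absent
    from the panel are logged and kept as their own clump seeds.

    Returns the accepted variant ids in acceptance order.
    """
    params = params or ClumpParams()
    frame = ss.table.copy()
    if values is not None:
        frame = frame.assign(**{value_col: np.asarray(values, dtype=float)})
    sig = _sorted_significant(frame, value_col, params.p_threshold)
    if len(sig) == 0:
        return []
    ld = _PanelLd(panel)
    accepted: list[str] = []
    acc_cols: list[int] = []
    acc_chrom: list[int] = []
    acc_pos: list[int] = []
    for row in sig.itertuples():
        col = ld.index_by_snp.get(row.snp)
        if col is None:
            accepted.append(row.snp)          # uncovered: own clump seed
            acc_cols.append(-1)
            acc_chrom.append(row.chrom)
            acc_pos.append(row.pos)
            continue
        near = [c for c, ch, po in zip(acc_cols, acc_chrom, acc_pos)
                if c >= 0 and ch == row.chrom
                and abs(po - row.pos) <= params.window_bp]
        if near:
            r2 = ld.r2_many(col, np.array(near))
            if np.any(r2 >= params.r2_independent):
                continue
        accepted.append(row.snp)
        acc_cols.append(col)
        acc_chrom.append(row.chrom)
        acc_pos.append(row.pos)
    return accepted


def define_loci(independent_ids: list, ss: SummaryStats, panel: GenotypePanel,
                params: ClumpParams | None = None,
                values=None, value_col: str = "p") -> list:
    """Lead SNPs, candidate SNPs and merged genomic risk loci.

    Leads are chosen greedily by significance among the independent SNPs
    at mutual r^2 < ``r2_lead`` within the window; every other
    independent SNP joins the lead it is in strongest LD with.  Candidate
    SNPs are all panel variants at r^2 >= ``r2_candidate`` with an
    independent SNP of the locus; the candidate span sets the borders.
    Loci are merged (transitively) when lead positions are closer than
    ``merge_bp`` or their candidate spans overlap.
    """
    params = params or ClumpParams()
    if not independent_ids:
        return []
    frame = ss.table.set_index("snp")
    if values is not None:
        frame = frame.assign(**{value_col: np.asarray(values, dtype=float)})
    ld = _PanelLd(panel)
    info = frame.loc[independent_ids]
    order = np.argsort(info[value_col].to_numpy(), kind="mergesort")

    ids = list(info.index)
    chroms = info["chrom"].to_numpy()
    poss = info["pos"].to_numpy()
    vals = info[value_col].to_numpy(float)
    cols = np.array([ld.index_by_snp.get(s, -1) for s in ids])

    lead_of = np.full(len(ids), -1)
    leads: list[int] = []
    for i in order:
        if lead_of[i] >= 0:
            continue
        best_lead, best_r2 = -1, params.r2_lead
        for li in leads:
            if (chroms[li] == chroms[i]
                    and abs(poss[li] - poss[i]) <= params.window_bp
                    and cols[i] >= 0 and cols[li] >= 0):
                r2 = ld.r2(cols[i], cols[li])
                if r2 >= best_r2:
                    best_lead, best_r2 = li, r2
        if best_lead >= 0:
            lead_of[i] = best_lead
        else:
            leads.append(i)
            lead_of[i] = i

    # build one raw locus per lead
    raw = []
    for li in leads:
        members = np.flatnonzero(lead_of == li)
        cand: set[str] = set()
        lo, hi = int(poss[members].min()), int(poss[members].max())
        for mi in members:
            if cols[mi] < 0:
                cand.add(ids[mi])
                continue
            win = np.flatnonzero((ld.chrom == chroms[mi])
                                 & (np.abs(ld.pos - poss[mi]) <= params.window_bp))
            r2 = ld.r2_many(cols[mi], win)
            hits = win[r2 >= params.r2_candidate]
            cand.update(ld.panel.variants["snp"].iloc[hits])
            if hits.size:
                lo = min(lo, int(ld.pos[hits].min()))
                hi = max(hi, int(ld.pos[hits].max()))
        raw.append(Locus(int(chroms[li]), lo, hi,
                         [ids[li]], [ids[m] for m in members],
                         sorted(cand), float(vals[members].min())))

    # transitive merge: lead distance < merge_bp, or overlapping spans
    lead_pos = {ids[li]: int(poss[li]) for li in leads}
    parent = list(range(len(raw)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(raw)):
        for b in range(a + 1, len(raw)):
            la, lb = raw[a], raw[b]
            if la.chrom != lb.chrom:
                continue
            dist = min(abs(lead_pos[x] - lead_pos[y])
                       for x in la.lead_ids for y in lb.lead_ids)
            if dist < params.merge_bp or la.overlaps(lb):
                parent[find(a)] = find(b)

    groups: dict[int, list[Locus]] = {}
    for a in range(len(raw)):
        groups.setdefault(find(a), []).append(raw[a])
    merged = []
    for group in groups.values():
        group.sort(key=lambda l: l.top_p)
        merged.append(Locus(
            group[0].chrom,
            min(l.start for l in group),
            max(l.end for l in group),
            [lid for l in group for lid in l.lead_ids],
            [i for l in group for i in l.independent_ids],
            sorted(set().union(*(set(l.candidate_ids) for l in group))),
            min(l.top_p for l in group),
        ))
    merged.sort(key=lambda l: (l.chrom, l.start))
    return merged


def cross_trait_unique_loci(loci_by_trait: dict) -> list:
    """Merge per-trait loci into unique regions by interval overlap.

    Loci from different traits whose [start, end] intervals overlap by
    at least one base pair join the same unique region; the region
    records which traits contributed.
    """
    items = [(locus, trait) for trait, loci in loci_by_trait.items()
             for locus in loci]
    items.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    regions: list[UniqueRegion] = []
    for locus, trait in items:
        if (regions and regions[-1].chrom == locus.chrom
                and locus.start <= regions[-1].end):
            regions[-1].end = max(regions[-1].end, locus.end)
            if trait not in regions[-1].traits:
                regions[-1].traits.append(trait)
        else:
            regions.append(UniqueRegion(locus.chrom, locus.start,
                                        locus.end, [trait]))
    return regions
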