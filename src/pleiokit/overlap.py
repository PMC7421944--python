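"""Cross-trait genetic overlap: conditional Q-Q, conditional and
conjunctional FDR, and shared-locus calling.

The conditional FDR of a variant for trait 1 given trait 2 is estimated
from stratified empirical CDFs as

    cFDR(p1 | p2) = p1 * |S(p2)| / #{i in S(p2) : p1_i <= p1},

with S(p2) the stratum of variants whose trait-2 p-value is at most the
observed one and the null proportion pi0 fixed at 1 (a conservative
upper bound).  The conjunctional FDR is the maximum of the two
reciprocal conditional FDRs; a variant significant under it is jointly
associated with both traits.  LD is handled by random pruning (one
variant per LD block per iteration) with the stratified counts averaged
over iterations on a -log10 grid, monotonicity-enforced and then
interpolated back to each variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .containers import GenotypePanel, P_FLOOR, SummaryStats, ValidationError
from .gwas import lambda_gc

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedPair", "harmonize_pair", "ld_blocks",
    "genomic_inflation_correct",
    "ExclusionRegion", "MHC", "REGION_8P23", "exclude_regions",
    "conditional_qq", "ConditionalQq",
    "CondFdrModel", "CondFdrResults", "CondFdrTable",
    "cond_fdr", "conj_fdr", "shared_loci", "SharedLocusReport",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: default -log10 p1 grid (0 .. ~7.3 step 0.1), covering 5e-8
DEFAULT_GRID = np.round(np.arange(0.0, 7.31, 0.1), 10)

#: default conditioning knots: the four Q-Q cutoffs (p2 <= 1, 0.1, 0.01,
#: 0.001) plus half-decade interpolation knots; deeper conditioning is
#: clamped to the strictest knot so strata stay populated after pruning
DEFAULT_GRID2 = np.round(np.arange(0.0, 3.01, 0.5), 10)


# ----------------------------------------------------------------------
# harmonization

@dataclass
class HarmonizedPair:
    """Two summary-statistic sets aligned to a shared variant map.

    ``z2`` is sign-flipped wherever trait 2 reported the swapped allele
    pair, so both z vectors refer to the same effect allele.  ``blocks``
    holds an integer LD-block label per variant when a panel (or
    explicit labels) was supplied.
    """

    table: pd.DataFrame            # snp chrom pos a1 a2 z1 p1 z2 p2
    blocks: np.ndarray | None = None
    drop_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z1(self) -> np.ndarray:
        return self.table["z1"].to_numpy(float)

    @property
    def z2(self) -> np.ndarray:
        return self.table["z2"].to_numpy(float)

    @property
    def p1(self) -> np.ndarray:
        return self.table["p1"].to_numpy(float)

    @property
    def p2(self) -> np.ndarray:
        return self.table["p2"].to_numpy(float)

    def swapped(self) -> "HarmonizedPair":
        """The same pair with trait order reversed."""
        t = self.table.rename(columns={"z1": "z2", "z2": "z1",
                                       "p1": "p2", "p2": "p1"})
        return HarmonizedPair(t[self.table.columns], self.blocks,
                              self.drop_log)

    def subset(self, mask) -> "HarmonizedPair":
        mask = np.asarray(mask)
        blocks = self.blocks[mask] if self.blocks is not None else None
        return HarmonizedPair(self.table[mask].reset_index(drop=True),
                              blocks, self.drop_log)


def _match_alleles(a1: str, a2: str, b1: str, b2: str) -> float | None:
    """+1 same orientation, -1 swapped, None unmatched.

    Handles direct and reverse-complement matches; the caller has
    already removed strand-ambiguous pairs, for which orientation would
    be undecidable.
    """
    if (a1, a2) == (b1, b2):
        return 1.0
    if (a1, a2) == (b2, b1):
        return -1.0
    rb1, rb2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if (a1, a2) == (rb1, rb2):
        return 1.0
    if (a1, a2) == (rb2, rb1):
        return -1.0
    return None


def harmonize_pair(ss1: SummaryStats, ss2: SummaryStats,
                   panel: GenotypePanel | None = None,
                   blocks=None, prune_r2: float = 0.1,
                   window_bp: int = 1_000_000) -> HarmonizedPair:
    """Align two summary-statistic sets on (chromosome, position).

    Trait-2 z-scores are flipped when the effect/other alleles are
    swapped (including reverse-complement matches); strand-ambiguous
    (A/T, C/G) and allele-mismatched variants are dropped with logged
    reasons.  When ``panel`` is given, LD-block labels (connected
    components at r^2 > ``prune_r2`` within ``window_bp``) are attached
    for pruning; precomputed ``blocks`` labels may be passed instead.
    """
    if len(ss1) == 0 or len(ss2) == 0:
        raise ValidationError("empty summary statistics")
    t1 = ss1.table
    t2 = ss2.table
    merged = t1.merge(t2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValidationError("no variants shared between the two tables")
    merged = merged.drop_duplicates(subset=["chrom", "pos"], keep="first")

    drop = {"strand_ambiguous": 0, "allele_mismatch": 0}
    flips = np.empty(len(merged))
    keep = np.zeros(len(merged), dtype=bool)
    for k, row in enumerate(merged.itertuples()):
        pa1, pa2 = str(row.a1_1).upper(), str(row.a2_1).upper()
        qa1, qa2 = str(row.a1_2).upper(), str(row.a2_2).upper()
        if (pa1, pa2) in _AMBIGUOUS or (qa1, qa2) in _AMBIGUOUS:
            drop["strand_ambiguous"] += 1
            continue
        flip = _match_alleles(pa1, pa2, qa1, qa2)
        if flip is None:
            drop["allele_mismatch"] += 1
            continue
        flips[k] = flip
        keep[k] = True
    merged = merged[keep].reset_index(drop=True)
    flips = flips[np.flatnonzero(keep)] if keep.any() else flips[:0]

    out = pd.DataFrame({
        "snp": merged["snp_1"],
        "chrom": merged["chrom"],
        "pos": merged["pos"],
        "a1": merged["a1_1"].str.upper(),
        "a2": merged["a2_1"].str.upper(),
        "z1": merged["z_1"].to_numpy(float),
        "p1": merged["p_1"].to_numpy(float),
        "z2": merged["z_2"].to_numpy(float) * flips,
        "p2": merged["p_2"].to_numpy(float),
    })
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    labels = None
    if blocks is not None:
        labels = np.asarray(blocks)
        if labels.shape[0] != len(out):
            raise ValidationError("blocks length does not match harmonized pair")
    elif panel is not None:
        panel_labels = ld_blocks(panel, r2_threshold=prune_r2,
                                 window_bp=window_bp)
        key = panel.variants.assign(_block=panel_labels)
        joined = out.merge(key[["chrom", "pos", "_block"]],
                           on=["chrom", "pos"], how="left")
        labels = joined["_block"].to_numpy(float)
        orphan = np.isnan(labels)
        if orphan.any():            # variants absent from the panel: own blocks
            labels[orphan] = panel_labels.max() + 1 + np.arange(orphan.sum())
        labels = labels.astype(int)
    return HarmonizedPair(out, labels, drop)


def ld_blocks(panel: GenotypePanel, r2_threshold: float = 0.1,
              window_bp: int = 1_000_000) -> np.ndarray:
    """Connected components at r^2 > threshold within a physical window."""
    z = np.nan_to_num(panel.standardized())
    n = panel.n_samples
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants
    parent = np.arange(m)

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    hi = 0
    for j in range(m):
        if hi <= j:
            hi = j + 1
        while (hi < m and chrom[hi] == chrom[j]
               and pos[hi] - pos[j] <= window_bp):
            hi += 1
        if hi == j + 1:
            continue
        r = (z[:, j] @ z[:, j + 1:hi]) / n
        for off in np.flatnonzero(r * r > r2_threshold):
            ra, rb = find(j), find(j + 1 + off)
            if ra != rb:
                parent[rb] = ra
    labels = np.fromiter((find(j) for j in range(m)), dtype=int, count=m)
    _, relabeled = np.unique(labels, return_inverse=True)
    return relabeled


# ----------------------------------------------------------------------
# inflation control and region exclusion

def genomic_inflation_correct(ss: SummaryStats):
    """Divide z by sqrt(lambda_GC) when lambda_GC > 1; never deflate.

    Returns ``(corrected SummaryStats, lambda_GC)``; p-values are
    recomputed from the corrected z.
    """
    if len(ss) < 1000:
        logger.warning("genomic inflation estimated from only %d variants",
                       len(ss))
    lam = lambda_gc(z=ss.z)
    if lam <= 1.0:
        return ss, lam
    t = ss.table.copy()
    z = ss.z / np.sqrt(lam)
    t["z"] = z
    t["p"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    if "beta" in t.columns:
        t["beta"] = t["beta"] / np.sqrt(lam)
    return SummaryStats(t), lam


@dataclass
class ExclusionRegion:
    """A genomic interval removed before FDR analysis (1-based inclusive)."""

    chrom: int
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("region start must be <= end")


#: extended major histocompatibility complex, hg19
MHC = ExclusionRegion(6, 25_119_106, 33_854_733, "MHC")
#: 8p23.1 inversion region, hg19
REGION_8P23 = ExclusionRegion(8, 7_242_715, 12_483_982, "8p23.1")


def exclude_regions(obj, regions):
    """Remove variants inside any region (inclusive bounds).

    Accepts a :class:`SummaryStats` or :class:`HarmonizedPair`; returns
    ``(filtered object, number removed)``.
    """
    table = obj.table
    inside = np.zeros(len(table), dtype=bool)
    chrom = table["chrom"].to_numpy()
    pos = table["pos"].to_numpy()
    for reg in regions:
        inside |= (chrom == reg.chrom) & (pos >= reg.start) & (pos <= reg.end)
    removed = int(inside.sum())
    if isinstance(obj, SummaryStats):
        return SummaryStats(table[~inside].reset_index(drop=True)), removed
    return obj.subset(~inside), removed


# ----------------------------------------------------------------------
# pruning

def _prune_masks(blocks: np.ndarray | None, m: int, n_iter: int,
                 seed) -> list[np.ndarray]:
    """Random one-variant-per-block masks; a single full mask if no LD."""
    if n_iter <= 0 or blocks is None:
        return [np.ones(m, dtype=bool)]
    rng = np.random.default_rng(seed)
    order = np.argsort(blocks, kind="mergesort")
    sorted_blocks = blocks[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_blocks) != 0])
    sizes = np.diff(np.r_[starts, m])
    masks = []
    for _ in range(n_iter):
        pick = starts + (rng.random(starts.size) * sizes).astype(int)
        mask = np.zeros(m, dtype=bool)
        mask[order[pick]] = True
        masks.append(mask)
    return masks


# ----------------------------------------------------------------------
# conditional Q-Q

@dataclass
class ConditionalQq:
    """Stratified Q-Q curves: data only, plotting is separate."""

    curves: dict                   # cutoff -> DataFrame(nominal_nlp, ecdf_nlp)
    cutoffs: list
    empty_strata: list

    def plot(self, ax=None):
        """Conditional Q-Q plot; x = empirical -log10 quantile, y = nominal."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for c in self.cutoffs:
            if c not in self.curves:
                continue
            crv = self.curves[c]
            ax.plot(crv["ecdf_nlp"], crv["nominal_nlp"], label=f"p2 <= {c:g}")
        lim = max(crv["nominal_nlp"].max() for crv in self.curves.values())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
        ax.set_xlabel("empirical -log10 quantile")
        ax.set_ylabel("nominal -log10 p")
        ax.legend()
        return ax


def conditional_qq(pair: HarmonizedPair,
                   cutoffs=(1.0, 0.1, 0.01, 0.001),
                   grid: np.ndarray | None = None,
                   n_prune: int = 0, seed: int = 0) -> ConditionalQq:
    """Empirical CDF of trait-1 p-values within trait-2 strata.

    For each cutoff ``c`` the stratum is ``{i : p2_i <= c}``; the ECDF of
    p1 restricted to the stratum is evaluated on a -log10 nominal grid
    and averaged over random-pruning iterations.  Enrichment appears as
    an upward/leftward deflection that grows with stricter cutoffs.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    thresholds = 10.0 ** (-grid)
    p1, p2 = pair.p1, pair.p2
    masks = _prune_masks(pair.blocks, len(pair), n_prune, seed)
    curves: dict = {}
    empty = []
    for c in cutoffs:
        ecdf_sum = np.zeros_like(grid)
        used = 0
        for mask in masks:
            sel = p1[mask & (p2 <= c)]
            if sel.size == 0:
                continue
            sel_sorted = np.sort(sel)
            # ECDF of p1 <= threshold within stratum
            counts = np.searchsorted(sel_sorted, thresholds, side="right")
            ecdf_sum += counts / sel.size
            used += 1
        if used == 0:
            empty.append(c)
            continue
        ecdf = ecdf_sum / used
        with np.errstate(divide="ignore"):
            curves[c] = pd.DataFrame({
                "nominal_nlp": grid,
                "ecdf": ecdf,
                "ecdf_nlp": -np.log10(np.maximum(ecdf, 1e-12)),
            })
    if not curves:
        raise ValidationError("all conditioning strata are empty")
    return ConditionalQq(curves, list(cutoffs), empty)


# ----------------------------------------------------------------------
# conditional FDR

@dataclass
class CondFdrTable:
    """Gridded conditional FDR lookup over (-log10 p1) x (-log10 p2)."""

    grid1: np.ndarray              # -log10 p1 knots
    grid2: np.ndarray              # -log10 p2 conditioning knots
    values: np.ndarray             # shape (len(grid2), len(grid1)), in [0,1]
    n_prune: int = 0

    def interpolate(self, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        """Bilinear interpolation in -log10 space, clamped to the grid."""
        x1 = np.clip(-np.log10(p1), self.grid1[0], self.grid1[-1])
        x2 = np.clip(-np.log10(p2), self.grid2[0], self.grid2[-1])
        itp = RegularGridInterpolator((self.grid2, self.grid1), self.values)
        return itp(np.column_stack([x2, x1]))


def _exact_cfdr(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-variant counting estimate cFDR = p1 |S(p2)| / #{p1_i <= p1 in S}.

    Computed for every variant at its own (p1, p2) with "<=" ties exactly
    as the formula states, via 2-D dominance counting (Fenwick tree).
    """
    m = p1.size
    ranks1 = np.searchsorted(np.unique(p1), p1) + 1   # 1-based rank of p1
    size = int(ranks1.max())
    tree = np.zeros(size + 1, dtype=np.int64)

    def add(i):
        while i <= size:
            tree[i] += 1
            i += i & (-i)

    def query(i):
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    order = np.argsort(p2, kind="mergesort")
    out = np.empty(m)
    k = 0
    while k < m:
        # insert the whole tie-group of equal p2 before querying it ("<=")
        j = k
        while j < m and p2[order[j]] == p2[order[k]]:
            add(int(ranks1[order[j]]))
            j += 1
        stratum_size = j
        for t in range(k, j):
            i = order[t]
            cnt = query(int(ranks1[i]))
            out[i] = p1[i] * stratum_size / cnt
        k = j
    return np.clip(out, p1, 1.0)


def _grid_cfdr(p1: np.ndarray, p2: np.ndarray, masks, grid1, grid2,
               n_prune: int, min_stratum: int = 25) -> CondFdrTable:
    """Stratified counting on a -log10 grid, pooled over pruning masks.

    Stratum sizes and threshold counts are summed across the pruning
    iterations before taking the ratio, which keeps the per-stratum ECDF
    stable where a single pruned iteration would leave only a handful of
    variants.  A stratum averaging fewer than ``min_stratum`` variants
    per iteration cannot support an ECDF estimate (it typically spans
    one or two LD blocks); such strata are widened to the next coarser
    knot, exactly like empty ones.  A pooled count of zero yields the
    conservative value 1.  Monotone non-increase along both -log10 axes
    is enforced by an antitonic (pool-adjacent-violators) pass.
    """
    from scipy.optimize import isotonic_regression

    thr1 = 10.0 ** (-grid1)
    size_acc = np.zeros(grid2.size)
    count_acc = np.zeros((grid2.size, grid1.size))
    for mask in masks:
        mp1, mp2 = p1[mask], p2[mask]
        for b in range(grid2.size):       # ascending -log10 p2 = stricter
            stratum = np.sort(mp1[mp2 <= 10.0 ** (-grid2[b])])
            size_acc[b] += stratum.size
            count_acc[b] += np.searchsorted(stratum, thr1, side="right")
    floor = max(1.0, min_stratum * len(masks))
    vals = np.ones((grid2.size, grid1.size))
    last_valid = None
    for b in range(grid2.size):
        if size_acc[b] < floor and last_valid is not None:
            vals[b] = vals[last_valid]    # widen to the next coarser knot
            logger.debug("sparse stratum at -log10 p2 = %.2f (pooled %d); "
                         "widened", grid2[b], int(size_acc[b]))
            continue
        with np.errstate(divide="ignore"):
            ratio = np.where(count_acc[b] > 0,
                             thr1 * size_acc[b] / np.maximum(count_acc[b], 1),
                             1.0)
        vals[b] = np.clip(ratio, 0.0, 1.0)
        last_valid = b
    for b in range(grid2.size):
        vals[b] = isotonic_regression(vals[b], increasing=False).x
    for a in range(grid1.size):
        vals[:, a] = isotonic_regression(vals[:, a], increasing=False).x
    return CondFdrTable(grid1, grid2, np.clip(vals, 0.0, 1.0), n_prune)


class CondFdrModel:
    """Conditional FDR of trait ``which`` given the other trait.

    With no pruning and no grid (the default) the per-variant counting
    formula is evaluated exactly.  With ``n_prune`` iterations (and/or an
    explicit grid) the stratified counts are computed per random-pruning
    mask on a -log10 grid, averaged, made monotone along both axes and
    bilinearly interpolated back to each variant, then clipped to
    ``[p1, 1]``.
    """

    def __init__(self, pair: HarmonizedPair, which: int = 1,
                 grid1=None, grid2=None, n_prune: int = 0, seed: int = 0):
        if which not in (1, 2):
            raise ValidationError("which must be 1 or 2")
        self.pair = pair
        self.which = which
        self.grid1 = None if grid1 is None else np.asarray(grid1, float)
        self.grid2 = None if grid2 is None else np.asarray(grid2, float)
        self.n_prune = int(n_prune)
        self.seed = seed
        if self.n_prune > 0 and pair.blocks is None:
            raise ValidationError(
                "pruning requires LD-block labels; harmonize with a panel "
                "or pass blocks explicitly")

    def fit(self) -> "CondFdrResults":
        pair = self.pair if self.which == 1 else self.pair.swapped()
        p1, p2 = pair.p1, pair.p2
        if self.n_prune == 0 and self.grid1 is None:
            fdr = _exact_cfdr(p1, p2)
            return CondFdrResults(fdr, None, self.which)
        grid1 = DEFAULT_GRID if self.grid1 is None else self.grid1
        grid2 = DEFAULT_GRID2 if self.grid2 is None else self.grid2
        masks = _prune_masks(pair.blocks, len(pair), self.n_prune, self.seed)
        table = _grid_cfdr(p1, p2, masks, grid1, grid2, self.n_prune)
        fdr = np.clip(table.interpolate(p1, p2), p1, 1.0)
        return CondFdrResults(fdr, table, self.which)


@dataclass
class CondFdrResults:
    """Per-variant conditional FDR values (and the grid table, if built)."""

    fdr: np.ndarray
    table: CondFdrTable | None
    which: int

    def summary(self) -> str:
        n05 = int(np.sum(self.fdr < 0.05))
        return (f"conditional FDR (trait {self.which}): "
                f"{self.fdr.size} variants, {n05} below 0.05")


def cond_fdr(pair: HarmonizedPair, which: int = 1, n_prune: int = 0,
             grid1=None, grid2=None, seed: int = 0) -> CondFdrResults:
    """Functional wrapper around :class:`CondFdrModel`."""
    return CondFdrModel(pair, which, grid1, grid2, n_prune, seed).fit()


def conj_fdr(pair: HarmonizedPair, n_prune: int = 0,
             grid1=None, grid2=None, seed: int = 0) -> np.ndarray:
    """Conjunctional FDR: max of the two reciprocal conditional FDRs.

    The same pruning masks are used for both directions, so the result
    is exactly symmetric in trait order.
    """
    f1 = cond_fdr(pair, 1, n_prune, grid1, grid2, seed).fdr
    f2 = cond_fdr(pair, 2, n_prune, grid1, grid2, seed).fdr
    return np.maximum(f1, f2)


# ----------------------------------------------------------------------
# shared loci

@dataclass
class SharedLocusReport:
    """Loci jointly associated with both traits at a conjFDR threshold."""

    loci: list
    table: pd.DataFrame            # per-locus lead, conjfdr, sign
    threshold: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def same_direction_fraction(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return float(np.mean(self.table["sign"] > 0))

    def summary(self) -> str:
        return (f"{self.n_loci} shared loci at conjFDR < {self.threshold:g}; "
                f"same-direction fraction "
                f"{self.same_direction_fraction:.2f}")


def shared_loci(pair: HarmonizedPair, conjfdr: np.ndarray,
                panel: GenotypePanel, threshold: float = 0.05,
                params=None) -> SharedLocusReport:
    """Clump conjFDR values into shared loci and score effect directions.

    Significance is ``conjFDR < threshold``; the clumping hierarchy is
    the same as for p-values.  The per-locus effect direction is
    ``sign(z1 * z2)`` at the lead (minimum conjFDR) variant.
    """
    from .clumping import ClumpParams, clump_independent, define_loci

    params = params or ClumpParams()
    import dataclasses
    params = dataclasses.replace(params, p_threshold=threshold)
    frame = pair.table[["snp", "chrom", "pos", "a1", "a2"]].copy()
    frame["p"] = np.asarray(conjfdr, dtype=float)
    frame["z"] = pair.z1
    frame["n"] = 0
    pseudo = SummaryStats(frame)
    indep = clump_independent(pseudo, panel, params)
    loci = define_loci(indep, pseudo, panel, params)
    zmap = pair.table.set_index("snp")
    fdr_by_snp = frame.set_index("snp")["p"]
    rows = []
    for locus in loci:
        # lead with the smallest conjFDR among this locus' leads
        lead = min(locus.lead_ids, key=lambda s: float(fdr_by_snp.loc[s]))
        z1 = float(zmap.loc[lead, "z1"])
        z2 = float(zmap.loc[lead, "z2"])
        if z1 == 0 or z2 == 0:
            raise ValidationError(f"zero z-score at lead {lead}")
        rows.append({"lead": lead, "chrom": locus.chrom,
                     "start": locus.start, "end": locus.end,
                     "conjfdr": locus.top_p,
                     "sign": int(np.sign(z1 * z2))})
    table = pd.DataFrame(rows, columns=["lead", "chrom", "start", "end",
                                        "conjfdr", "sign"])
    return SharedLocusReport(loci, table, threshold)
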