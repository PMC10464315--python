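"""Region calling, distinct-locus counting and genomic annotation of hits.

Differentially/variably methylated regions (DMRs/VMRs) are runs of at least
3 significant CpGs with consecutive significant positions no more than 1 kb
apart, tolerating at most 3 non-significant array CpGs inside the region
span.  Distinct loci = hits - hits-in-regions + regions, i.e. every region
collapses to one locus and singletons count individually.

Annotation covers three axes: methylation-level category from untransformed
mean beta (hypo < 0.25, intermediate, hyper > 0.7 — thresholds at the male
density peaks, where intermediate methylation is the signature of an
Xa-hypomethylated / Xi-hypermethylated average), CpG-island context (CGI /
2 kb shore / non-CGI) and X-inactivation status transferred from the nearest
TSS when within 2 kb.  Enrichment of hits versus non-hit background CpGs is
tested by Pearson chi-square, switching to an exact/conditional test when
any expected cell count is below 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "call_regions",
    "count_distinct_loci",
    "meth_category",
    "annotate_cgi",
    "annotate_xci",
    "enrichment_test",
    "read_bed_intervals",
]

MAX_GAP_BP = 1000      # max distance between consecutive significant members
MAX_NONSIG = 3         # max non-significant array CpGs inside a region
MIN_MEMBERS = 3        # min significant CpGs per region

HYPO_MAX = 0.25        # mean beta below -> hypomethylated
HYPER_MIN = 0.70       # mean beta above -> hypermethylated
SHORE_BP = 2000        # CGI shore width
TSS_WINDOW_BP = 2000   # max CpG-TSS distance for XCI status transfer


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    members: tuple[int, ...]     # significant positions in the region
    n_gaps: int                  # non-significant array CpGs inside the span

    @property
    def n_members(self) -> int:
        return len(self.members)


def _check_sorted(a: np.ndarray, name: str) -> None:
    if np.any(np.diff(a) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


def call_regions(
    sig_positions,
    all_positions,
    max_gap_bp: int = MAX_GAP_BP,
    max_nonsig: int = MAX_NONSIG,
    min_members: int = MIN_MEMBERS,
) -> list[Region]:
    """Greedy left-to-right region caller.

    A region grows while the next significant position is within
    ``max_gap_bp`` of the previous member and the running count of
    intervening non-significant array CpGs stays at most ``max_nonsig``;
    it is emitted when it holds at least ``min_members`` significant CpGs.
    Regions are disjoint and maximal under these rules.
    """
    sig = np.asarray(sig_positions, dtype=np.int64)
    allp = np.asarray(all_positions, dtype=np.int64)
    if sig.size:
        _check_sorted(sig, "sig_positions")
    if allp.size:
        _check_sorted(allp, "all_positions")
    if not np.isin(sig, allp).all():
        raise ValueError("sig_positions must be a subset of all_positions")

    sig_set = set(sig.tolist())
    regions: list[Region] = []
    i = 0
    while i < sig.size:
        # maximal right extension from start i (constraints are monotone,
        # so greedy extension reaches the unique maximal end for this start)
        members = [int(sig[i])]
        gaps = 0
        j = i + 1
        while j < sig.size:
            nxt, prev = int(sig[j]), members[-1]
            if nxt - prev > max_gap_bp:
                break
            between = allp[(allp > prev) & (allp < nxt)]
            n_between = sum(1 for p in between.tolist() if p not in sig_set)
            if gaps + n_between > max_nonsig:
                break
            gaps += n_between
            members.append(nxt)
            j += 1
        if len(members) >= min_members:
            regions.append(Region(members[0], members[-1], tuple(members), gaps))
            i = j
        else:
            i += 1
    return regions


def count_distinct_loci(n_hits: int, regions: list[Region], hit_positions=None) -> int:
    """hits - (hits inside regions) + (number of regions).

    If ``hit_positions`` is given, every region member must be one of them.
    """
    if hit_positions is not None:
        hits = set(int(p) for p in hit_positions)
        for r in regions:
            if not set(r.members) <= hits:
                raise ValueError("region member is not a hit")
    in_regions = sum(r.n_members for r in regions)
    if in_regions > n_hits:
        raise ValueError("more region members than hits")
    return n_hits - in_regions + len(regions)


def meth_category(mean_beta: float, hypo_max: float = HYPO_MAX, hyper_min: float = HYPER_MIN) -> str:
    """Three-way methylation-level category from untransformed mean beta."""
    if np.isnan(mean_beta):
        return "unknown"
    if mean_beta < hypo_max:
        return "hypo"
    if mean_beta > hyper_min:
        return "hyper"
    return "intermediate"


def read_bed_intervals(path) -> np.ndarray:
    """Read a BED interval track (0-based half-open) into 1-based inclusive
    (start, end) rows, merged if overlapping."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((int(f[1]) + 1, int(f[2])))
    return merge_intervals(np.array(rows, dtype=np.int64).reshape(-1, 2))


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def annotate_cgi(pos, cgi_intervals: np.ndarray) -> np.ndarray:
    """CGI / shore / nonCGI class for 1-based positions.

    ``cgi_intervals``: merged 1-based inclusive (start, end) array.  A
    position inside an island is CGI regardless of any other island's shore;
    within SHORE_BP of an island edge it is shore; otherwise nonCGI.
    """
    p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    if (p < 0).any():
        raise ValueError("positions must be non-negative")
    out = np.full(p.shape, "nonCGI", dtype=object)
    if cgi_intervals.size == 0:
        return out if np.ndim(pos) else out[0]
    starts, ends = cgi_intervals[:, 0], cgi_intervals[:, 1]
    idx = np.searchsorted(starts, p, side="right") - 1
    inside = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
    # shore: within SHORE_BP of the nearest island edge
    near_prev = (idx >= 0) & (p - ends[np.clip(idx, 0, None)] <= SHORE_BP)
    nxt = np.clip(idx + 1, 0, len(starts) - 1)
    near_next = (idx + 1 < len(starts)) & (starts[nxt] - p <= SHORE_BP)
    out[near_prev | near_next] = "shore"
    out[inside] = "CGI"
    return out if np.ndim(pos) else out[0]


def annotate_xci(pos, tss_positions, tss_status, window_bp: int = TSS_WINDOW_BP):
    """XCI status from the nearest TSS within ``window_bp``; ties broken to
    the lower TSS coordinate; beyond the window -> "unannotated"."""
    tss = np.asarray(tss_positions, dtype=np.int64)
    if tss.size == 0:
        raise ValueError("tss table is empty")
    order = np.argsort(tss, kind="mergesort")
    tss = tss[order]
    status = np.asarray(tss_status, dtype=object)[order]
    p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    i = np.searchsorted(tss, p)
    left = np.clip(i - 1, 0, tss.size - 1)
    right = np.clip(i, 0, tss.size - 1)
    dl = np.abs(p - tss[left])
    dr = np.abs(tss[right] - p)
    # tie -> lower coordinate, i.e. the left candidate wins on equality
    pick = np.where(dl <= dr, left, right)
    dist = np.minimum(dl, dr)
    out = np.where(dist <= window_bp, status[pick], "unannotated").astype(object)
    return out if np.ndim(pos) else out[0]


def enrichment_test(
    hit_counts, background_counts, seed: int = 0, n_mc: int = 20000
) -> tuple[float, float, str]:
    """Hits-vs-background contingency test over annotation categories.

    Pearson chi-square by default; if any expected cell count is < 5, a 2x2
    table uses Fisher's exact test and a larger table uses a Monte-Carlo
    conditional test (random tables with fixed margins, chi-square
    statistic, seeded).  Returns (statistic, p, method).
    """
    hit = np.asarray(hit_counts, dtype=np.int64)
    bg = np.asarray(background_counts, dtype=np.int64)
    if hit.shape != bg.shape or hit.size < 2:
        raise ValueError("need matching count vectors over >= 2 categories")
    table = np.vstack([hit, bg])
    if table.sum() == 0:
        raise ValueError("zero-total contingency table")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi-square"
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        stat, _, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "fisher"
    # conditional Monte-Carlo for r x c with small expected counts
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(n_mc, random_state=rng)
    exceed = 0
    for t in draws:
        s, _, _, _ = stats.chi2_contingency(t, correction=False)
        if s >= stat - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_mc + 1)
    return float(stat), float(p), "mc-exact"
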