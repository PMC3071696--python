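"""Region-to-gene assignment, peak-class gene classification, and
region-set / track comparisons.

Assignment rule: a bound region maps to every gene it overlaps by at least
one bp; a region overlapping nothing maps to the single gene minimizing the
distance from the region centre to the nearer gene end.  Strand is ignored.
Genes are classified by peak multiplicity: a single-peak gene has exactly
one 10%-FDR peak and no other peak up to 25% FDR; a multiple-peak gene has
at least four 10%-FDR peaks; everything else is unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hoxchip.peaks import BoundRegion
from hoxchip.signal import RatioTrack
from hoxchip.synthetic import GeneModel


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    region_id: str
    assignment_mode: str  # "overlap" | "nearest"
    distance_bp: int

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")
        if self.assignment_mode not in ("overlap", "nearest"):
            raise ValueError(f"bad assignment mode {self.assignment_mode!r}")


def _region_id(region: BoundRegion, i: int) -> str:
    return region.region_id or f"region{i:05d}"


def assign_regions_to_genes(
    regions: list[BoundRegion],
    genes: list[GeneModel],
    blacklist: set[str] | None = None,
) -> list[GeneAssignment]:
    """Map each bound region to its overlapping gene(s) or nearest gene.

    Overlap (>= 1 bp shared) assigns all overlapping genes.  Otherwise the
    region's centre is compared with both ends of every same-chromosome
    gene and the gene with the smallest end distance wins; ties break by
    smaller gene start, then lexicographic gene id.  Blacklisted gene ids
    (e.g. tandem histone repeats) are removed after assignment, so a region
    whose nearest gene is blacklisted yields no assignment rather than
    being reassigned.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))

    assignments: list[GeneAssignment] = []
    for i, region in enumerate(regions):
        rid = _region_id(region, i)
        glist = by_chrom.get(region.chrom)
        if not glist:
            raise ValueError(f"no genes on chromosome {region.chrom!r}")
        overlapping = [g for g in glist
                       if g.start < region.end and region.start < g.end]
        if overlapping:
            for g in overlapping:
                assignments.append(GeneAssignment(g.gene_id, rid, "overlap", 0))
        else:
            center = (region.start + region.end) // 2
            best = min(
                glist,
                key=lambda g: (min(abs(center - g.start), abs(center - g.end)),
                               g.start, g.gene_id),
            )
            dist = min(abs(center - best.start), abs(center - best.end))
            assignments.append(GeneAssignment(best.gene_id, rid, "nearest", int(dist)))
    if blacklist:
        assignments = [a for a in assignments if a.gene_id not in blacklist]
    return assignments


def unique_genes(assignments: list[GeneAssignment]) -> list[str]:
    return sorted({a.gene_id for a in assignments})


def classify_peak_genes(
    regions: list[BoundRegion],
    genes: list[GeneModel],
    blacklist: set[str] | None = None,
) -> pd.DataFrame:
    """Classify genes by peak multiplicity across the 10% and 25% FDR tiers.

    Uses the standard assignment rule at each tier (tier sets are nested,
    so every 10% peak is also a 25% peak).  Returns a DataFrame with
    columns gene_id, n_peaks_10, n_peaks_25, peak_class over all genes with
    at least one 25%-tier peak.
    """
    at10 = [r for r in regions if r.fdr_tier is not None and r.fdr_tier <= 10]
    at25 = [r for r in regions if r.fdr_tier is not None and r.fdr_tier <= 25]
    count10: dict[str, int] = {}
    count25: dict[str, int] = {}
    for rs, counts in ((at10, count10), (at25, count25)):
        if rs:
            for a in assign_regions_to_genes(rs, genes, blacklist):
                counts[a.gene_id] = counts.get(a.gene_id, 0) + 1
    rows = []
    for gid in sorted(set(count10) | set(count25)):
        n10 = count10.get(gid, 0)
        n25 = count25.get(gid, 0)
        if n10 == 1 and n25 == 1:
            cls = "single"
        elif n10 >= 4:
            cls = "multiple"
        else:
            cls = "unassigned"
        rows.append((gid, n10, n25, cls))
    return pd.DataFrame(rows, columns=["gene_id", "n_peaks_10", "n_peaks_25", "peak_class"])


def region_set_overlap(
    set_a: list[BoundRegion],
    set_b: list[BoundRegion],
    min_overlap_bp: int = 100,
):
    """Count regions of A overlapped by >= min_overlap_bp with some region of B.

    Returns (count, fraction of A overlapped, matched (a_index, b_index)
    pairs).  The 100 bp default is the conventional threshold for calling
    two bound regions shared between ChIP datasets.
    """
    pairs = []
    hit = np.zeros(len(set_a), dtype=bool)
    b_by_chrom: dict[str, list[tuple[int, BoundRegion]]] = {}
    for j, b in enumerate(set_b):
        b_by_chrom.setdefault(b.chrom, []).append((j, b))
    for blist in b_by_chrom.values():
        blist.sort(key=lambda t: t[1].start)
    for i, a in enumerate(set_a):
        for j, b in b_by_chrom.get(a.chrom, []):
            if b.start >= a.end:
                break
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_overlap_bp:
                hit[i] = True
                pairs.append((i, j))
    count = int(hit.sum())
    fraction = count / len(set_a) if set_a else float("nan")
    return count, fraction, pairs


def track_correlation(track_a: RatioTrack, track_b: RatioTrack) -> float:
    """Pearson correlation of two tracks over their common probe positions."""
    key_a = pd.MultiIndex.from_arrays([track_a.chroms, track_a.positions])
    key_b = pd.MultiIndex.from_arrays([track_b.chroms, track_b.positions])
    sa = pd.Series(track_a.score, index=key_a)
    sb = pd.Series(track_b.score, index=key_b)
    common = sa.index.intersection(sb.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 common probe positions")
    x = sa.loc[common].to_numpy()
    y = sb.loc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance track; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def write_assignments_tsv(assignments: list[GeneAssignment], path,
                          tier: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tregion_id\tmode\tdistance_bp\ttier\n")
        for a in assignments:
            fh.write(f"{a.gene_id}\t{a.region_id}\t{a.assignment_mode}\t"
                     f"{a.distance_bp}\t{tier if tier is not None else 'NA'}\n")
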