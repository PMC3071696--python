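"""Empirical-FDR peak calling on smoothed enrichment tracks.

Candidate bound regions are maximal runs of probes whose smoothed score
clears a threshold; the false-discovery rate attached to a peak height h is
the average number of null peaks at least as high, divided by the observed
number, with the null built by balanced replicate label swaps between the
specific and control conditions (the swap preserves per-probe affinity
structure).  Regions are labelled with the most stringent FDR tier
(1/5/10/25%) their height satisfies; tiers are nested by construction.

The FDR machinery is a reconstruction of an unpublished tiling-array
peak-caller's behaviour and is tagged as such in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from hoxchip._rng import substream
from hoxchip.signal import (ProbePanel, RatioTrack, SmoothingConfig,
                            log2_ratio, smooth_trimmed_mean)

TIERS = (1, 5, 10, 25)


@dataclass(frozen=True)
class BoundRegion:
    """A called enriched interval (0-based half-open) with its summit."""

    chrom: str
    start: int
    end: int
    summit: int
    height: float
    fdr_tier: int | None = None
    region_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NullEnsemble:
    """Peak heights from null (label-swapped or permuted) tracks."""

    n_null: int
    null_heights: list[np.ndarray]  # one array of peak heights per iteration
    construction: str
    seed: int

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if len(self.null_heights) != self.n_null:
            raise ValueError("one height array per null iteration required")

    @property
    def all_heights(self) -> np.ndarray:
        if not self.null_heights:
            return np.array([])
        return np.concatenate([np.asarray(h, dtype=float) for h in self.null_heights]) \
            if any(len(h) for h in self.null_heights) else np.array([])


def _estimate_spacing(positions: np.ndarray) -> int:
    if positions.size < 2:
        return 36
    return int(np.median(np.diff(positions)))


def find_candidate_regions(track: RatioTrack, score_threshold: float,
                           max_gap_bp: int | None = None) -> list[BoundRegion]:
    """Scan a smoothed track for maximal above-threshold probe runs.

    Runs whose flanking probes are separated by at most ``max_gap_bp``
    (default twice the probe spacing) are merged, tolerating single missing
    probes without fusing distinct peaks.  A region spans its first to last
    probe plus one probe spacing; the summit is the leftmost maximal probe.
    """
    regions: list[BoundRegion] = []
    for chrom in pd.unique(track.chroms):
        sel = np.flatnonzero(track.chroms == chrom)
        pos = track.positions[sel]
        sc = track.score[sel]
        spacing = _estimate_spacing(pos)
        gap = 2 * spacing if max_gap_bp is None else max_gap_bp
        above = np.flatnonzero(sc >= score_threshold)
        if above.size == 0:
            continue
        # split indices where the bp gap between consecutive hits exceeds gap
        breaks = np.flatnonzero(np.diff(pos[above]) > gap)
        for run in np.split(above, breaks + 1):
            run_sc = sc[run]
            top = int(run[np.argmax(run_sc)])  # argmax is leftmost on ties
            regions.append(BoundRegion(
                chrom=str(chrom),
                start=int(pos[run[0]]),
                end=int(pos[run[-1]]) + spacing,
                summit=int(pos[top]),
                height=float(run_sc.max()),
            ))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _balanced_swaps(n_spec: int, n_ctrl: int):
    """All non-identity balanced label swaps between two replicate groups."""
    swaps = []
    for k in range(1, min(n_spec, n_ctrl) + 1):
        for s in combinations(range(n_spec), k):
            for c in combinations(range(n_ctrl), k):
                swaps.append((s, c))
    return swaps


def build_null_ensemble(
    specific: ProbePanel,
    control: ProbePanel,
    n_null: int,
    smoothing: SmoothingConfig,
    score_threshold: float,
    seed: int,
    max_gap_bp: int | None = None,
) -> NullEnsemble:
    """Build the peak-height null by balanced replicate label swaps.

    Each iteration exchanges a random balanced subset of replicates between
    the specific and control panels, reruns ratio + smoothing + candidate
    finding, and records all resulting peak heights.  With fewer than two
    replicates per condition, label swapping is impossible and the raw
    log2-ratio scores are instead permuted within each chromosome.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = substream(seed, "null-ensemble")
    can_swap = specific.n_replicates >= 2 and control.n_replicates >= 2
    heights: list[np.ndarray] = []
    if can_swap:
        swaps = _balanced_swaps(specific.n_replicates, control.n_replicates)
        replace = n_null > len(swaps)
        chosen = rng.choice(len(swaps), size=n_null, replace=replace)
        for idx in chosen:
            s_idx, c_idx = swaps[int(idx)]
            spec_m = specific.intensities.copy()
            ctrl_m = control.intensities.copy()
            spec_m[list(s_idx)], ctrl_m[list(c_idx)] = \
                control.intensities[list(c_idx)], specific.intensities[list(s_idx)]
            null_spec = ProbePanel(specific.chroms, specific.positions, spec_m, "specific")
            null_ctrl = ProbePanel(control.chroms, control.positions, ctrl_m, "control")
            track = smooth_trimmed_mean(log2_ratio(null_spec, null_ctrl), smoothing)
            peaks = find_candidate_regions(track, score_threshold, max_gap_bp)
            heights.append(np.array([p.height for p in peaks]))
        construction = "balanced-label-swap"
    else:
        raw = log2_ratio(specific, control)
        for _ in range(n_null):
            perm = raw.score.copy()
            for chrom in pd.unique(raw.chroms):
                sel = np.flatnonzero(raw.chroms == chrom)
                perm[sel] = rng.permutation(perm[sel])
            track = smooth_trimmed_mean(
                RatioTrack(raw.chroms, raw.positions, perm), smoothing)
            peaks = find_candidate_regions(track, score_threshold, max_gap_bp)
            heights.append(np.array([p.height for p in peaks]))
        construction = "within-chromosome-permutation"
    return NullEnsemble(n_null, heights, construction, seed)


def assign_fdr_tiers(
    candidates: list[BoundRegion],
    ensemble: NullEnsemble,
    tiers: tuple[int, ...] = TIERS,
) -> list[BoundRegion]:
    """Attach empirical FDR tiers to candidate regions.

    For each observed peak height h, ``FDR(h)`` is the mean per-iteration
    count of null peaks >= h divided by the observed count of peaks >= h,
    made non-increasing in h by a cumulative minimum.  Each region is
    labelled with the most stringent tier whose threshold its height meets;
    regions failing the loosest tier are dropped.  Tier sets are nested.
    """
    if not candidates:
        return []
    tiers = tuple(sorted(tiers))
    null = ensemble.all_heights
    obs = np.array([r.height for r in candidates])
    hs = np.sort(np.unique(obs))  # ascending candidate thresholds
    # counts at threshold h: observed and mean null peaks with height >= h
    n_obs = obs.size - np.searchsorted(np.sort(obs), hs, side="left")
    n_null = (null.size - np.searchsorted(np.sort(null), hs, side="left")) / ensemble.n_null \
        if null.size else np.zeros_like(hs)
    fdr = np.minimum(n_null / n_obs, 1.0)
    # enforce FDR non-increasing in h: a stricter threshold never reports a
    # worse rate than a looser one (running minimum over ascending h)
    fdr = np.minimum.accumulate(fdr)

    thresholds: dict[int, float] = {}
    for tier in tiers:
        ok = np.flatnonzero(fdr <= tier / 100.0)
        if ok.size:
            thresholds[tier] = float(hs[ok[0]])  # smallest h achieving the tier

    out: list[BoundRegion] = []
    for i, r in enumerate(candidates):
        tier_label = None
        for tier in tiers:  # most stringent first
            if tier in thresholds and r.height >= thresholds[tier]:
                tier_label = tier
                break
        if tier_label is not None:
            out.append(BoundRegion(r.chrom, r.start, r.end, r.summit, r.height,
                                   tier_label, region_id=f"region{i:05d}"))
    return out


def regions_at_tier(regions: list[BoundRegion], tier: int) -> list[BoundRegion]:
    """Regions called at or below (more stringent than) the given tier."""
    return [r for r in regions if r.fdr_tier is not None and r.fdr_tier <= tier]


# ---------------------------------------------------------------------------
# BED I/O (BED6+2: summit and FDR tier as extra columns)
# ---------------------------------------------------------------------------

def write_regions_bed(regions: list[BoundRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.region_id or f"region{i:05d}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t"
                     f"{int(round(r.height * 100))}\t.\t{r.summit}\t"
                     f"{r.fdr_tier if r.fdr_tier is not None else 'NA'}\n")


def read_regions_bed(path) -> list[BoundRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}: malformed BED6+2 line {lineno}")
            tier = None if parts[7] == "NA" else int(parts[7])
            regions.append(BoundRegion(parts[0], int(parts[1]), int(parts[2]),
                                       int(parts[6]), float(parts[4]) / 100.0,
                                       tier, region_id=parts[3]))
    return regions
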