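"""Probe-level normalization and the windowed log2-ratio track.

The processing chain mirrors standard tiling-array practice: all replicates
(specific and control together) are median scaled and quantile normalized
against each other, the per-probe log2 ratio of replicate means is formed,
and the ratio track is smoothed with a sliding window of trimmed means
(675 bp default).  Tracks round-trip through the three-column ``.sgr``
browser format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ProbePanel:
    """Replicate intensity matrix on a tiled probe grid.

    ``chroms``/``positions`` are parallel per-probe arrays (positions are
    probe starts, 0-based, strictly increasing within each chromosome);
    ``intensities`` is a replicate x probe matrix of positive values.
    """

    chroms: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.positions.size:
            raise ValueError("intensity matrix does not match probe count")
        if (self.intensities <= 0).any():
            raise ValueError("intensities must be strictly positive")
        for chrom in pd.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_probes(self) -> int:
        return self.positions.size

    def copy(self) -> "ProbePanel":
        return ProbePanel(self.chroms.copy(), self.positions.copy(),
                          self.intensities.copy(), self.condition)


@dataclass(frozen=True)
class SmoothingConfig:
    """Sliding-window trimmed-mean smoothing parameters.

    ``window_bp`` is a bp-defined window centred on each probe position,
    half-open ``[p - w//2, p + (w - w//2))``; ``trim_fraction`` is removed
    from each tail (``floor(trim_fraction * n)`` values) before averaging.
    """

    window_bp: int = 675
    trim_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


@dataclass
class RatioTrack:
    """Per-probe log2 enrichment scores (the .sgr payload)."""

    chroms: np.ndarray
    positions: np.ndarray
    score: np.ndarray
    smoothing: SmoothingConfig | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != self.positions.shape:
            raise ValueError("score/position length mismatch")
        if not np.isfinite(self.score).all():
            raise ValueError("scores must be finite")

    @property
    def n_probes(self) -> int:
        return self.positions.size


def median_scale(panels: list[ProbePanel], target_median: float | None = None) -> list[ProbePanel]:
    """Multiplicatively scale every replicate to a common median.

    The default target is the grand median of all replicate medians across
    all supplied panels, so the joint intensity scale is preserved.
    """
    if not panels:
        raise ValueError("no panels supplied")
    medians = [np.median(row) for p in panels for row in p.intensities]
    if any(m == 0 for m in medians):
        raise ValueError("replicate with zero median cannot be scaled")
    if target_median is None:
        target_median = float(np.median(medians))
    if target_median <= 0:
        raise ValueError("target median must be positive")
    out = []
    i = 0
    for p in panels:
        q = p.copy()
        for r in range(q.n_replicates):
            q.intensities[r] *= target_median / medians[i]
            i += 1
        out.append(q)
    return out


def quantile_normalize(panels: list[ProbePanel]) -> list[ProbePanel]:
    """Quantile normalize all replicates of all panels against each other.

    After normalization every replicate has the identical sorted value
    vector (the across-replicate mean of sorted values); ranks within each
    replicate are preserved.  Idempotent.
    """
    if not panels:
        raise ValueError("no panels supplied")
    n = panels[0].n_probes
    for p in panels:
        if p.n_probes != n:
            raise ValueError("panels differ in probe count; cannot quantile normalize")
    rows = np.vstack([p.intensities for p in panels])
    order = np.argsort(rows, axis=1, kind="stable")
    sorted_rows = np.take_along_axis(rows, order, axis=1)
    ref = sorted_rows.mean(axis=0)
    normed = np.empty_like(rows)
    for r in range(rows.shape[0]):
        normed[r, order[r]] = ref
    out = []
    i = 0
    for p in panels:
        q = p.copy()
        q.intensities = normed[i:i + p.n_replicates]
        i += p.n_replicates
        out.append(q)
    return out


def log2_ratio(specific: ProbePanel, control: ProbePanel) -> RatioTrack:
    """Per-probe log2 of (mean specific IP / mean control IP)."""
    if specific.n_probes != control.n_probes or \
            (specific.chroms != control.chroms).any() or \
            (specific.positions != control.positions).any():
        raise ValueError("specific and control panels are on different probe grids")
    mean_s = specific.intensities.mean(axis=0)
    mean_c = control.intensities.mean(axis=0)
    if (mean_c == 0).any():
        raise ValueError("zero control mean at some probe")
    return RatioTrack(specific.chroms, specific.positions, np.log2(mean_s / mean_c))


def _trimmed_mean(values: np.ndarray, trim_fraction: float) -> float:
    n = values.size
    k = int(trim_fraction * n)
    if 2 * k >= n:
        k = (n - 1) // 2
    v = np.sort(values)
    return float(v[k:n - k].mean())


def smooth_trimmed_mean(track: RatioTrack, cfg: SmoothingConfig | None = None) -> RatioTrack:
    """Smooth a ratio track with a bp-defined sliding trimmed-mean window.

    For each probe p the output is the trimmed mean of the raw scores of
    all probes in ``[p - w//2, p + (w - w//2))`` on the same chromosome;
    the window always contains at least the probe itself.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    w = cfg.window_bp
    out = np.empty_like(track.score)
    for chrom in pd.unique(track.chroms):
        sel = np.flatnonzero(track.chroms == chrom)
        pos = track.positions[sel]
        sc = track.score[sel]
        lo = np.searchsorted(pos, pos - w // 2, side="left")
        hi = np.searchsorted(pos, pos + (w - w // 2), side="left")
        smoothed = np.empty_like(sc)
        for i in range(pos.size):
            smoothed[i] = _trimmed_mean(sc[lo[i]:hi[i]], cfg.trim_fraction)
        out[sel] = smoothed
    return RatioTrack(track.chroms, track.positions, out, smoothing=cfg)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_sgr(track: RatioTrack, path) -> None:
    """Write a track as .sgr (chrom TAB position TAB score).

    Positions are written 1-based (browser convention); scores with six
    decimal places.
    """
    with open(path, "w") as fh:
        for chrom, pos, sc in zip(track.chroms, track.positions, track.score):
            fh.write(f"{chrom}\t{pos + 1}\t{sc:.6f}\n")


def read_sgr(path) -> RatioTrack:
    """Read an .sgr file back into a RatioTrack (positions to 0-based)."""
    chroms, positions, scores = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed .sgr line {lineno}: {line!r}")
            try:
                chroms.append(parts[0])
                positions.append(int(parts[1]) - 1)
                scores.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed .sgr line {lineno}: {line!r}") from exc
    return RatioTrack(np.array(chroms), np.array(positions), np.array(scores))


def write_intensity_tsv(panel: ProbePanel, path) -> None:
    """TSV with header chrom, position, rep1..repN (positions 0-based)."""
    cols = {"chrom": panel.chroms, "position": panel.positions}
    for r in range(panel.n_replicates):
        cols[f"rep{r + 1}"] = panel.intensities[r]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_intensity_tsv(path, condition: str) -> ProbePanel:
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols or "chrom" not in df.columns or "position" not in df.columns:
        raise ValueError(f"{path}: expected columns chrom, position, rep1..repN")
    return ProbePanel(df["chrom"].to_numpy(), df["position"].to_numpy(),
                      df[rep_cols].to_numpy().T, condition)


def normalize_panels(specific: ProbePanel, control: ProbePanel,
                     target_median: float | None = None) -> tuple[ProbePanel, ProbePanel]:
    """Median scale then quantile normalize both conditions jointly."""
    scaled = median_scale([specific, control], target_median)
    normed = quantile_normalize(scaled)
    return normed[0], normed[1]
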