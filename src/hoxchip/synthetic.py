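"""Ground-truth simulator for ChIP-tiling-array experiments.

Generates every input the analysis pipeline consumes: a small
multi-chromosome genome with non-overlapping gene models, chromatin
accessibility domains bounded by simulated insulator sites, planted bound
regions (isolated peaks and multi-peak clusters), tiled-probe intensity
panels for specific and control immunoprecipitations, and
differential-expression labels with a controllable repression bias among
bound genes.

Binding can be restricted to accessible (ON) domains, emulating the
exclusion of transcription-factor binding from Polycomb-silenced chromatin:
in constrained mode no planted region intersects an OFF domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hoxchip._rng import substream

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic genome.

    Parameters
    ----------
    chromosomes : list of (name, length_bp)
    base_composition : probabilities of A, C, G, T; must sum to 1.
    seed : master seed for sequence and gene placement.
    gene_density_per_kb : expected genes per kb of chromosome.
    gene_length_mean_bp, gene_length_sigma : log-normal gene-length model
        (mean on the natural scale; sigma on the log scale).  The default
        mean of 5,600 bp matches a compact invertebrate genome average.
    """

    chromosomes: list[tuple[str, int]]
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    gene_density_per_kb: float = 0.1
    gene_length_mean_bp: float = 5600.0
    gene_length_sigma: float = 0.8

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length {length}")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or (comp > 1).any():
            raise ValueError("base_composition must be 4 probabilities in [0,1]")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(f"base_composition sums to {comp.sum()}, not 1")


@dataclass(frozen=True)
class GeneModel:
    """A gene as a 0-based half-open interval with a strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AccessibilityDomain:
    """A chromatin domain, ON (accessible) or OFF (silenced).

    Domains tile each chromosome without overlap; their boundaries are the
    simulated insulator positions.
    """

    chrom: str
    start: int
    end: int
    state: str  # "ON" | "OFF"

    def __post_init__(self) -> None:
        if self.state not in ("ON", "OFF"):
            raise ValueError(f"state must be ON or OFF, got {self.state!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid domain interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class TrueRegion:
    """A planted bound region: the simulator's ground truth.

    The enrichment kernel is centred at ``center`` and reaches zero at
    ``center ± half_width``; ``enrichment_fold`` is the fold enrichment at
    the kernel maximum.  Cluster members share a ``cluster_id``.
    """

    chrom: str
    center: int
    half_width: int
    enrichment_fold: float
    cluster_id: str | None = None
    planted_motif: str | None = None
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width


@dataclass(frozen=True)
class ArrayConfig:
    """Tiling-array design and noise model.

    25-mer probes tiled every ``spacing_bp`` (36 bp default, approximating
    a genome tiling array 2.0 design), three biological replicates per
    condition.  Background intensity for probe p in replicate r is
    ``exp(mu_log + a_p + e_pr)`` with a probe affinity term ``a_p`` shared
    across replicates and conditions (the probe hybridizes identically in
    both IPs) and independent replicate noise ``e_pr``; quantile
    normalization exists to absorb exactly this heavy-tailed,
    probe-correlated structure.
    """

    spacing_bp: int = 36
    probe_length: int = 25
    n_replicates: int = 3
    mu_log: float = math.log(100.0)
    sigma_affinity: float = 0.5
    sigma_replicate: float = 0.3
    kernel: str = "triangular"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.spacing_bp <= 0:
            raise ValueError("probe spacing must be positive")
        if self.n_replicates < 1:
            raise ValueError("at least one replicate required")
        if self.kernel not in ("triangular", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class PlantConfig:
    """How many regions to plant and where.

    ``n_single`` isolated peaks are placed near one gene each;
    ``n_clusters`` clusters of ``cluster_size`` (>= 4) peaks are placed
    within the span of one long gene each, emulating multiple-peak genes.
    In ``constrained`` mode every region must lie wholly inside an ON
    accessibility domain.
    """

    n_single: int = 40
    n_clusters: int = 5
    cluster_size: int = 4
    half_width_bp: int = 500
    fold_min: float = 6.0
    fold_max: float = 10.0
    constrained: bool = True
    max_tries: int = 200
    # centre-to-centre separation of cluster peaks, in half-widths; 3 leaves
    # a full kernel-free trough between neighbours so peaks stay resolvable
    cluster_sep_half_widths: float = 3.0

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_clusters < 0:
            raise ValueError("region counts must be nonnegative")
        if self.n_clusters > 0 and self.cluster_size < 4:
            raise ValueError("cluster_size must be >= 4")
        if self.fold_min < 1 or self.fold_max < self.fold_min:
            raise ValueError("need 1 <= fold_min <= fold_max")


@dataclass(frozen=True)
class BiasConfig:
    """Differential-expression label model.

    A bound gene is 'regulated' with probability ``frac_regulated_bound``
    (unbound genes with ``frac_regulated_unbound``); regulated genes are
    labelled ``down`` with the conditional probability for their binding
    status, otherwise ``up``.  Unregulated genes are labelled ``none``.
    Defaults reproduce a repression-biased study design: ~76% of regulated
    bound genes down versus ~62% of regulated unbound genes, pooling to
    roughly 65% down overall.
    """

    frac_regulated_bound: float = 0.8
    frac_regulated_unbound: float = 0.5
    p_down_bound: float = 0.76
    p_down_unbound: float = 0.62

    def __post_init__(self) -> None:
        for name in ("frac_regulated_bound", "frac_regulated_unbound",
                     "p_down_bound", "p_down_unbound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


class PlacementError(RuntimeError):
    """Raised when requested features cannot be placed in the genome."""


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def generate_genome(spec: GenomeSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate random chromosome sequences and non-overlapping genes.

    Gene counts per chromosome follow ``gene_density_per_kb``; lengths are
    log-normal.  Genes are laid out left to right with random gaps drawn by
    stick-breaking over the residual space, which guarantees no overlaps.

    Returns
    -------
    (sequences, genes) : chromosome name -> sequence string, and the gene
    models sorted by (chrom, start).  Deterministic for a fixed spec.
    """
    rng = substream(spec.seed, "genome")
    comp = np.asarray(spec.base_composition, dtype=float)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    mu = math.log(spec.gene_length_mean_bp) - spec.gene_length_sigma**2 / 2
    for chrom, length in spec.chromosomes:
        seq = rng.choice(BASES, size=length, p=comp)
        sequences[chrom] = "".join(seq)
        n_genes = int(round(spec.gene_density_per_kb * length / 1000))
        if n_genes == 0:
            continue
        lengths = np.round(rng.lognormal(mu, spec.gene_length_sigma, n_genes)).astype(int)
        lengths = np.clip(lengths, 200, None)
        slack = length - int(lengths.sum())
        if slack < 0:
            raise PlacementError(
                f"cannot place {n_genes} genes totalling {lengths.sum()} bp "
                f"on {chrom} ({length} bp)"
            )
        # n_genes+1 gaps partitioning the slack uniformly at random
        cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
        gaps = np.diff(np.concatenate(([0], cuts, [slack])))
        pos = 0
        for glen, gap in zip(lengths, gaps[:-1]):
            start = pos + int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gene_no:05d}", chrom, start, start + int(glen), strand))
            gene_no += 1
            pos = start + int(glen)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return sequences, genes


def generate_accessibility(
    chrom_lengths: dict[str, int],
    n_domains: int,
    fraction_off: float,
    seed: int,
) -> list[AccessibilityDomain]:
    """Partition each chromosome into accessibility domains.

    Each chromosome is cut at ``n_domains - 1`` random insulator positions
    into ``n_domains`` domains.  OFF states are then assigned to a random
    subset of domains chosen so the realized OFF length fraction tracks
    ``fraction_off`` (a shuffled greedy fill toward the target length),
    keeping the silenced share of the genome stable across seeds instead
    of fluctuating with the heavy-tailed domain-length distribution.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    if not 0.0 <= fraction_off <= 1.0:
        raise ValueError("fraction_off must be in [0,1]")
    rng = substream(seed, "accessibility")
    intervals: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        k = min(n_domains, length)  # degenerate tiny chromosomes
        if k > 1:
            cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = np.concatenate(([0], cuts, [length]))
        for i in range(k):
            intervals.append((chrom, int(bounds[i]), int(bounds[i + 1])))
    total = sum(e - s for _, s, e in intervals)
    target = fraction_off * total
    order = rng.permutation(len(intervals))
    lengths = np.array([intervals[i][2] - intervals[i][1] for i in order])
    cumulative = np.concatenate(([0.0], np.cumsum(lengths)))
    k_best = int(np.argmin(np.abs(cumulative - target)))
    states = [False] * len(intervals)
    for idx in order[:k_best]:
        states[idx] = True
    return [AccessibilityDomain(c, s, e, "OFF" if states[i] else "ON")
            for i, (c, s, e) in enumerate(intervals)]


def off_fraction(domains: list[AccessibilityDomain]) -> float:
    """Length-weighted OFF fraction of a domain list."""
    total = sum(d.end - d.start for d in domains)
    off = sum(d.end - d.start for d in domains if d.state == "OFF")
    return off / total if total else 0.0


# ---------------------------------------------------------------------------
# planted regions
# ---------------------------------------------------------------------------

def _inside_on_domain(chrom: str, start: int, end: int,
                      domains: list[AccessibilityDomain] | None) -> bool:
    if domains is None:
        return True
    for d in domains:
        if d.chrom == chrom and d.start <= start and end <= d.end:
            return d.state == "ON"
    return False


def plant_bound_regions(
    genes: list[GeneModel],
    domains: list[AccessibilityDomain] | None,
    config: PlantConfig,
    seed: int,
) -> list[TrueRegion]:
    """Plant single-peak and clustered bound regions near genes.

    Single regions get one randomly chosen gene each, with the kernel
    centre uniform inside the gene span (inset by the half-width where the
    gene allows).  Cluster regions pick a gene long enough to hold
    ``cluster_size`` peaks separated by at least twice the half-width and
    place the peaks by stick-breaking inside the span.  In constrained mode
    a candidate placement is rejected unless the full region lies inside a
    single ON domain; after ``max_tries`` rejections per feature the
    placement fails, listing what could not be placed.
    """
    rng = substream(seed, "plant")
    if config.n_single == 0 and config.n_clusters == 0:
        return []
    if not genes:
        raise PlacementError("no genes to plant regions near")
    constrained = config.constrained and domains is not None
    dom = domains if constrained else None
    hw = config.half_width_bp
    regions: list[TrueRegion] = []
    unplaced: list[str] = []

    def draw_fold() -> float:
        return float(rng.uniform(config.fold_min, config.fold_max))

    # --- clusters (first, so long genes are not consumed by singles) ------
    min_sep = int(config.cluster_sep_half_widths * hw)
    need = (config.cluster_size - 1) * min_sep + 2 * hw
    long_genes = [g for g in genes if g.length >= need]
    rng.shuffle(long_genes)  # type: ignore[arg-type]
    for ci in range(config.n_clusters):
        placed_cluster = None
        while long_genes:
            gene = long_genes.pop()
            for _ in range(config.max_tries):
                centers = _stick_break_centers(rng, gene.start + hw, gene.end - hw,
                                               config.cluster_size, min_sep)
                if centers is None:
                    break
                if all(_inside_on_domain(gene.chrom, c - hw, c + hw, dom) for c in centers):
                    placed_cluster = (gene, centers)
                    break
            if placed_cluster:
                break
        if placed_cluster is None:
            unplaced.append(f"cluster {ci + 1}/{config.n_clusters} "
                            f"(cluster_size={config.cluster_size})")
            continue
        gene, centers = placed_cluster
        for c in centers:
            regions.append(TrueRegion(gene.chrom, int(c), hw, draw_fold(),
                                      cluster_id=f"cluster{ci:03d}",
                                      target_gene=gene.gene_id))

    # --- singles -----------------------------------------------------------
    used = {r.target_gene for r in regions}
    gene_pool = [g for g in genes if g.gene_id not in used]
    rng.shuffle(gene_pool)  # type: ignore[arg-type]
    placed = 0
    pool_iter = iter(gene_pool)
    while placed < config.n_single:
        gene = next(pool_iter, None)
        if gene is None:
            unplaced.append(f"single region {placed + 1}/{config.n_single}")
            break
        lo = gene.start + hw
        hi = gene.end - hw
        if lo >= hi:  # short gene: centre on the midpoint
            lo = hi = (gene.start + gene.end) // 2
        for _ in range(config.max_tries):
            center = int(rng.integers(lo, hi + 1))
            if center - hw >= 0 and _inside_on_domain(gene.chrom, center - hw, center + hw, dom):
                regions.append(TrueRegion(gene.chrom, center, hw, draw_fold(),
                                          target_gene=gene.gene_id))
                placed += 1
                break
        # gene exhausted its tries: silently move to the next gene

    if unplaced:
        raise PlacementError(
            "insufficient accessible space; unplaced features: " + ", ".join(unplaced)
        )
    regions.sort(key=lambda r: (r.chrom, r.center))
    return regions


def _stick_break_centers(rng: np.random.Generator, lo: int, hi: int,
                         k: int, min_sep: int) -> np.ndarray | None:
    """k ordered centres in [lo, hi] with pairwise separation >= min_sep."""
    span = hi - lo
    slack = span - (k - 1) * min_sep
    if slack < 0:
        return None
    u = np.sort(rng.integers(0, slack + 1, size=k))
    return lo + u + min_sep * np.arange(k)


def insert_motif_matches(
    sequences: dict[str, str],
    regions: list[TrueRegion],
    motif_instance: str,
) -> tuple[dict[str, str], list[TrueRegion]]:
    """Write a concrete motif instance into the genome at each region centre.

    Returns updated sequences and regions with ``planted_motif`` recorded.
    Used to construct positive controls for motif-enrichment analysis.
    """
    arrs = {c: list(s) for c, s in sequences.items()}
    out_regions = []
    for r in regions:
        start = r.center - len(motif_instance) // 2
        seq = arrs[r.chrom]
        if start < 0 or start + len(motif_instance) > len(seq):
            out_regions.append(r)
            continue
        seq[start:start + len(motif_instance)] = list(motif_instance)
        out_regions.append(TrueRegion(r.chrom, r.center, r.half_width,
                                      r.enrichment_fold, r.cluster_id,
                                      motif_instance, r.target_gene))
    return {c: "".join(s) for c, s in arrs.items()}, out_regions


# ---------------------------------------------------------------------------
# probe intensities
# ---------------------------------------------------------------------------

def _kernel_profile(kind: str, positions: np.ndarray, center: int, half_width: int) -> np.ndarray:
    x = np.abs(positions - center) / half_width
    if kind == "triangular":
        return np.clip(1.0 - x, 0.0, None)
    # gaussian: sigma chosen so the kernel is ~0.01 at the half-width edge
    return np.exp(-0.5 * (x / 0.33) ** 2)


def simulate_probe_intensities(
    chrom_lengths: dict[str, int],
    true_regions: list[TrueRegion],
    config: ArrayConfig,
    seed: int,
):
    """Simulate specific-IP and control-IP probe panels.

    Control replicates are background only; specific replicates multiply
    the background by ``1 + (fold - 1) * kernel(position)`` under each
    planted region.  All intensities are strictly positive by construction
    (log-normal background times a factor >= 1).

    Returns
    -------
    (specific, control) : two :class:`~hoxchip.signal.ProbePanel` objects
    sharing the same probe grid.
    """
    from hoxchip.signal import ProbePanel  # deferred: avoid import cycle

    rng = substream(seed, "array")
    chroms_all, pos_all = [], []
    for chrom, length in chrom_lengths.items():
        n = max(0, (length - config.probe_length) // config.spacing_bp + 1)
        pos = np.arange(n) * config.spacing_bp
        chroms_all.append(np.full(n, chrom))
        pos_all.append(pos)
    chroms = np.concatenate(chroms_all)
    positions = np.concatenate(pos_all)
    n_probes = positions.size
    R = config.n_replicates

    affinity = rng.normal(0.0, config.sigma_affinity, n_probes)
    noise_ctrl = rng.normal(0.0, config.sigma_replicate, (R, n_probes))
    noise_spec = rng.normal(0.0, config.sigma_replicate, (R, n_probes))
    base_ctrl = np.exp(config.mu_log + affinity + noise_ctrl)
    base_spec = np.exp(config.mu_log + affinity + noise_spec)

    enrich = np.ones(n_probes)
    # probe "position" for kernel evaluation: the probe midpoint
    mid = positions + config.probe_length // 2
    for r in true_regions:
        sel = chroms == r.chrom
        k = _kernel_profile(config.kernel, mid[sel], r.center, r.half_width)
        enrich[sel] = np.maximum(enrich[sel], 1.0 + (r.enrichment_fold - 1.0) * k)
    specific = ProbePanel(chroms, positions, base_spec * enrich, "specific")
    control = ProbePanel(chroms, positions, base_ctrl, "control")
    return specific, control


# ---------------------------------------------------------------------------
# expression labels
# ---------------------------------------------------------------------------

def simulate_expression_labels(
    genes: list[GeneModel],
    true_regions: list[TrueRegion],
    config: BiasConfig,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Assign up/down/none expression labels with a repression bias.

    Genes targeted by a planted region count as bound.  Returns the label
    table (gene_id, label) and a dict of realized fractions for auditing.
    """
    rng = substream(seed, "labels")
    bound_ids = {r.target_gene for r in true_regions if r.target_gene is not None}
    rows = []
    for gene in genes:
        bound = gene.gene_id in bound_ids
        frac = config.frac_regulated_bound if bound else config.frac_regulated_unbound
        p_down = config.p_down_bound if bound else config.p_down_unbound
        if rng.random() < frac:
            label = "down" if rng.random() < p_down else "up"
        else:
            label = "none"
        rows.append((gene.gene_id, label, bound))
    df = pd.DataFrame(rows, columns=["gene_id", "label", "bound"])
    reg = df[df.label != "none"]
    stats = {
        "n_genes": len(df),
        "n_bound": int(df.bound.sum()),
        "n_regulated": len(reg),
        "frac_down_bound": float((reg[reg.bound].label == "down").mean()) if reg.bound.any() else float("nan"),
        "frac_down_unbound": float((reg[~reg.bound].label == "down").mean()) if (~reg.bound).any() else float("nan"),
        "frac_down_pool": float((reg.label == "down").mean()) if len(reg) else float("nan"),
    }
    return df[["gene_id", "label"]], stats
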