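"""IUPAC consensus-motif scanning and enrichment Z-scores.

Peak-centred sequences (400 nt by default) are scanned for degenerate
consensus matches on both strands; enrichment is measured against random
sequence sets of the same size and length drawn from the genome, as a
Z-score of the observed total count against the background-set counts,
with Z > 3 the conventional significance cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hoxchip._rng import substream
from hoxchip.peaks import BoundRegion

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide consensus, e.g. TGATNNATKR or TAAT."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        bad = [c for c in pat if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC characters {bad!r} in {pat!r}")
        if len(pat) < 3:
            raise ValueError("motif length must be >= 3")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def reverse_complement(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif: IUPACMotif
    observed_count: int
    background_counts: np.ndarray
    z_score: float
    significant: bool


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_peak_sequences(
    sequences: dict[str, str],
    regions: list[BoundRegion],
    length: int = 400,
) -> list[str]:
    """One sequence of exactly ``length`` nt centred on each region summit.

    Windows clipped by a chromosome edge are dropped with a warning rather
    than padded, so every returned sequence has the full length.
    """
    out = []
    dropped = 0
    for r in regions:
        if r.chrom not in sequences:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")
        chrom_seq = sequences[r.chrom]
        start = r.summit - length // 2
        end = start + length
        if start < 0 or end > len(chrom_seq):
            dropped += 1
            continue
        out.append(chrom_seq[start:end].upper())
    if dropped:
        warnings.warn(f"dropped {dropped} peak sequence(s) clipped at chromosome edges",
                      stacklevel=2)
    return out


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N, gaps) -> 4, which never matches."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _match_positions(encoded: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean array: does a match of ``pattern`` start at each position."""
    L = len(pattern)
    n = encoded.size - L + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC[code]:
            allowed[_BASE_INDEX[b]] = True
        ok &= allowed[encoded[j:j + n]]
    return ok


def scan_consensus(
    sequences: list[str],
    motif: IUPACMotif | str,
    both_strands: bool = True,
) -> tuple[int, list[int]]:
    """Count all (possibly overlapping) consensus matches in each sequence.

    With ``both_strands`` the reverse-complement pattern is also matched on
    the forward sequence; a position matching both patterns (strand-
    symmetric motifs) is counted once.  Positions containing N never match.
    Returns (total count, per-sequence counts).
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    rc = motif.reverse_complement
    per_seq = []
    for seq in sequences:
        enc = _encode(seq)
        hits = _match_positions(enc, motif.pattern)
        if both_strands:
            hits = hits | _match_positions(enc, rc)
        per_seq.append(int(hits.sum()))
    return sum(per_seq), per_seq


def sample_background_sets(
    sequences: dict[str, str],
    n_sets: int,
    set_size: int,
    seq_length: int,
    seed: int = 0,
    max_resample: int = 100,
):
    """Yield ``n_sets`` random sequence sets drawn uniformly from the genome.

    Each set contains ``set_size`` sequences of ``seq_length`` nt, start
    positions uniform over the genome (chromosomes weighted by eligible
    length), strand chosen at random; draws containing N are resampled.
    Yields sets lazily so large background ensembles never sit in memory.
    """
    chroms = [c for c, s in sequences.items() if len(s) >= seq_length]
    if not chroms:
        raise ValueError(f"no chromosome can hold a {seq_length} nt sequence")
    weights = np.array([len(sequences[c]) - seq_length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    rng = substream(seed, "background")
    for _ in range(n_sets):
        batch = []
        for _ in range(set_size):
            for _ in range(max_resample):
                ci = int(rng.choice(len(chroms), p=weights))
                chrom_seq = sequences[chroms[ci]]
                start = int(rng.integers(0, len(chrom_seq) - seq_length + 1))
                seq = chrom_seq[start:start + seq_length].upper()
                if "N" not in seq:
                    break
            else:
                raise ValueError("could not place an N-free background sequence")
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            batch.append(seq)
        yield batch


def motif_zscore(
    observed_count: int,
    background_counts,
    motif: IUPACMotif | str = "NNN",
) -> MotifEnrichmentResult:
    """Z-score of an observed motif count against background-set counts.

    z = (observed - mean(background)) / sd(background, unbiased);
    significant when z > 3.
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    bg = np.asarray(list(background_counts), dtype=float)
    if bg.size < 2:
        raise ValueError("need >= 2 background sets")
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("zero background variance; Z-score undefined")
    z = (observed_count - bg.mean()) / sd
    return MotifEnrichmentResult(motif, int(observed_count), bg, float(z), bool(z > 3))


def motif_enrichment(
    sequences: dict[str, str],
    peak_seqs: list[str],
    motif: IUPACMotif | str,
    n_sets: int = 1000,
    seed: int = 0,
) -> MotifEnrichmentResult:
    """End-to-end enrichment: scan peaks, scan matched backgrounds, Z-score."""
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    if not peak_seqs:
        raise ValueError("no peak sequences")
    seq_length = len(peak_seqs[0])
    observed, _ = scan_consensus(peak_seqs, motif)
    bg_counts = [
        scan_consensus(batch, motif)[0]
        for batch in sample_background_sets(sequences, n_sets, len(peak_seqs),
                                            seq_length, seed)
    ]
    return motif_zscore(observed, bg_counts, motif)


def expected_motif_rate(
    motif: IUPACMotif | str,
    base_composition=(0.25, 0.25, 0.25, 0.25),
) -> tuple[float, float]:
    """Expected double-stranded match rate per bp and the mean spacing.

    The per-position match probability is the product over motif positions
    of the summed base probabilities each IUPAC code allows, for the
    forward pattern plus the reverse-complement pattern, minus the
    probability of matching both at the same position (so strand-symmetric
    motifs are not double counted).  For TAAT under uniform composition the
    rate is 2 x (1/4)^4 = 1/128, i.e. a match every 128 bp on average.

    Returns (rate per bp, expected spacing in bp).
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("base composition must be 4 probabilities summing to 1")
    prob = {b: comp[i] for b, i in _BASE_INDEX.items()}

    def pattern_prob(pattern: str) -> float:
        p = 1.0
        for code in pattern:
            p *= sum(prob[b] for b in IUPAC[code])
        return p

    def both_prob(p1: str, p2: str) -> float:
        p = 1.0
        for c1, c2 in zip(p1, p2):
            p *= sum(prob[b] for b in set(IUPAC[c1]) & set(IUPAC[c2]))
        return p

    rc = motif.reverse_complement
    rate = pattern_prob(motif.pattern) + pattern_prob(rc) - both_prob(motif.pattern, rc)
    if rate == 0:
        raise ValueError(
            f"motif {motif.pattern!r} has zero probability under this composition; "
            "expected spacing is infinite")
    return float(rate), float(1.0 / rate)
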