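"""Grammar dissection: confidence tiers, redundancy purge, binned motif
enrichment with mutual information, motif ablation, and gradient saliency.

The enrichment statistic follows the FIRE recipe: items are sorted by a
continuous profile (e.g. secretion probability or expression log-fold change)
and cut into equally populated bins; each bin's motif count is scored with
exact hypergeometric tails, the global association is summarized as the
mutual information between motif presence and bin index, and the MI is
calibrated as a z-score against profile permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

ECX_CUT = 0.95
ICX_CUT = 0.05


# ---------------------------------------------------------------------------
# Confidence tiers
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceAssignment:
    id: str
    label: str
    probability: float
    tier: str  # ECX | ICX | none


def select_confident(
    assignments: Sequence[tuple[str, str, float]],
    ecx_cut: float = ECX_CUT,
    icx_cut: float = ICX_CUT,
) -> list[ConfidenceAssignment]:
    """Tier records as ECX (true EC, p > 0.95), ICX (true IC, p < 0.05), or none.

    Mispredicted records never enter an extreme tier: a false positive
    (IC with high probability) is 'none', not ECX.
    """
    out = []
    for rid, label, p in assignments:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0,1] for {rid!r}: {p}")
        if label == "EC" and p > ecx_cut:
            tier = "ECX"
        elif label == "IC" and p < icx_cut:
            tier = "ICX"
        else:
            tier = "none"
        out.append(ConfidenceAssignment(rid, label, p, tier))
    return out


# ---------------------------------------------------------------------------
# Redundancy purge
# ---------------------------------------------------------------------------

def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def purge_similar(
    sequences: Sequence[str],
    score_threshold: float = 50.0,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> list[str]:
    """Greedy redundancy purge by local-alignment score.

    Scanning in input order, a sequence is dropped when its best local
    alignment against any already-retained sequence scores >= threshold
    (BLAST-like scale: +5 match / -4 mismatch, affine gaps -10/-1).
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    al = _aligner(match, mismatch, gap_open, gap_extend)
    kept: list[str] = []
    for seq in sequences:
        s = str(seq).upper().replace("U", "T")
        redundant = any(al.score(s, k) >= score_threshold for k in kept)
        if not redundant:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# Motif patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """Positional pattern: literal letters or bracketed letter classes.

    RNA/DNA alphabets are normalized to the internal DNA alphabet, so
    ``[ACU]AG[GU][GU]`` and ``[ACT]AG[GT][GT]`` are the same pattern.
    """

    pattern: str
    positions: tuple[frozenset, ...] = field(default=(), compare=False)

    def __post_init__(self):
        object.__setattr__(self, "positions", _parse_pattern(self.pattern))

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, offset: int) -> bool:
        if offset < 0 or offset + len(self) > len(seq):
            return False
        return all(seq[offset + i] in s for i, s in enumerate(self.positions))

    def find_all(self, seq: str) -> list[int]:
        """All match offsets (overlaps included) on the given strand."""
        seq = seq.upper().replace("U", "T")
        return [i for i in range(len(seq) - len(self) + 1) if self.matches_at(seq, i)]

    def contains(self, seq: str) -> bool:
        return bool(self.find_all(seq))


def _parse_pattern(pattern: str) -> tuple[frozenset, ...]:
    if not pattern:
        raise ValueError("empty motif pattern")
    out: list[frozenset] = []
    i = 0
    norm = pattern.upper().replace("U", "T")
    while i < len(norm):
        ch = norm[i]
        if ch == "[":
            j = norm.find("]", i)
            if j <= i + 1:
                raise ValueError(f"malformed letter class in pattern {pattern!r}")
            letters = set(norm[i + 1 : j])
            if not letters <= set("ACGT"):
                raise ValueError(f"invalid letters in class {norm[i:j+1]!r}")
            out.append(frozenset(letters))
            i = j + 1
        elif ch in "ACGT":
            out.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"invalid pattern character {ch!r} in {pattern!r}")
    return tuple(out)


# ---------------------------------------------------------------------------
# FIRE-style binned enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    n_bins: int
    bin_sizes: np.ndarray
    bin_motif_counts: np.ndarray
    signed_log10_p: np.ndarray  # + over-representation, - under-representation
    mi_bits: float
    z_score: float
    significant: np.ndarray  # per bin, Bonferroni across bins at 0.05
    bin_order: np.ndarray  # item -> bin assignment


def equal_population_bins(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Assign each item to one of n_bins equally populated, value-sorted bins.

    Ties break by stable input order; bin sizes differ by at most 1.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds item count {n}")
    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if b < extra else 0) for b in range(n_bins)]
    assign = np.empty(n, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        assign[order[pos : pos + size]] = b
        pos += size
    return assign


def mutual_information_bits(flags: np.ndarray, bins: np.ndarray, n_bins: int) -> float:
    """MI (bits) between a binary flag and the bin index, from observed joints."""
    n = len(flags)
    mi = 0.0
    p_flag = np.array([(flags == 0).mean(), (flags == 1).mean()])
    for b in range(n_bins):
        in_b = bins == b
        p_b = in_b.mean()
        if p_b == 0:
            continue
        for fval in (0, 1):
            p_joint = float(np.mean(in_b & (flags == fval)))
            if p_joint > 0 and p_flag[fval] > 0:
                mi += p_joint * np.log2(p_joint / (p_b * p_flag[fval]))
    return max(mi, 0.0)


def bin_enrichment_profile(
    values: Sequence[float],
    has_motif: Sequence[bool],
    n_bins: int = 9,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnrichmentProfile:
    """Equally populated bins over a value profile, scored per bin by exact
    hypergeometric tails and globally by MI with a permutation z-score."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(has_motif).astype(int)
    n = len(values)
    if len(flags) != n:
        raise ValueError("values and has_motif must have equal length")
    if flags.sum() == 0:
        raise ValueError("at least one motif-bearing item is required")
    bins = equal_population_bins(values, n_bins)

    K = int(flags.sum())  # marked items in the population
    sizes = np.bincount(bins, minlength=n_bins)
    counts = np.array([int(flags[bins == b].sum()) for b in range(n_bins)])

    signed = np.empty(n_bins)
    raw_p = np.empty(n_bins)
    for b in range(n_bins):
        k, m = counts[b], sizes[b]
        p_over = float(hypergeom.sf(k - 1, n, K, m))  # P(X >= k)
        p_under = float(hypergeom.cdf(k, n, K, m))  # P(X <= k)
        if p_over <= p_under:
            signed[b] = -np.log10(max(p_over, 1e-300))
            raw_p[b] = p_over
        else:
            signed[b] = np.log10(max(p_under, 1e-300))
            raw_p[b] = p_under

    mi = mutual_information_bits(flags, bins, n_bins)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = mutual_information_bits(flags, rng.permutation(bins), n_bins)
    sd = null.std(ddof=1)
    z = float((mi - null.mean()) / sd) if sd > 0 else float("inf") if mi > null.mean() else 0.0

    significant = raw_p * n_bins < alpha
    return EnrichmentProfile(
        n_bins=n_bins, bin_sizes=sizes, bin_motif_counts=counts,
        signed_log10_p=signed, mi_bits=float(mi), z_score=z,
        significant=significant, bin_order=bins,
    )


# ---------------------------------------------------------------------------
# Motif ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationReport:
    motif: str
    mode: str
    n: int
    n_excluded: int
    mean_prob_before: float
    mean_prob_after: float
    frac_ecx_lost: float  # prob fell to <= 0.95
    frac_ecx_lost_decision: float  # prob fell to < 0.5


def apply_motif_ablation(sequence: str, motif: MotifPattern, mode: str) -> str:
    """Mask matched positions with 'N' (zero one-hot column) or delete them."""
    seq = sequence.upper().replace("U", "T")
    hit = np.zeros(len(seq), dtype=bool)
    for off in motif.find_all(seq):
        hit[off : off + len(motif)] = True
    if not hit.any():
        return seq
    if mode == "mask":
        return "".join("N" if h else c for c, h in zip(seq, hit))
    if mode == "remove":
        return "".join(c for c, h in zip(seq, hit) if not h)
    raise ValueError(f"mode must be 'mask' or 'remove', got {mode!r}")


def motif_ablation(
    model,
    sequences: Sequence[str],
    motif: MotifPattern | str,
    mode: str = "mask",
    ecx_cut: float = ECX_CUT,
) -> AblationReport:
    """Compare secretion probabilities before and after motif mask/removal.

    Sequences without a match are excluded and counted. 'ECX lost' is reported
    under both readings: probability dropping to <= 0.95 (no longer extreme)
    and dropping below the 0.5 decision boundary (no longer predicted EC).
    """
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    seqs = [str(s).upper().replace("U", "T") for s in sequences]
    matched = [s for s in seqs if motif.contains(s)]
    n_excluded = len(seqs) - len(matched)
    if not matched:
        return AblationReport(motif.pattern, mode, 0, n_excluded,
                              float("nan"), float("nan"), float("nan"), float("nan"))
    before = np.asarray(model.secretion_probability(matched))
    ablated = [apply_motif_ablation(s, motif, mode) for s in matched]
    after = np.asarray(model.secretion_probability(ablated))
    was_ecx = before > ecx_cut
    if was_ecx.any():
        lost = float(np.mean(after[was_ecx] <= ecx_cut))
        lost_dec = float(np.mean(after[was_ecx] < 0.5))
    else:
        lost = lost_dec = float("nan")
    return AblationReport(
        motif=motif.pattern, mode=mode, n=len(matched), n_excluded=n_excluded,
        mean_prob_before=float(before.mean()), mean_prob_after=float(after.mean()),
        frac_ecx_lost=lost, frac_ecx_lost_decision=lost_dec,
    )


# ---------------------------------------------------------------------------
# Saliency
# ---------------------------------------------------------------------------

def saliency(model, sequence: str) -> np.ndarray:
    """Gradient x input attribution per position (channels summed).

    Requires a differentiable family (cnn/lstm/gru); for classical models use
    motif ablation instead.
    """
    if not hasattr(model, "input_gradient"):
        raise TypeError(
            "saliency requires a differentiable model family (cnn/lstm/gru); "
            "use motif_ablation for classical models"
        )
    seq = str(sequence).upper().replace("U", "T")
    from .features import encode_onehot

    Xoh, _ = encode_onehot([seq], max_len=model.max_len)
    grad = model.input_gradient([seq])
    attr = (grad[0] * Xoh[0]).sum(axis=1)
    return attr[: min(len(seq), model.max_len)]


__all__ = [
    "ConfidenceAssignment", "select_confident",
    "purge_similar",
    "MotifPattern",
    "EnrichmentProfile", "equal_population_bins", "mutual_information_bits",
    "bin_enrichment_profile",
    "AblationReport", "apply_motif_ablation", "motif_ablation",
    "saliency",
    "ECX_CUT", "ICX_CUT",
]
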