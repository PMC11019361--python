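"""RBP binding-site enrichment over signal tracks.

Per protein: replicate tracks merged by per-base maximum, signal extracted
over peak-overlapping bases of the EC-extreme vs IC-extreme regions (or over
the union of the two region sets, which avoids zero inflation from
non-overlapping peak bases), a one-sided Mann-Whitney test of EV > IC, BH
correction across the protein panel, and intra-protein summary features with
robust outlier calls (MAD z, parametric z, percentile rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval, SignalTrack


@dataclass
class RBPSignalBundle:
    protein: str
    tracks: list[SignalTrack]
    peaks: list[GenomicInterval]

    def __post_init__(self):
        if not self.tracks:
            raise ValueError("at least one signal track is required")
        sizes = self.tracks[0].chrom_sizes
        for t in self.tracks[1:]:
            if t.chrom_sizes != sizes:
                raise ValueError("replicate tracks disagree on chromosome sizes")


def max_over_replicates(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base maximum across replicate tracks; absent positions read 0."""
    if not tracks:
        raise ValueError("at least one track required")
    sizes = tracks[0].chrom_sizes
    for t in tracks[1:]:
        if t.chrom_sizes != sizes:
            raise ValueError("chromosome-size tables differ between tracks")
    merged = SignalTrack(sizes)
    for chrom in sizes:
        merged.values[chrom] = np.max([t.values[chrom] for t in tracks], axis=0)
    return merged


def _interval_mask(intervals: Sequence[GenomicInterval], sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for iv in intervals:
        if iv.chrom not in masks:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def extract_region_signals(
    track: SignalTrack,
    peaks: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    mode: str = "union",
    zero_fill: bool = False,
) -> np.ndarray:
    """Signal values over region bases, in deterministic genomic order.

    ``peak_only``: bases in (peaks intersect regions); with ``zero_fill`` the
    non-peak region bases contribute explicit zeros (the zero-inflated variant).
    ``union``: all bases of the supplied regions — callers pass the union of
    the EC-extreme and IC-extreme regions as the restriction set. Overlapping
    regions are deduplicated per base.
    """
    sizes = track.chrom_sizes
    region_mask = _interval_mask(regions, sizes)
    if mode == "peak_only":
        peak_mask = _interval_mask(peaks, sizes)
        select = {c: region_mask[c] & peak_mask[c] for c in sizes}
        if zero_fill:
            out = []
            for c in sorted(sizes):
                vals = track.values[c][region_mask[c]].copy()
                inpeak = peak_mask[c][region_mask[c]]
                vals[~inpeak] = 0.0
                out.append(vals)
            return np.concatenate(out) if out else np.array([])
    elif mode == "union":
        select = region_mask
    else:
        raise ValueError(f"mode must be 'peak_only' or 'union', got {mode!r}")
    out = [track.values[c][select[c]] for c in sorted(sizes)]
    return np.concatenate(out) if out else np.array([])


@dataclass
class EnrichmentTestResult:
    protein: str
    n_ev: int
    n_ic: int
    u_statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def rank_sum_enrichment(ev_values: Sequence[float], ic_values: Sequence[float],
                        protein: str = "") -> EnrichmentTestResult:
    """One-sided Mann-Whitney (EV greater), exact for small tie-free samples."""
    ev = np.asarray(ev_values, dtype=float)
    ic = np.asarray(ic_values, dtype=float)
    if len(ev) == 0 or len(ic) == 0:
        raise ValueError("both EV and IC value sets must be non-empty")
    has_ties = len(np.unique(np.concatenate([ev, ic]))) < len(ev) + len(ic)
    method = "exact" if (min(len(ev), len(ic)) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(ev, ic, alternative="greater", method=method)
    return EnrichmentTestResult(protein, len(ev), len(ic),
                                float(res.statistic), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_protein_panel(
    results: Sequence[EnrichmentTestResult], alpha: float = 0.05
) -> list[EnrichmentTestResult]:
    """BH-adjust a panel of per-protein tests and flag significance."""
    adj = bh_adjust([r.p_value for r in results])
    out = []
    for r, q in zip(results, adj):
        out.append(EnrichmentTestResult(r.protein, r.n_ev, r.n_ic, r.u_statistic,
                                        r.p_value, float(q), bool(q < alpha)))
    return out


# ---------------------------------------------------------------------------
# Intra-protein features
# ---------------------------------------------------------------------------

@dataclass
class GroupFeatures:
    n_regions: int
    total_length: int
    total_signal: float
    mean_signal: float


@dataclass
class IntraProteinFeatures:
    protein: str
    ev: GroupFeatures
    ic: GroupFeatures


def _group_features(track: SignalTrack, peaks: Sequence[GenomicInterval],
                    regions: Sequence[GenomicInterval]) -> GroupFeatures:
    peak_mask = _interval_mask(peaks, track.chrom_sizes)
    n = 0
    total_len = 0
    total_sig = 0.0
    for iv in regions:
        overlap = peak_mask[iv.chrom][iv.start : iv.end]
        if overlap.any():
            n += 1
            total_len += int(overlap.sum())
            total_sig += float(track.values[iv.chrom][iv.start : iv.end][overlap].sum())
    mean = total_sig / total_len if total_len else 0.0
    return GroupFeatures(n, total_len, total_sig, mean)


def intra_protein_features(
    bundle: RBPSignalBundle,
    ev_regions: Sequence[GenomicInterval],
    ic_regions: Sequence[GenomicInterval],
) -> IntraProteinFeatures:
    """Counts, overlap lengths, signal sums, and mean signal per group for
    regions overlapping the protein's peaks.

    Callers pre-filter regions by their model probability floor (the
    high-confidence sets); the floors differ per group and are an explicit
    caller decision.
    """
    track = max_over_replicates(bundle.tracks)
    return IntraProteinFeatures(
        protein=bundle.protein,
        ev=_group_features(track, bundle.peaks, ev_regions),
        ic=_group_features(track, bundle.peaks, ic_regions),
    )


@dataclass
class OutlierFlags:
    robust_z: np.ndarray
    parametric_z: np.ndarray
    percentile: np.ndarray
    robust_outlier: np.ndarray
    parametric_outlier: np.ndarray
    percentile_outlier: np.ndarray
    mad_degenerate: bool


def outlier_flags(values: Sequence[float], robust_cut: float = 3.5,
                  z_cut: float = 3.0, pct_cut: float = 0.99) -> OutlierFlags:
    """Robust (MAD) z, parametric z, and percentile-rank outlier calls across
    a protein panel for one feature."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        rz = 0.6745 * (x - med) / mad
        degenerate = False
    else:
        rz = np.full_like(x, np.nan)
        degenerate = True
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    pz = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    from scipy.stats import rankdata

    pct = (rankdata(x) - 1) / max(len(x) - 1, 1)
    return OutlierFlags(
        robust_z=rz, parametric_z=pz, percentile=pct,
        robust_outlier=(np.abs(rz) > robust_cut) if not degenerate else np.zeros(len(x), dtype=bool),
        parametric_outlier=np.abs(pz) > z_cut,
        percentile_outlier=pct > pct_cut,
        mad_degenerate=degenerate,
    )


__all__ = [
    "RBPSignalBundle", "max_over_replicates", "extract_region_signals",
    "EnrichmentTestResult", "rank_sum_enrichment", "bh_adjust", "adjust_protein_panel",
    "GroupFeatures", "IntraProteinFeatures", "intra_protein_features",
    "OutlierFlags", "outlier_flags",
]
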