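"""Planted-grammar benchmark generator.

Emulates the statistical structure the pipeline assumes — EC sequences
enriched for short consensus motifs over an order-1 Markov background, heavy
IC:EC imbalance, overdispersed EV/CM/IC counts with an EC secretion effect,
and EC-biased per-base signal tracks with peaks — so every stage is testable
without downloading anything.

Defaults state the benchmark world once: 5,000 EC vs 20,000 IC (the ~1:4
retained imbalance at desk scale), planted motifs CCUGGC (0.60 EC / 0.05 IC),
GAGUC (0.40 / 0.05) and [ACU]AG[GU][GU] (0.30 / 0.05), lengths 18-50 with
mean 20, motif insertion by overwriting background letters so length stays
label-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DinucModel, generate_sequences
from .interpret import MotifPattern
from .io import GenomicInterval, SignalTrack, SmallRNARecord


def uniform_dinuc_model(mean_len: float = 20.0, len_sd: float = 4.0) -> DinucModel:
    return DinucModel(
        initial=np.full(4, 0.25),
        transition=np.full((4, 4), 0.25),
        mean_len=mean_len,
        len_sd=len_sd,
    )


def default_planted_motifs() -> list[tuple[str, float, float]]:
    return [
        ("CCTGGC", 0.60, 0.05),  # CCUGGC
        ("GAGTC", 0.40, 0.05),  # GAGUC
        ("[ACT]AG[GT][GT]", 0.30, 0.05),  # [ACU]AG[GU][GU]
    ]


@dataclass
class BenchmarkSpec:
    n_ec: int = 5000
    n_ic: int = 20000
    background: DinucModel = field(default_factory=uniform_dinuc_model)
    motifs: list[tuple[str, float, float]] = field(default_factory=default_planted_motifs)
    # count model
    mean_ic: float = 100.0
    mean_ev: float = 100.0
    mean_cm: float = 100.0
    dispersion: float = 0.2  # NB: var = mu + alpha * mu^2
    effect_log2: float = 2.0  # EV/CM mean multiplier 2^effect for EC records
    cm_extra_noise: float = 0.5  # CM behaves like EV with more variance
    # signal model
    signal_baseline: float = 2.0
    signal_boost: float = 3.0  # multiplier over EV regions for the planted protein
    signal_noise_sd: float = 0.5
    peak_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for pat, p_ec, p_ic in self.motifs:
            if not (0 <= p_ec <= 1 and 0 <= p_ic <= 1):
                raise ValueError(f"insertion probabilities out of [0,1] for {pat!r}")


def _sample_class_member(rng: np.random.Generator, letters: frozenset) -> str:
    opts = sorted(letters)
    return opts[rng.integers(len(opts))]


def _insert_motif(seq: str, motif: MotifPattern, rng: np.random.Generator) -> tuple[str, int, str]:
    """Overwrite background letters with one sampled motif instance."""
    L, m = len(seq), len(motif)
    if m > L:
        raise ValueError(f"motif {motif.pattern!r} longer than sequence length {L}")
    off = int(rng.integers(0, L - m + 1))
    instance = "".join(_sample_class_member(rng, s) for s in motif.positions)
    return seq[:off] + instance + seq[off + m :], off, instance


def make_sequence_dataset(
    spec: BenchmarkSpec,
) -> tuple[list[SmallRNARecord], pd.DataFrame]:
    """Labeled records plus a truth table of every motif insertion.

    Each planted motif is inserted independently with its class probability at
    a uniformly random offset (overwriting, one copy per motif). Later
    insertions may overwrite earlier ones; the truth table records the final
    state by re-checking each recorded offset.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = [(MotifPattern(p), pe, pi) for p, pe, pi in spec.motifs]
    min_needed = max(len(m) for m, _, _ in motifs)
    if min_needed > spec.background.min_len:
        raise ValueError("a planted motif exceeds the minimum sequence length")

    n_total = spec.n_ec + spec.n_ic
    backgrounds = generate_sequences(spec.background, n_total,
                                     seed=int(rng.integers(2**31 - 1)))
    records: list[SmallRNARecord] = []
    truth_rows: list[dict] = []
    width = len(str(n_total))
    for i, seq in enumerate(backgrounds):
        label = "EC" if i < spec.n_ec else "IC"
        rid = f"{label.lower()}_{i:0{width}d}"
        insertions: list[tuple[MotifPattern, int, str]] = []
        for motif, p_ec, p_ic in motifs:
            p = p_ec if label == "EC" else p_ic
            if rng.random() < p:
                seq, off, inst = _insert_motif(seq, motif, rng)
                insertions.append((motif, off, inst))
        for motif, off, inst in insertions:
            if motif.matches_at(seq, off):  # may have been overwritten
                truth_rows.append({"id": rid, "motif": motif.pattern, "offset": off,
                                   "instance": inst, "label": label})
        records.append(SmallRNARecord(id=rid, sequence=seq, label=label, source="synthbench"))
    truth = pd.DataFrame(truth_rows, columns=["id", "motif", "offset", "instance", "label"])
    return records, truth


def make_count_table(records: Sequence[SmallRNARecord], spec: BenchmarkSpec) -> pd.DataFrame:
    """Overdispersed NB counts per fraction; EC records get the EV/CM boost.

    NB parameterized by mean mu and dispersion alpha (var = mu + alpha mu^2);
    alpha -> 0 recovers Poisson.
    """
    if spec.mean_ic <= 0 or spec.mean_ev <= 0 or spec.mean_cm <= 0:
        raise ValueError("count means must be positive")
    rng = np.random.default_rng([spec.seed, 1])
    boost = 2.0 ** spec.effect_log2

    def nb_draw(mu: np.ndarray, alpha: float) -> np.ndarray:
        if alpha <= 1e-9:
            return rng.poisson(mu)
        r = 1.0 / alpha
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    is_ec = np.array([r.label == "EC" for r in records])
    n = len(records)
    mu_ic = np.full(n, spec.mean_ic)
    mu_ev = np.where(is_ec, spec.mean_ev * boost, spec.mean_ev)
    mu_cm = np.where(is_ec, spec.mean_cm * boost, spec.mean_cm)
    ic = nb_draw(mu_ic, spec.dispersion)
    ev = nb_draw(mu_ev, spec.dispersion)
    cm = nb_draw(mu_cm, spec.dispersion + spec.cm_extra_noise)
    return pd.DataFrame({"id": [r.id for r in records], "IC": ic, "EV": ev, "CM": cm})


@dataclass
class SignalFixture:
    bundles: list
    ev_regions: list[GenomicInterval]
    ic_regions: list[GenomicInterval]
    chrom_sizes: dict
    planted_protein: str


def make_signal_fixture(
    spec: BenchmarkSpec,
    records: Sequence[SmallRNARecord],
    n_proteins: int = 20,
    planted_index: int = 0,
    n_regions_per_group: int = 50,
    spacing: int = 10,
) -> SignalFixture:
    """Toy-chromosome signal bundles: one planted EC-biased protein among nulls.

    Records are assigned disjoint intervals on a synthetic chromosome in input
    order (EV regions first). Null proteins draw identical noise over both
    groups; the planted protein's signal over EV regions is multiplied by the
    spec's boost. Peaks cover ``peak_fraction`` of the regions.
    """
    from .rbp import RBPSignalBundle

    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    ev_recs = [r for r in records if r.label == "EC"][:n_regions_per_group]
    ic_recs = [r for r in records if r.label == "IC"][:n_regions_per_group]
    if len(ev_recs) < n_regions_per_group or len(ic_recs) < n_regions_per_group:
        raise ValueError("not enough records per group for the requested regions")

    rng = np.random.default_rng([spec.seed, 2])
    pos = 0
    ev_regions, ic_regions = [], []
    for group, recs, out in (("EV", ev_recs, ev_regions), ("IC", ic_recs, ic_regions)):
        for r in recs:
            L = len(r.sequence)
            out.append(GenomicInterval("chrS", pos, pos + L, "+"))
            pos += L + spacing
    sizes = {"chrS": pos + spacing}

    bundles = []
    planted_name = None
    for pi in range(n_proteins):
        name = f"RBP{pi:02d}"
        track = SignalTrack(sizes)
        noise = np.abs(rng.normal(spec.signal_baseline, spec.signal_noise_sd,
                                  size=sizes["chrS"]))
        track.values["chrS"] = noise
        if pi == planted_index:
            planted_name = name
            for iv in ev_regions:
                track.values["chrS"][iv.start : iv.end] *= spec.signal_boost
        peaks = []
        all_regions = ev_regions + ic_regions
        n_peaked = int(round(spec.peak_fraction * len(all_regions)))
        for iv in all_regions[:n_peaked]:
            peaks.append(iv)
        bundles.append(RBPSignalBundle(protein=name, tracks=[track], peaks=peaks))
    return SignalFixture(bundles, ev_regions, ic_regions, sizes, planted_name)


def null_spec(seed: int = 0, **kwargs) -> BenchmarkSpec:
    """The no-grammar world: all insertion probabilities zero, no count effect."""
    motifs = [(p, 0.0, 0.0) for p, _, _ in default_planted_motifs()]
    return BenchmarkSpec(motifs=motifs, effect_log2=0.0, signal_boost=1.0,
                         seed=seed, **kwargs)


__all__ = [
    "BenchmarkSpec", "SignalFixture",
    "uniform_dinuc_model", "default_planted_motifs", "null_spec",
    "make_sequence_dataset", "make_count_table", "make_signal_fixture",
]
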