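"""Readers/writers for the standard formats shared by all stages.

Coordinates are 0-based half-open everywhere (BED native); 1-based wiggle is
converted on read. FASTA is the carrier for sequence sets, with EC/IC labels
either in the header (``label=EC``) or in a sidecar TSV (``id<TAB>label``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

VALID_LABELS = ("EC", "IC", "unlabeled")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SmallRNARecord:
    """One small RNA: id, canonical DNA-alphabet sequence, EC/IC label."""

    id: str
    sequence: str
    label: str = "unlabeled"
    source: str = ""
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        self.sequence = canonical_dna(self.sequence)
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    def as_rna(self) -> str:
        return self.sequence.replace("T", "U")


def canonical_dna(seq: str) -> str:
    """Upper-case and map U->T; internal alphabet is {A,C,G,T,N}."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq


def to_rna(seq: str) -> str:
    """T->U for RNA-facing output."""
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_labeled_fasta(
    path: str | Path,
    label_source: str = "header",
    sidecar: str | Path | None = None,
    source: str = "",
) -> list[SmallRNARecord]:
    """Read a FASTA of small RNAs with EC/IC labels.

    ``label_source`` is ``header`` (``>id label=EC``) or ``sidecar`` (TSV of
    ``id<TAB>label``; ids missing from the sidecar stay unlabeled).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if label_source not in ("header", "sidecar"):
        raise ValueError(f"label_source must be 'header' or 'sidecar', got {label_source!r}")

    labels: dict[str, str] = {}
    if label_source == "sidecar":
        if sidecar is None:
            raise ValueError("label_source='sidecar' requires a sidecar path")
        labels = read_label_sidecar(sidecar)

    records: list[SmallRNARecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        fields = header.split()
        rid = fields[0]
        if rid in seen:
            raise ValueError(f"duplicate identifier in FASTA: {rid!r}")
        seen.add(rid)
        label = "unlabeled"
        if label_source == "header":
            for f in fields[1:]:
                if f.startswith("label="):
                    val = f[len("label="):].upper()
                    if val in ("EC", "IC"):
                        label = val
                    elif val not in ("UNLABELED", "NONE", ""):
                        raise ValueError(
                            f"unknown label {val!r} for record {rid!r} (line {header_line})"
                        )
        else:
            label = labels.get(rid, "unlabeled")
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"record {rid!r} has an empty sequence (line {header_line})")
        records.append(SmallRNARecord(id=rid, sequence=seq, label=label, source=source))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                header_line = i
                if not header:
                    raise ValueError(f"malformed FASTA: empty header at line {i}")
            else:
                if header is None:
                    raise ValueError(f"malformed FASTA: sequence before any header at line {i}")
                chunks.append(line)
        flush(-1)

    if not records:
        warnings.warn(f"no records read from {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SmallRNARecord], path: str | Path, rna: bool = False) -> None:
    """Write records with labels in headers; byte-stable for round trips."""
    with open(path, "w") as fh:
        for rec in records:
            seq = to_rna(rec.sequence) if rna else rec.sequence
            fh.write(f">{rec.id} label={rec.label}\n{seq}\n")


def read_label_sidecar(path: str | Path) -> dict[str, str]:
    """TSV of id<TAB>label (EC/IC), no header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed sidecar line {i}: {line!r}")
            out[parts[0]] = parts[1].upper()
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph / wiggle
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6; score column ignored, strand kept when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: {line!r}")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


class SignalTrack:
    """Dense per-base signal over a declared chromosome-size table.

    Dense arrays keep interval arithmetic trivially correct; intended for the
    desk-scale fixtures this package tests on, not whole genomes (bigWig
    ingestion is deliberately out of scope).
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.values: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=float) for c, n in self.chrom_sizes.items()
        }

    def set_interval(self, chrom: str, start: int, end: int, value: float) -> None:
        if chrom not in self.values:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        if start < 0:
            raise ValueError(f"negative coordinate: {start}")
        if end > self.chrom_sizes[chrom]:
            raise ValueError(
                f"interval [{start},{end}) exceeds size of {chrom} ({self.chrom_sizes[chrom]})"
            )
        self.values[chrom][start:end] = value

    def get(self, interval: GenomicInterval) -> np.ndarray:
        if interval.chrom not in self.values:
            raise KeyError(f"unknown chromosome: {interval.chrom!r}")
        return self.values[interval.chrom][interval.start:interval.end]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            chrom, size = line.split()[:2]
            out[chrom] = int(size)
    return out


def read_signal_track(path: str | Path, chrom_sizes: Mapping[str, int]) -> SignalTrack:
    """Read bedGraph or wiggle (fixedStep/variableStep) into a dense track.

    Overlapping input lines are resolved last-wins with a warning; positions
    absent from the file read as 0. Wiggle's 1-based starts are converted to
    the internal 0-based half-open convention.
    """
    track = SignalTrack(chrom_sizes)
    covered: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=bool) for c, n in track.chrom_sizes.items()
    }
    overlap_warned = False

    def assign(chrom: str, start: int, end: int, value: float, line_no: int) -> None:
        nonlocal overlap_warned
        if chrom not in track.values:
            raise KeyError(f"unknown chromosome {chrom!r} at line {line_no}")
        if start < 0:
            raise ValueError(f"negative coordinate at line {line_no}")
        if covered[chrom][start:end].any() and not overlap_warned:
            warnings.warn(
                f"overlapping signal definitions (line {line_no}); last value wins",
                stacklevel=3,
            )
            overlap_warned = True
        track.values[chrom][start:end] = value
        covered[chrom][start:end] = True

    mode = "bedgraph"
    wig_chrom, wig_pos, wig_step, wig_span = "", 0, 1, 1
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode = "fixed"
                wig_chrom = kv["chrom"]
                wig_pos = int(kv["start"]) - 1  # wiggle is 1-based
                wig_step = int(kv.get("step", 1))
                wig_span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode = "variable"
                wig_chrom = kv["chrom"]
                wig_span = int(kv.get("span", 1))
                continue
            parts = line.split()
            if mode == "fixed" and len(parts) == 1:
                assign(wig_chrom, wig_pos, wig_pos + wig_span, float(parts[0]), i)
                wig_pos += wig_step
            elif mode == "variable" and len(parts) == 2:
                start = int(parts[0]) - 1
                assign(wig_chrom, start, start + wig_span, float(parts[1]), i)
            elif len(parts) == 4:
                mode = "bedgraph"
                assign(parts[0], int(parts[1]), int(parts[2]), float(parts[3]), i)
            else:
                raise ValueError(f"malformed signal line {i}: {line!r}")
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Run-length encode nonzero stretches as bedGraph lines."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            if vals.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [vals.size]))
            for s, e in zip(starts, ends):
                if vals[s] != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:g}\n")


# ---------------------------------------------------------------------------
# Counts, config, run log
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns id, IC, EV, CM (non-negative integer counts)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "IC", "EV", "CM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    for col in ("IC", "EV", "CM"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    return df.set_index("id")


@dataclass
class RunConfig:
    """Named config sections plus the single global seed.

    Every stochastic stage derives its generator from ``seed`` plus a stage
    name, so stages are independently reproducible.
    """

    seed: int = 0
    curation: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    interpretation: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    def stage_rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator derived from the global seed plus a stage name."""
    return np.random.default_rng([seed, int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")])


def write_run_log(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    import secgram

    log = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {"secgram": secgram.__version__, "numpy": np.__version__},
    }
    if extra:
        log.update(extra)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)


__all__ = [
    "GenomicInterval",
    "SmallRNARecord",
    "SignalTrack",
    "RunConfig",
    "canonical_dna",
    "to_rna",
    "read_labeled_fasta",
    "write_fasta",
    "read_label_sidecar",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_signal_track",
    "write_bedgraph",
    "read_count_table",
    "stage_rng",
    "write_run_log",
]
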