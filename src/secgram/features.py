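"""Sequence and structure featurization.

Four representations are derived per small RNA: the primary sequence, the
dot-bracket secondary structure, the per-position structural element string
(five-prime f, three-prime t, stem s, interior loop i, multiloop m, hairpin h),
and the 8-term notation (sequence letters upper-cased where paired). K-mer
frequencies over each representation, folding free energy, and length make up
the tabular feature space; one-hot encoding serves the sequence models.

Folding backends: ``vienna`` delegates to the ViennaRNA python bindings when
installed; ``nussinov`` is a zero-dependency maximum-pairing fallback
(Watson-Crick + GU wobble, minimum hairpin loop 3, energy = -1 per pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SmallRNARecord, to_rna

DEFAULT_KS = (1, 2, 3, 4, 5, 7)
MAX_LEN = 50
NT_ORDER = "ACGT"

# internal DNA alphabet; GU wobble is GT here
_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_HAIRPIN = 3

ALPHABETS = {
    "primary": set("ACGT"),
    "dotbracket": set("().'"),
    "elements": set("ftsimh"),
    "eightterm": set("ACGTacgt"),
}


@dataclass
class SecondaryStructure:
    """Dot-bracket string, element string, free energy, 8-term string."""

    dot_bracket: str
    elements: str
    free_energy: float
    eight_term: str


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def nussinov_fold(sequence: str, min_hairpin: int = MIN_HAIRPIN) -> tuple[str, float]:
    """Maximum base-pairing dot-bracket via the Nussinov recursion.

    A pair (i, j) requires j - i > min_hairpin. Ties resolve toward the
    unpaired branch, then the smallest split point, so output is deterministic.
    Energy is -1.0 per pair.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n < 1:
        raise ValueError("sequence must be non-empty")
    dp = np.zeros((n, n), dtype=int)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j] if i + 1 <= j else 0
            for k in range(i + min_hairpin + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    left = dp[i + 1, k - 1] if i + 1 <= k - 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i, j] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        if i >= j or dp[i, j] == 0:
            return
        if dp[i, j] == dp[i + 1, j]:
            trace(i + 1, j)
            return
        for k in range(i + min_hairpin + 1, j + 1):
            if _can_pair(seq[i], seq[k]):
                left = dp[i + 1, k - 1] if i + 1 <= k - 1 else 0
                right = dp[k + 1, j] if k + 1 <= j else 0
                if dp[i, j] == 1 + left + right:
                    structure[i], structure[k] = "(", ")"
                    trace(i + 1, k - 1)
                    trace(k + 1, j)
                    return
        raise AssertionError("traceback failed")  # pragma: no cover

    trace(0, n - 1)
    db = "".join(structure)
    return db, -1.0 * db.count("(")


def vienna_fold(sequence: str) -> tuple[str, float]:
    """Fold with the ViennaRNA bindings (RNAfold MFE)."""
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "ViennaRNA python bindings are not installed; "
            "use backend='nussinov' or install the 'ViennaRNA' package"
        ) from exc
    db, mfe = RNA.fold(to_rna(sequence))  # pragma: no cover
    return db, float(mfe)  # pragma: no cover


def fold(sequence: str, backend: str = "nussinov") -> SecondaryStructure:
    """Predict secondary structure; elements and 8-term are filled in."""
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    if "N" in sequence.upper():
        raise ValueError("cannot fold sequences containing N")
    if backend == "nussinov":
        db, energy = nussinov_fold(sequence)
    elif backend == "vienna":
        db, energy = vienna_fold(sequence)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return SecondaryStructure(
        dot_bracket=db,
        elements=annotate_elements(db),
        free_energy=energy,
        eight_term=eight_term(sequence, db),
    )


# ---------------------------------------------------------------------------
# Structural annotation
# ---------------------------------------------------------------------------

def pair_table(dot_bracket: str) -> dict[int, int]:
    """0-based partner map from a balanced, non-crossing dot-bracket."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unclosed '(' at position {stack[-1]}")
    return pairs


def annotate_elements(dot_bracket: str) -> str:
    """Per-position structural element letters over {f,t,s,i,m,h}.

    Paired positions are stems (s). An unpaired position takes its type from
    the closest enclosing pair: no enclosed helix -> hairpin (h), one -> interior
    loop/bulge (i), two or more -> multiloop segment (m). Unpaired positions
    outside all pairs are five-prime (f) before the first paired base,
    three-prime (t) after the last, and exterior multiloop (m) in between.
    """
    pairs = pair_table(dot_bracket)
    n = len(dot_bracket)
    out = ["?"] * n

    # number of helix children directly inside each enclosing pair's loop,
    # and the closest enclosing pair per position
    enclosing = [-1] * n  # index of the '(' of the closest enclosing pair
    children: dict[int, int] = {-1: 0}
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            parent = stack[-1] if stack else -1
            if i in pairs:
                # new helix child unless continuing a stacked helix
                if not (stack and stack[-1] == i - 1 and pairs[stack[-1]] == pairs[i] + 1):
                    children[parent] = children.get(parent, 0) + 1
            children.setdefault(i, 0)
            stack.append(i)
            enclosing[i] = parent
        elif c == ")":
            stack.pop()
            enclosing[i] = stack[-1] if stack else -1
        else:
            enclosing[i] = stack[-1] if stack else -1

    paired_positions = sorted(pairs)
    first_paired = paired_positions[0] if paired_positions else None
    last_paired = paired_positions[-1] if paired_positions else None

    for i in range(n):
        if i in pairs:
            out[i] = "s"
            continue
        enc = enclosing[i]
        if enc == -1:
            if first_paired is None or i < first_paired:
                out[i] = "f"
            elif i > last_paired:
                out[i] = "t"
            else:
                out[i] = "m"
        else:
            k = children.get(enc, 0)
            out[i] = "h" if k == 0 else ("i" if k == 1 else "m")
    return "".join(out)


def eight_term(sequence: str, dot_bracket: str) -> str:
    """Sequence letters upper-cased at paired (bracket) positions, else lower."""
    if len(sequence) != len(dot_bracket):
        raise ValueError(
            f"length mismatch: sequence {len(sequence)} vs structure {len(dot_bracket)}"
        )
    seq = sequence.upper().replace("U", "T")
    return "".join(
        s.upper() if b in "()" else s.lower() for s, b in zip(seq, dot_bracket)
    )


# ---------------------------------------------------------------------------
# K-mer features
# ---------------------------------------------------------------------------

def kmer_features(
    token_string: str,
    ks: Iterable[int] = DEFAULT_KS,
    alphabet: set[str] | None = None,
    prefix: str = "",
) -> dict[str, float]:
    """Sparse k-mer frequencies: count / (L - k + 1) per observed k-mer.

    Frequencies for a fixed k sum to 1 whenever L >= k; k > L emits nothing.
    """
    if alphabet is not None:
        for pos, ch in enumerate(token_string):
            if ch not in alphabet:
                raise ValueError(f"character {ch!r} at position {pos} outside alphabet")
    L = len(token_string)
    out: dict[str, float] = {}
    for k in sorted(set(ks)):
        if k < 1:
            raise ValueError(f"k must be positive, got {k}")
        if k > L:
            continue
        denom = L - k + 1
        counts: dict[str, int] = {}
        for i in range(denom):
            tok = token_string[i : i + k]
            counts[tok] = counts.get(tok, 0) + 1
        for tok, c in counts.items():
            out[f"{prefix}{k}mer_{tok}"] = c / denom
    return out


def assemble_features(
    record: SmallRNARecord,
    structure: SecondaryStructure,
    ks: Iterable[int] = DEFAULT_KS,
) -> dict[str, float]:
    """Full named feature vector for one record.

    K-mers over the four representations, plus raw and per-nucleotide free
    energy and the sequence length. Unobserved k-mers are implicit zeros; the
    union schema is materialized at matrix export (see ``feature_matrix``).
    """
    reps = {
        "primary": record.sequence,
        "dotbracket": structure.dot_bracket,
        "elements": structure.elements,
        "eightterm": structure.eight_term,
    }
    feats: dict[str, float] = {}
    for name, tokens in reps.items():
        feats.update(kmer_features(tokens, ks, ALPHABETS[name], prefix=f"{name}_"))
    L = len(record.sequence)
    feats["free_energy"] = structure.free_energy
    feats["free_energy_per_nt"] = structure.free_energy / L
    feats["length"] = float(L)
    return feats


def feature_matrix(
    feature_dicts: Sequence[Mapping[str, float]],
) -> tuple[np.ndarray, list[str]]:
    """Dense matrix over the union feature schema, zeros for absent features."""
    names = sorted({k for d in feature_dicts for k in d})
    index = {n: j for j, n in enumerate(names)}
    X = np.zeros((len(feature_dicts), len(names)), dtype=float)
    for i, d in enumerate(feature_dicts):
        for k, v in d.items():
            X[i, index[k]] = v
    return X, names


def featurize_records(
    records: Sequence[SmallRNARecord],
    backend: str = "nussinov",
    ks: Iterable[int] = DEFAULT_KS,
) -> tuple[np.ndarray, list[str]]:
    """Fold + assemble features for a record collection."""
    dicts = [assemble_features(r, fold(r.sequence, backend), ks) for r in records]
    return feature_matrix(dicts)


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def encode_onehot(
    sequences: Sequence[str] | Sequence[SmallRNARecord],
    max_len: int = MAX_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-length 4-channel one-hot batch plus validity mask.

    Longer sequences keep their first ``max_len`` nucleotides (the 5' end);
    shorter ones are right-padded with all-zero columns (mask 0). 'N' encodes
    as an all-zero column with mask 1 — the masking symbol used by the
    interpretation module.
    """
    seqs = [s.sequence if isinstance(s, SmallRNARecord) else str(s).upper().replace("U", "T") for s in sequences]
    n = len(seqs)
    X = np.zeros((n, max_len, 4), dtype=np.float32)
    mask = np.zeros((n, max_len), dtype=np.float32)
    idx = {c: i for i, c in enumerate(NT_ORDER)}
    for r, seq in enumerate(seqs):
        seq = seq[:max_len]
        for p, ch in enumerate(seq):
            mask[r, p] = 1.0
            if ch in idx:
                X[r, p, idx[ch]] = 1.0
            elif ch != "N":
                raise ValueError(f"cannot one-hot encode character {ch!r}")
    return X, mask


__all__ = [
    "SecondaryStructure",
    "DEFAULT_KS",
    "MAX_LEN",
    "NT_ORDER",
    "fold",
    "nussinov_fold",
    "vienna_fold",
    "pair_table",
    "annotate_elements",
    "eight_term",
    "kmer_features",
    "assemble_features",
    "feature_matrix",
    "featurize_records",
    "encode_onehot",
]
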