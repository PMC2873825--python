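"""Pair encodings, profile centers, and dataset statistics.

A residue pair (i, j) is encoded as the concatenation of profile rows
under three windows: one of length ``w_flank`` centred at i, one of
length ``w_mid`` centred at the integer midpoint (i + j) // 2, and one
of length ``w_flank`` centred at j.  Rows outside 1..L are zero-padded.
With defaults 9/5/9 and 20 profile columns the vector has
20 * (9 + 5 + 9) = 460 entries, L1-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from gacontact.contacts import LabeledPair
from gacontact.profile_io import CANONICAL_AA, ProfileMatrix

DEFAULT_W_FLANK = 9
DEFAULT_W_MID = 5


@dataclass
class SPVector:
    """Encoded residue pair: 20 * (2*w_flank + w_mid) non-negative
    reals summing to 1 (unless the raw windows were all zero)."""

    chain_id: str
    i: int
    j: int
    values: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SPCenter:
    """Mean encoded vector of one contact class.

    ``provenance`` is "per_chain" (mean over one chain's pairs) or
    "test_pooled" (mean over training-chain centers); ``m`` is the
    count averaged over.
    """

    class_id: int
    vector: np.ndarray
    provenance: str
    m: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.class_id not in (0, 1):
            raise ValueError("class_id must be 0 or 1")
        if np.any(self.vector < 0):
            raise ValueError("center vector must be non-negative")


def _window_rows(center: int, width: int, L: int) -> np.ndarray:
    """1-based row indices of a window; 0 marks out-of-range (padding)."""
    half = width // 2
    rows = np.arange(center - half, center + half + 1)
    rows[(rows < 1) | (rows > L)] = 0
    return rows


def encode_pair(
    profile: ProfileMatrix,
    i: int,
    j: int,
    w_flank: int = DEFAULT_W_FLANK,
    w_mid: int = DEFAULT_W_MID,
    label: int | None = None,
) -> SPVector:
    """Encode one residue pair into an L1-normalized window vector."""
    if i >= j:
        raise ValueError("requires i < j")
    if w_flank % 2 == 0 or w_mid % 2 == 0:
        raise ValueError("window sizes must be odd")
    L = profile.length
    if not (1 <= i and j <= L):
        raise ValueError(f"pair ({i},{j}) out of range 1..{L}")
    padded = np.vstack([np.zeros((1, 20)), profile.matrix])  # row 0 = padding
    rows = np.concatenate(
        [
            _window_rows(i, w_flank, L),
            _window_rows((i + j) // 2, w_mid, L),
            _window_rows(j, w_flank, L),
        ]
    )
    raw = padded[rows].ravel()
    total = raw.sum()
    values = raw / total if total > 0 else raw
    return SPVector(chain_id=profile.chain_id, i=i, j=j, values=values, label=label)


def encode_pairs(
    profile: ProfileMatrix,
    pairs: Sequence[tuple[int, int]],
    w_flank: int = DEFAULT_W_FLANK,
    w_mid: int = DEFAULT_W_MID,
) -> np.ndarray:
    """Vectorized encoding of many pairs; returns an (n, dim) matrix
    whose rows match :func:`encode_pair` output exactly."""
    if w_flank % 2 == 0 or w_mid % 2 == 0:
        raise ValueError("window sizes must be odd")
    L = profile.length
    padded = np.vstack([np.zeros((1, 20)), profile.matrix])
    ii = np.asarray([p[0] for p in pairs], dtype=int)
    jj = np.asarray([p[1] for p in pairs], dtype=int)
    if len(ii) == 0:
        return np.zeros((0, 20 * (2 * w_flank + w_mid)))
    if np.any(ii >= jj) or np.any(ii < 1) or np.any(jj > L):
        raise ValueError("invalid pair indices")

    def block(centers: np.ndarray, width: int) -> np.ndarray:
        half = width // 2
        rows = centers[:, None] + np.arange(-half, half + 1)[None, :]
        rows = np.where((rows < 1) | (rows > L), 0, rows)
        return padded[rows].reshape(len(centers), width * 20)

    raw = np.hstack([block(ii, w_flank), block((ii + jj) // 2, w_mid), block(jj, w_flank)])
    totals = raw.sum(axis=1, keepdims=True)
    return np.divide(raw, totals, out=raw, where=totals > 0)


def spc_per_chain(samples: Iterable[SPVector], class_id: int) -> SPCenter:
    """Mean encoded vector over one chain's pairs of the given class."""
    vectors = [s.values for s in samples if s.label == class_id]
    if not vectors:
        raise ValueError(f"empty class {class_id}: no samples to average")
    return SPCenter(
        class_id=class_id,
        vector=np.mean(vectors, axis=0),
        provenance="per_chain",
        m=len(vectors),
    )


def spc_for_test(per_chain_centers: Sequence[SPCenter], class_id: int) -> SPCenter:
    """Pooled test-time center: mean over training-chain centers."""
    if not per_chain_centers:
        raise ValueError("empty center list")
    for c in per_chain_centers:
        if c.class_id != class_id:
            raise ValueError("all centers must share the requested class")
    dims = {len(c.vector) for c in per_chain_centers}
    if len(dims) != 1:
        raise ValueError("center dimensions disagree")
    return SPCenter(
        class_id=class_id,
        vector=np.mean([c.vector for c in per_chain_centers], axis=0),
        provenance="test_pooled",
        m=len(per_chain_centers),
    )


@dataclass
class CompositionResult:
    """Per-amino-acid occurrence fractions among pair members, one
    distribution per class; fractions sum to 1 within each class."""

    contact_fractions: dict[str, float]
    noncontact_fractions: dict[str, float] | None  # None when no class-0 pairs
    skipped_unknown: int


def aa_contact_composition(
    pairs: Sequence[LabeledPair],
    residues: Mapping[str, str],
) -> CompositionResult:
    """Tally amino-acid occurrences over pair members per class.

    Both members of each pair are counted.  Residue letters outside the
    20 standard amino acids are skipped and counted in
    ``skipped_unknown``.
    """
    counts = {0: dict.fromkeys(CANONICAL_AA, 0), 1: dict.fromkeys(CANONICAL_AA, 0)}
    skipped = 0
    for p in pairs:
        seq = residues[p.chain_id]
        for idx in (p.i, p.j):
            aa = seq[idx - 1]
            if aa in counts[p.label]:
                counts[p.label][aa] += 1
            else:
                skipped += 1
    totals = {k: sum(counts[k].values()) for k in (0, 1)}
    if totals[1] == 0:
        raise ValueError("no contact pairs: class-1 composition undefined")
    noncontact = (
        {a: counts[0][a] / totals[0] for a in CANONICAL_AA} if totals[0] else None
    )
    return CompositionResult(
        contact_fractions={a: counts[1][a] / totals[1] for a in CANONICAL_AA},
        noncontact_fractions=noncontact,
        skipped_unknown=skipped,
    )


def aa_propensity_log2(composition: CompositionResult) -> dict[str, float | None]:
    """log2(contact fraction / non-contact fraction) per amino acid;
    None where either fraction is zero (undefined, not +/- inf)."""
    if composition.noncontact_fractions is None:
        raise ValueError("propensities need both class compositions")
    out: dict[str, float | None] = {}
    for aa in CANONICAL_AA:
        fc = composition.contact_fractions[aa]
        fn = composition.noncontact_fractions[aa]
        out[aa] = float(np.log2(fc / fn)) if fc > 0 and fn > 0 else None
    return out


def fit_length_contact_line(
    lengths: Sequence[float], contact_counts: Sequence[float]
) -> tuple[float, float]:
    """OLS fit of contact count against chain length -> (slope, intercept)."""
    lengths = np.asarray(lengths, dtype=float)
    contact_counts = np.asarray(contact_counts, dtype=float)
    if len(lengths) < 2 or len(lengths) != len(contact_counts):
        raise ValueError("need >= 2 (length, count) points")
    if np.ptp(lengths) == 0:
        raise ValueError("all lengths identical: slope undefined")
    res = stats.linregress(lengths, contact_counts)
    return float(res.slope), float(res.intercept)
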