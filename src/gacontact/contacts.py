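"""Contact maps and long-range pair labelling.

A long-range pair is (i, j) with j - i >= min_sep (default 24); it is a
contact when the C-alpha distance is <= cutoff (default 8 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from gacontact.profile_io import CaTrace

DEFAULT_CUTOFF = 8.0
DEFAULT_MIN_SEP = 24


@dataclass
class ContactMap:
    """Upper-triangle set of long-range contacts for one chain."""

    chain_id: str
    length: int
    cutoff: float = DEFAULT_CUTOFF
    min_sep: int = DEFAULT_MIN_SEP
    contact_pairs: frozenset = field(default_factory=frozenset)
    #: 1-based indices of residues without a C-alpha; pairs touching
    #: these are undefined and excluded from labelling.
    missing_residues: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.contact_pairs = frozenset(tuple(p) for p in self.contact_pairs)
        self.missing_residues = frozenset(self.missing_residues)
        for i, j in self.contact_pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range 1..{self.length}")
            if j - i < self.min_sep:
                raise ValueError(f"pair ({i},{j}) violates separation >= {self.min_sep}")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_pairs)


@dataclass(frozen=True)
class LabeledPair:
    chain_id: str
    i: int
    j: int
    label: int  # 1 = long-range contact, 0 = long-range non-contact


def build_contact_map(
    trace: CaTrace,
    cutoff: float = DEFAULT_CUTOFF,
    min_sep: int = DEFAULT_MIN_SEP,
) -> ContactMap:
    """Compute the long-range contact map of a C-alpha trace.

    (i, j) is a contact iff both C-alphas are present, j - i >= min_sep
    and the Euclidean distance is <= cutoff.  Chains too short to have
    any long-range pair yield an empty map.
    """
    L = len(trace)
    missing = frozenset((np.flatnonzero(trace.missing_mask) + 1).tolist())
    pairs: set[tuple[int, int]] = set()
    present = np.flatnonzero(~trace.missing_mask)
    if len(present) >= 2:
        dmat = squareform(pdist(trace.coords[present]))
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                i, j = int(present[a]) + 1, int(present[b]) + 1
                if j - i >= min_sep and dmat[a, b] <= cutoff:
                    pairs.add((i, j))
    return ContactMap(
        chain_id=trace.chain_id,
        length=L,
        cutoff=cutoff,
        min_sep=min_sep,
        contact_pairs=frozenset(pairs),
        missing_residues=missing,
    )


def enumerate_long_range_pairs(L: int, min_sep: int = DEFAULT_MIN_SEP) -> list[tuple[int, int]]:
    """All (i, j) with 1 <= i < j <= L and j - i >= min_sep, in
    lexicographic order; (L-s)(L-s+1)/2 pairs when L > s."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return [(i, j) for i in range(1, L + 1) for j in range(i + min_sep, L + 1)]


def label_long_range_pairs(cm: ContactMap) -> list[LabeledPair]:
    """Label every long-range pair of the chain; pairs touching a
    residue with no C-alpha are dropped entirely."""
    out: list[LabeledPair] = []
    for i, j in enumerate_long_range_pairs(cm.length, cm.min_sep):
        if i in cm.missing_residues or j in cm.missing_residues:
            continue
        out.append(LabeledPair(cm.chain_id, i, j, int((i, j) in cm.contact_pairs)))
    return out
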