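"""File I/O: C-alpha traces from PDB, profile tables, RR predictions, models.

Formats are deliberately plain text: a whitespace-delimited profile
table (header ``idx aa A R N D ...``), CASP RR-style contact lines, and
a versioned JSON model file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

#: Canonical amino-acid column order used everywhere downstream.
CANONICAL_AA = "ARNDCQEGHILKMFPSTWYV"

MODEL_FORMAT_VERSION = 1


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the structure."""


class ProfileFormatError(ValueError):
    """Malformed profile table."""


@dataclass
class CaTrace:
    """C-alpha coordinates of one chain, renumbered sequentially 1..L.

    ``coords[k]`` is NaN and ``missing_mask[k]`` is True for residues
    that have no C-alpha atom.
    """

    chain_id: str
    residue_numbers: np.ndarray  # (L,) int, 1..L
    coords: np.ndarray  # (L, 3) float, Angstrom
    missing_mask: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        L = len(self.residue_numbers)
        if self.coords.shape != (L, 3):
            raise ValueError("coords length must equal residue_numbers length")
        if self.missing_mask.shape != (L,):
            raise ValueError("missing_mask length must equal residue_numbers length")
        if L and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass
class ProfileMatrix:
    """Per-residue 20-column sequence profile for one chain."""

    chain_id: str
    residues: str
    matrix: np.ndarray  # (L, 20), non-negative, columns in CANONICAL_AA order
    column_order: str = CANONICAL_AA

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("profile matrix must be L x 20")
        if self.matrix.shape[0] != len(self.residues):
            raise ValueError("row count must equal residue string length")
        if np.any(self.matrix < 0):
            raise ValueError("profile entries must be non-negative")
        if len(set(self.column_order)) != 20:
            raise ValueError("column_order must name 20 distinct amino acids")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PredictionSet:
    """Scored long-range pair predictions for one chain.

    Lower score = more contact-like.
    """

    chain_id: str
    records: list[tuple[int, int, float, int]]  # (i, j, score, label)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        min_sep = int(self.metadata.get("min_sep", 1))
        for i, j, _, _ in self.records:
            if i >= j:
                raise ValueError(f"record ({i},{j}) violates i < j")
            if j - i < min_sep:
                raise ValueError(f"record ({i},{j}) violates separation >= {min_sep}")


def read_pdb_ca(path: str | Path, chain_id: str) -> CaTrace:
    """Extract the C-alpha trace of one chain from a PDB file.

    Residues are taken in file order and renumbered 1..L; residues with
    distinct insertion codes count as distinct residues.  Alternate
    locations resolve to the highest-occupancy atom (Biopython's
    default, first wins on ties).  Residues without a C-alpha get NaN
    coordinates and a True ``missing_mask`` entry.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("chain", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    chain = model[chain_id]
    coords: list[np.ndarray] = []
    missing: list[bool] = []
    for residue in chain:
        hetflag = residue.id[0]
        if hetflag != " ":
            continue  # ATOM records only
        if "CA" in residue:
            coords.append(np.asarray(residue["CA"].coord, dtype=float))
            missing.append(False)
        else:
            coords.append(np.full(3, np.nan))
            missing.append(True)
    if not coords or all(missing):
        raise ValueError(f"no CA records in chain {chain_id!r}")
    L = len(coords)
    return CaTrace(
        chain_id=chain_id,
        residue_numbers=np.arange(1, L + 1),
        coords=np.vstack(coords),
        missing_mask=np.asarray(missing, dtype=bool),
    )


def read_profile_table(path: str | Path, chain_id: str | None = None) -> ProfileMatrix:
    """Read a whitespace-delimited profile table.

    Expected header: ``idx aa`` followed by the 20 amino-acid columns in
    any order; one row per residue.  Columns are reordered into
    :data:`CANONICAL_AA` order.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ProfileFormatError(f"cannot parse profile table {path}: {exc}") from exc
    for col in ("idx", "aa"):
        if col not in df.columns:
            raise ProfileFormatError(f"missing required column {col!r}")
    missing_cols = [a for a in CANONICAL_AA if a not in df.columns]
    if missing_cols:
        raise ProfileFormatError(f"missing amino-acid columns: {missing_cols}")
    idx = df["idx"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        raise ProfileFormatError("idx column must run 1..L")
    values = df[list(CANONICAL_AA)].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ProfileFormatError("non-numeric profile entry")
    if np.any(~np.isfinite(values)):
        raise ProfileFormatError("non-finite profile entry")
    if np.any(values < 0):
        raise ProfileFormatError("negative profile entry")
    residues = "".join(df["aa"].astype(str))
    if chain_id is None:
        chain_id = Path(path).stem
    return ProfileMatrix(chain_id=chain_id, residues=residues, matrix=values)


def write_profile_table(profile: ProfileMatrix, path: str | Path) -> None:
    """Write a :class:`ProfileMatrix` in the table format read back by
    :func:`read_profile_table`."""
    with open(path, "w") as fh:
        fh.write("idx\taa\t" + "\t".join(CANONICAL_AA) + "\n")
        for k in range(profile.length):
            row = "\t".join(f"{v:.6f}" for v in profile.matrix[k])
            fh.write(f"{k + 1}\t{profile.residues[k]}\t{row}\n")


# Floor for the RR probability column so it stays in (0, 1].
_RR_MIN_PROB = 1e-3


def write_rr(predictions: PredictionSet, path: str | Path) -> None:
    """Write predictions as CASP RR-style lines ``i j 0 <cutoff> p``.

    Records must already be sorted most-contact-like first (ascending
    score); the probability column is ``1 - score`` floored at 0.001.
    """
    scores = [r[2] for r in predictions.records]
    if any(b < a for a, b in zip(scores, scores[1:])):
        raise ValueError("records must be sorted by score (ascending) before writing")
    cutoff = predictions.metadata.get("cutoff", 8.0)
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {predictions.chain_id}\n")
        for i, j, score, _label in predictions.records:
            p = max(_RR_MIN_PROB, min(1.0, 1.0 - score))
            fh.write(f"{i} {j} 0 {cutoff:g} {p:.3f}\n")
        fh.write("END\n")


def read_rr(path: str | Path, chain_id: str | None = None) -> PredictionSet:
    """Read an RR file back into a :class:`PredictionSet`.

    The stored score is ``1 - p`` so write/read is an involution up to
    the probability floor; labels are reconstructed as 1 for p > 0.5.
    """
    records: list[tuple[int, int, float, int]] = []
    target = chain_id
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "TARGET" and target is None and len(parts) > 1:
                target = parts[1]
                continue
            if len(parts) == 5:
                try:
                    i, j = int(parts[0]), int(parts[1])
                    p = float(parts[4])
                except ValueError:
                    continue
                records.append((i, j, 1.0 - p, int(p > 0.5)))
    return PredictionSet(chain_id=target or "unknown", records=records)


def save_model(model, path: str | Path) -> None:
    """Serialize a trained ensemble to a versioned JSON file."""
    from gacontact.ensemble import EnsembleModel

    if not isinstance(model, EnsembleModel):
        raise TypeError("save_model expects an EnsembleModel")
    if not model.gacs:
        raise ValueError("no classifiers in ensemble")
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    """Load an ensemble saved by :func:`save_model`, validating version
    and chromosome alphabet."""
    from gacontact.ensemble import EnsembleModel

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model file: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version mismatch: file has {version}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    model = EnsembleModel.from_dict(payload["model"])
    if not model.gacs:
        raise ValueError("no classifiers in ensemble")
    return model


def residues_by_chain(profiles: Sequence[ProfileMatrix]) -> dict[str, str]:
    """Convenience: map chain_id -> residue string."""
    return {p.chain_id: p.residues for p in profiles}
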