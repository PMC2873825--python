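"""Synthetic fixture data: folded-chain geometry, class-conditional
profiles, and planted-separation vector sets for GA unit tests.

Chains are excluded-volume random walks confined to a sphere whose
radius is chosen so the number of geometry-derived long-range contacts
grows roughly linearly in chain length with a configurable slope.
Residues participating in long-range contacts are enriched for the
hydrophobic letters C/V/I/L and depleted of E/D/K, so the downstream
composition/propensity statistics recover the construction by sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gacontact.contacts import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_SEP,
    ContactMap,
    LabeledPair,
    build_contact_map,
    label_long_range_pairs,
)
from gacontact.ensemble import ChainData
from gacontact.profile_io import CANONICAL_AA, CaTrace, ProfileMatrix, write_profile_table

HYDROPHOBIC = "CVIL"  # enriched in contacts
HYDROPHILIC = "EDK"  # depleted in contacts

# Empirical calibration of the confinement radius.  For this walk
# model simulation shows long-range contacts ~ (C / r0**3) * (L-s)**2
# / L * phi(L), with radius = r0 * L**(1/3), s the minimum separation
# and phi a small residual length trend; constants fitted over r0 in
# [2.8, 4.2], L in [40, 140].  Inverting for a target
# contacts-per-residue slope holds within ~10% for slopes near 1.0 and
# within ~25% over [0.6, 1.6].
_C_GEOM = 95.0
_PHI_0, _PHI_1 = 0.95, 0.0015  # phi(L) = _PHI_0 + _PHI_1 * L
_R0_MIN = 2.45  # hard floor: tighter spheres jam the excluded-volume walk


@dataclass
class SyntheticConfig:
    n_chains: int = 30
    length_range: tuple[int, int] = (60, 110)
    step_length: float = 3.8
    min_distance: float = 3.5  # excluded-volume hard core
    contact_slope: float = 1.0  # target long-range contacts per residue
    enrichment: float = 1.0  # hydrophobic enrichment strength (delta)
    concentration: float = 50.0  # profile Dirichlet concentration (kappa)
    cutoff: float = DEFAULT_CUTOFF
    min_sep: int = DEFAULT_MIN_SEP
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.length_range[0] < 30:
            raise ValueError("minimum chain length must be >= 30")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_chains < 0:
            raise ValueError("n_chains must be >= 0")


def _confinement_radius(L: int, slope: float, min_sep: int = DEFAULT_MIN_SEP) -> float:
    phi = _PHI_0 + _PHI_1 * L
    r0 = (_C_GEOM * phi * (L - min_sep) ** 2 / (slope * L * L)) ** (1.0 / 3.0)
    return max(r0, _R0_MIN) * L ** (1.0 / 3.0)


def _confined_walk(
    L: int,
    radius: float,
    rng: np.random.Generator,
    step: float,
    min_dist: float,
    max_step_tries: int = 80,
    max_restarts: int = 40,
) -> np.ndarray:
    """Self-avoiding random walk of L beads inside a sphere."""
    for _ in range(max_restarts):
        pts = np.empty((L, 3))
        pts[0] = rng.normal(size=3)
        pts[0] *= (radius / 2) * rng.random() ** (1 / 3) / np.linalg.norm(pts[0])
        ok = True
        for k in range(1, L):
            placed = False
            for _try in range(max_step_tries):
                d = rng.normal(size=3)
                d *= step / np.linalg.norm(d)
                cand = pts[k - 1] + d
                if np.linalg.norm(cand) > radius:
                    continue
                if k >= 2:
                    dists = np.linalg.norm(pts[: k - 1] - cand, axis=1)
                    if dists.min() < min_dist:
                        continue
                pts[k] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise RuntimeError(f"failed to place a {L}-residue walk after {max_restarts} restarts")


def _letter_weights(in_contact: bool, delta: float) -> np.ndarray:
    sign = np.zeros(20)
    for aa in HYDROPHOBIC:
        sign[CANONICAL_AA.index(aa)] = 1.0
    for aa in HYDROPHILIC:
        sign[CANONICAL_AA.index(aa)] = -1.0
    w = np.exp((delta if in_contact else -delta) * sign)
    return w / w.sum()


def generate_chain(
    cfg: SyntheticConfig, rng: np.random.Generator, chain_id: str = "synth"
) -> tuple[CaTrace, ProfileMatrix]:
    """Generate one chain: geometry, letters, and profile rows.

    Letters are assigned after the geometry so that residues taking
    part in at least one long-range contact are drawn from a
    hydrophobic-tilted distribution (tilt ``enrichment``); profile rows
    are Dirichlet draws centred on a mix of the residue identity and
    its class composition, with concentration ``concentration``.
    """
    L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    radius = _confinement_radius(L, cfg.contact_slope, cfg.min_sep)
    coords = _confined_walk(L, radius, rng, cfg.step_length, cfg.min_distance)
    trace = CaTrace(
        chain_id=chain_id,
        residue_numbers=np.arange(1, L + 1),
        coords=coords,
        missing_mask=np.zeros(L, dtype=bool),
    )
    cm = build_contact_map(trace, cfg.cutoff, cfg.min_sep)
    in_contact = np.zeros(L, dtype=bool)
    for i, j in cm.contact_pairs:
        in_contact[i - 1] = True
        in_contact[j - 1] = True

    w_contact = _letter_weights(True, cfg.enrichment)
    w_free = _letter_weights(False, cfg.enrichment)
    letters = []
    rows = np.empty((L, 20))
    aa_idx = {a: k for k, a in enumerate(CANONICAL_AA)}
    for k in range(L):
        w = w_contact if in_contact[k] else w_free
        aa = CANONICAL_AA[rng.choice(20, p=w)]
        letters.append(aa)
        onehot = np.zeros(20)
        onehot[aa_idx[aa]] = 1.0
        center = 0.6 * onehot + 0.4 * w
        rows[k] = rng.dirichlet(cfg.concentration * center + 0.02)
    profile = ProfileMatrix(chain_id=chain_id, residues="".join(letters), matrix=rows)
    return trace, profile


@dataclass
class SyntheticChain:
    chain_id: str
    trace: CaTrace
    profile: ProfileMatrix
    contact_map: ContactMap
    labeled_pairs: list[LabeledPair] = field(repr=False)

    def as_chain_data(self, group: str | None = None) -> ChainData:
        return ChainData(
            chain_id=self.chain_id,
            profile=self.profile,
            contact_map=self.contact_map,
            group=group,
        )


def generate_dataset(cfg: SyntheticConfig) -> list[SyntheticChain]:
    """Generate ``cfg.n_chains`` chains with derived per-chain seeds."""
    master = np.random.SeedSequence(cfg.rng_seed)
    chains = []
    for k, child in enumerate(master.spawn(cfg.n_chains)):
        rng = np.random.default_rng(child)
        cid = f"syn{k:03d}"
        trace, profile = generate_chain(cfg, rng, chain_id=cid)
        cm = build_contact_map(trace, cfg.cutoff, cfg.min_sep)
        chains.append(
            SyntheticChain(
                chain_id=cid,
                trace=trace,
                profile=profile,
                contact_map=cm,
                labeled_pairs=label_long_range_pairs(cm),
            )
        )
    return chains


def planted_separation_dataset(
    n_pos: int,
    n_neg: int,
    n_informative: int,
    n_noise: int,
    separation: float,
    rng: np.random.Generator,
    concentration: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-normalized vectors whose class means differ only on the first
    ``n_informative`` dimensions, by total L1 mass ``separation``.

    The shift alternates in sign across the informative dimensions
    (positives up on even ones, down on odd ones; negatives reversed)
    so it is mass-balanced and the noise dimensions keep identical mean
    mass in both classes.  Samples are Dirichlet draws around the class
    mean; ``concentration`` sets the within-class noise.  Returns
    (X, y) with positives first.
    """
    d = n_informative + n_noise
    if d < 1 or n_informative < 2:
        raise ValueError("need at least two informative dimensions")
    if not 0.0 <= separation < 1.0:
        raise ValueError("separation must be in [0, 1)")
    # informative block carries half the mass (all of it when there is
    # no noise block), so any separation < 1 is representable
    info_mass = 0.5 if n_noise else 1.0
    base = np.empty(d)
    base[:n_informative] = info_mass / n_informative
    if n_noise:
        base[n_informative:] = (1.0 - info_mass) / n_noise
    delta = separation / (2.0 * n_informative)
    if delta >= base[0]:
        raise ValueError("separation too large for this dimensionality")
    shift = np.zeros(d)
    n_paired = n_informative - (n_informative % 2)
    shift[0:n_paired:2] = delta
    shift[1:n_paired:2] = -delta
    mean_pos = base + shift
    mean_neg = base - shift
    X_pos = rng.dirichlet(concentration * mean_pos + 1e-3, size=n_pos)
    X_neg = rng.dirichlet(concentration * mean_neg + 1e-3, size=n_neg)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return X, y


_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb_ca(trace: CaTrace, residues: str, path: str | Path, chain_id: str = "A") -> None:
    """Write a C-alpha-only PDB file (3-decimal coordinate columns)."""
    with open(path, "w") as fh:
        serial = 1
        for k in range(len(trace)):
            if trace.missing_mask[k]:
                continue
            x, y, z = trace.coords[k]
            resname = _AA_1TO3.get(residues[k], "GLY")
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname} {chain_id}{trace.residue_numbers[k]:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
            serial += 1
        fh.write("END\n")


def write_dataset(chains: list[SyntheticChain], outdir: str | Path) -> dict[str, dict[str, str]]:
    """Write each chain as PDB + profile TSV + truth contact TSV;
    returns {chain_id: {"pdb": ..., "profile": ..., "contacts": ...}}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for ch in chains:
        pdb = outdir / f"{ch.chain_id}.pdb"
        tsv = outdir / f"{ch.chain_id}.profile.tsv"
        truth = outdir / f"{ch.chain_id}.contacts.tsv"
        write_pdb_ca(ch.trace, ch.profile.residues, pdb)
        write_profile_table(ch.profile, tsv)
        with open(truth, "w") as fh:
            fh.write("i\tj\n")
            for i, j in sorted(ch.contact_map.contact_pairs):
                fh.write(f"{i}\t{j}\n")
        manifest[ch.chain_id] = {"pdb": str(pdb), "profile": str(tsv), "contacts": str(truth)}
    return manifest
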