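"""Undersampling ensemble of GA classifiers and cross-validation driver.

Negative samples are partitioned into disjoint positive-sized subsets;
each subset paired with the full positive set trains one GaC (two
GA-evolved sub-classifiers with nearest-centroid decision rules).
Ensemble label: any-positive vote by default (one positive sub-vote
suffices), majority as an alternative.  Ensemble score: mean over GaCs
of d1/(d1+d0), the relative distance to the contact centroid — lower
means more contact-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from gacontact import features as feat
from gacontact import ga_transform as ga
from gacontact.contacts import ContactMap, label_long_range_pairs
from gacontact.profile_io import PredictionSet, ProfileMatrix

VOTE_RULES = ("any_positive", "majority")
DECISION_RULES = ("sub1", "agreement")


@dataclass
class SubClassifier:
    """One trained sub-classifier: chromosome, its compiled
    transformation, and transformed class centroids."""

    target_class: int
    chromosome: str
    c1: np.ndarray
    c0: np.ndarray
    fitness_value: int
    dissimilarity: str = "euclidean"

    def __post_init__(self) -> None:
        self.c1 = np.asarray(self.c1, dtype=float)
        self.c0 = np.asarray(self.c0, dtype=float)
        self._t = ga.compile_chromosome(self.chromosome)
        if self._t.n_features != len(self.c1) or self._t.n_features != len(self.c0):
            raise ValueError("centroid dimension must equal chromosome group count")

    @property
    def transformation(self) -> ga.Transformation:
        return self._t

    def distances(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(d1, d0) distances from transformed rows of X to the two
        transformed centroids."""
        T = ga.apply_matrix(self._t, np.atleast_2d(X))
        return (
            ga._distance(T, self.c1, self.dissimilarity),
            ga._distance(T, self.c0, self.dissimilarity),
        )

    def assign(self, X: np.ndarray) -> np.ndarray:
        d1, d0 = self.distances(X)
        return (d1 < d0).astype(int)  # tie -> class 0


@dataclass
class GaCModel:
    sub1: SubClassifier
    sub0: SubClassifier
    subset_id: int
    seed: int


@dataclass
class EnsembleConfig:
    n_gacs: int = 20
    vote_rule: str = "any_positive"
    decision_rule: str = "sub1"
    subset_size: int | None = None  # None -> |positives|

    def __post_init__(self) -> None:
        if self.n_gacs < 1:
            raise ValueError("n_gacs must be >= 1")
        if self.vote_rule not in VOTE_RULES:
            raise ValueError(f"vote_rule must be one of {VOTE_RULES}")
        if self.decision_rule not in DECISION_RULES:
            raise ValueError(f"decision_rule must be one of {DECISION_RULES}")

    def to_dict(self) -> dict:
        return {
            "n_gacs": self.n_gacs,
            "vote_rule": self.vote_rule,
            "decision_rule": self.decision_rule,
            "subset_size": self.subset_size,
        }


@dataclass
class EnsembleModel:
    """Trained ensemble plus everything needed to reproduce it."""

    gacs: list[GaCModel]
    vote_rule: str = "any_positive"
    decision_rule: str = "sub1"
    input_dim: int = 460
    master_seed: int | None = None
    ga_config: dict = field(default_factory=dict)
    encoding: dict = field(default_factory=dict)  # w_flank, w_mid, cutoff, min_sep
    #: Pooled test-time class centers (mean of per-chain training
    #: centers), stored untransformed for reporting and the SPC-distance
    #: scoring route.
    test_centers: dict = field(default_factory=dict)  # {"1": vector, "0": vector}

    def to_dict(self) -> dict:
        return {
            "vote_rule": self.vote_rule,
            "decision_rule": self.decision_rule,
            "input_dim": self.input_dim,
            "master_seed": self.master_seed,
            "ga_config": self.ga_config,
            "encoding": self.encoding,
            "test_centers": {k: np.asarray(v).tolist() for k, v in self.test_centers.items()},
            "gacs": [
                {
                    "subset_id": g.subset_id,
                    "seed": g.seed,
                    "subs": [
                        {
                            "target_class": s.target_class,
                            "chromosome": s.chromosome,
                            "c1": s.c1.tolist(),
                            "c0": s.c0.tolist(),
                            "fitness": s.fitness_value,
                            "dissimilarity": s.dissimilarity,
                        }
                        for s in (g.sub1, g.sub0)
                    ],
                }
                for g in self.gacs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        gacs = []
        for g in d["gacs"]:
            subs = [
                SubClassifier(
                    target_class=s["target_class"],
                    chromosome=s["chromosome"],
                    c1=np.asarray(s["c1"], dtype=float),
                    c0=np.asarray(s["c0"], dtype=float),
                    fitness_value=int(s["fitness"]),
                    dissimilarity=s.get("dissimilarity", "euclidean"),
                )
                for s in g["subs"]
            ]
            gacs.append(GaCModel(sub1=subs[0], sub0=subs[1], subset_id=g["subset_id"], seed=g["seed"]))
        return cls(
            gacs=gacs,
            vote_rule=d["vote_rule"],
            decision_rule=d.get("decision_rule", "sub1"),
            input_dim=int(d["input_dim"]),
            master_seed=d.get("master_seed"),
            ga_config=d.get("ga_config", {}),
            encoding=d.get("encoding", {}),
            test_centers={k: np.asarray(v, dtype=float) for k, v in d.get("test_centers", {}).items()},
        )


def partition_negatives(
    n_negatives: int,
    n_subsets: int,
    subset_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Draw ``n_subsets`` pairwise-disjoint random index subsets.

    Each subset has size min(subset_size, n_negatives // n_subsets), so
    scarce negatives cap the subset size rather than overlap.  Returns
    index arrays into the negative sample array.
    """
    if n_negatives < 1:
        raise ValueError("negatives must be non-empty")
    if n_negatives < n_subsets:
        raise ValueError(
            f"insufficient negatives: {n_negatives} < {n_subsets} subsets"
        )
    size = min(subset_size, n_negatives // n_subsets)
    if size < 1:
        raise ValueError("insufficient negatives for requested subset count")
    perm = rng.permutation(n_negatives)
    return [perm[k * size : (k + 1) * size] for k in range(n_subsets)]


def _child_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(master_seed), *map(int, key)))
    return int(ss.generate_state(1)[0])


def train_gac(
    positives: np.ndarray,
    negative_subset: np.ndarray,
    ga_config: ga.GaConfig,
    seed: int,
    subset_id: int = 0,
) -> GaCModel:
    """Train one GaC: two GA runs with independent derived seeds, one
    per target class, on the same positive/negative sample pair."""
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negative_subset = np.atleast_2d(np.asarray(negative_subset, dtype=float))
    if positives.shape[0] == 0 or negative_subset.shape[0] == 0:
        raise ValueError("both sample sets must be non-empty")
    X = np.vstack([positives, negative_subset])
    y = np.concatenate([np.ones(len(positives), int), np.zeros(len(negative_subset), int)])
    subs = {}
    for k in (1, 0):
        cfg_k = ga.GaConfig(**{**ga_config.to_dict(), "rng_seed": _child_seed(seed, k)})
        best, history = ga.run_ga(X, y, cfg_k)
        t = ga.compile_chromosome(best)
        if t.n_features == 0:
            # degenerate all-'a' winner: fall back to identity to keep
            # the model usable (fitness 0 recorded)
            best = "b" * X.shape[1]
            t = ga.compile_chromosome(best)
        c1, c0 = ga.centroid_functions(t, positives, negative_subset)
        subs[k] = SubClassifier(
            target_class=k,
            chromosome=best,
            c1=c1,
            c0=c0,
            fitness_value=history[-1].best_fitness,
            dissimilarity=ga_config.dissimilarity,
        )
    return GaCModel(sub1=subs[1], sub0=subs[0], subset_id=subset_id, seed=seed)


def gac_label(gac: GaCModel, x: np.ndarray, decision_rule: str = "sub1") -> int:
    """Label one vector with one GaC.

    ``sub1`` (default): the class assigned by sub-classifier 1's
    nearest-centroid rule.  ``agreement``: 1 only when both
    sub-classifiers assign class 1.
    """
    return int(gac_label_matrix(gac, np.atleast_2d(x), decision_rule)[0])


def gac_label_matrix(gac: GaCModel, X: np.ndarray, decision_rule: str = "sub1") -> np.ndarray:
    a1 = gac.sub1.assign(X)
    if decision_rule == "sub1":
        return a1
    if decision_rule == "agreement":
        return a1 & gac.sub0.assign(X)
    raise ValueError(f"unknown decision rule {decision_rule!r}")


def gac_score_matrix(gac: GaCModel, X: np.ndarray) -> np.ndarray:
    """Per-vector relative distance d1/(d1+d0) to sub1's contact
    centroid; 0.5 where both distances vanish."""
    d1, d0 = gac.sub1.distances(X)
    total = d1 + d0
    return np.divide(d1, total, out=np.full_like(d1, 0.5), where=total > 0)


def ensemble_label(model: EnsembleModel, x: np.ndarray) -> int:
    return int(ensemble_label_matrix(model, np.atleast_2d(x))[0])


def ensemble_label_matrix(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Combine per-GaC labels: 'any_positive' -> 1 iff at least one GaC
    votes 1; 'majority' -> 1 iff more than half vote 1."""
    votes = np.vstack([gac_label_matrix(g, X, model.decision_rule) for g in model.gacs])
    if model.vote_rule == "any_positive":
        return (votes.sum(axis=0) >= 1).astype(int)
    if model.vote_rule == "majority":
        return (votes.sum(axis=0) > len(model.gacs) / 2).astype(int)
    raise ValueError(f"unknown vote rule {model.vote_rule!r}")


def ensemble_score(model: EnsembleModel, x: np.ndarray) -> float:
    return float(ensemble_score_matrix(model, np.atleast_2d(x))[0])


def ensemble_score_matrix(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Mean of per-GaC relative contact-centroid distances; in [0, 1],
    lower = more contact-like."""
    return np.mean([gac_score_matrix(g, X) for g in model.gacs], axis=0)


def ensemble_score_vs_test_centers(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Alternative scoring route: distances to the pooled test-time
    class centers, transformed per GaC by sub1's transformation."""
    if "1" not in model.test_centers or "0" not in model.test_centers:
        raise ValueError("model has no stored test centers")
    c1_raw = np.asarray(model.test_centers["1"], dtype=float)
    c0_raw = np.asarray(model.test_centers["0"], dtype=float)
    scores = []
    for g in model.gacs:
        t = g.sub1.transformation
        T = ga.apply_matrix(t, np.atleast_2d(X))
        tc1 = ga.apply_transformation(t, c1_raw)
        tc0 = ga.apply_transformation(t, c0_raw)
        d1 = ga._distance(T, tc1, g.sub1.dissimilarity)
        d0 = ga._distance(T, tc0, g.sub1.dissimilarity)
        total = d1 + d0
        scores.append(np.divide(d1, total, out=np.full_like(d1, 0.5), where=total > 0))
    return np.mean(scores, axis=0)


def train_ensemble(
    positives: np.ndarray,
    negatives: np.ndarray,
    ga_config: ga.GaConfig,
    ens_config: EnsembleConfig,
    master_seed: int = 0,
) -> EnsembleModel:
    """Train the full undersampling ensemble on encoded sample matrices."""
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    rng = np.random.default_rng(_child_seed(master_seed, 0xA11))
    subset_size = ens_config.subset_size or len(positives)
    subsets = partition_negatives(len(negatives), ens_config.n_gacs, subset_size, rng)
    gacs = []
    for gidx, idx in enumerate(subsets):
        seed = _child_seed(master_seed, 1, gidx)
        gacs.append(train_gac(positives, negatives[idx], ga_config, seed, subset_id=gidx))
    return EnsembleModel(
        gacs=gacs,
        vote_rule=ens_config.vote_rule,
        decision_rule=ens_config.decision_rule,
        input_dim=positives.shape[1],
        master_seed=master_seed,
        ga_config=ga_config.to_dict(),
    )


def two_fold_split(chain_ids: Sequence[str], rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Random chain-level halves (sizes differ by at most one)."""
    ids = list(chain_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 chains for two-fold split")
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    fold_a = [ids[k] for k in sorted(perm[:half])]
    fold_b = [ids[k] for k in sorted(perm[half:])]
    return fold_a, fold_b


@dataclass
class ChainData:
    """One chain's inputs to training/prediction."""

    chain_id: str
    profile: ProfileMatrix
    contact_map: ContactMap
    group: str | None = None


def _encode_chain(chain: ChainData, w_flank: int, w_mid: int):
    pairs = label_long_range_pairs(chain.contact_map)
    X = feat.encode_pairs(chain.profile, [(p.i, p.j) for p in pairs], w_flank, w_mid)
    y = np.asarray([p.label for p in pairs], dtype=int)
    return pairs, X, y


@dataclass
class FoldResult:
    fold_id: str
    train_chains: list[str]
    test_chains: list[str]
    model: EnsembleModel
    predictions: dict[str, PredictionSet]


def run_cross_validation(
    chains: Sequence[ChainData],
    ga_config: ga.GaConfig,
    ens_config: EnsembleConfig,
    master_seed: int = 0,
    w_flank: int = feat.DEFAULT_W_FLANK,
    w_mid: int = feat.DEFAULT_W_MID,
) -> list[FoldResult]:
    """Two-fold cross-validation: train on one chain-level half, score
    every long-range pair of the other half, and vice versa."""
    rng = np.random.default_rng(_child_seed(master_seed, 0xF01D))
    by_id = {c.chain_id: c for c in chains}
    fold_a, fold_b = two_fold_split(sorted(by_id), rng)
    results = []
    for fold_idx, (fold_id, train_ids, test_ids) in enumerate(
        (("A", fold_a, fold_b), ("B", fold_b, fold_a))
    ):
        assert not set(train_ids) & set(test_ids)
        model = train_fold(
            [by_id[c] for c in train_ids], ga_config, ens_config,
            _child_seed(master_seed, 2, fold_idx), w_flank, w_mid,
        )
        predictions = {
            cid: predict_chain(model, by_id[cid], w_flank, w_mid) for cid in test_ids
        }
        results.append(
            FoldResult(
                fold_id=fold_id,
                train_chains=list(train_ids),
                test_chains=list(test_ids),
                model=model,
                predictions=predictions,
            )
        )
    return results


def train_fold(
    train_chains: Sequence[ChainData],
    ga_config: ga.GaConfig,
    ens_config: EnsembleConfig,
    master_seed: int,
    w_flank: int = feat.DEFAULT_W_FLANK,
    w_mid: int = feat.DEFAULT_W_MID,
) -> EnsembleModel:
    """Encode training chains, train the ensemble, and attach pooled
    test-time class centers (mean of per-chain class means; chains
    missing a class are skipped for that class)."""
    pos_blocks, neg_blocks = [], []
    centers = {1: [], 0: []}
    for chain in train_chains:
        _, X, y = _encode_chain(chain, w_flank, w_mid)
        if (y == 1).any():
            pos_blocks.append(X[y == 1])
            centers[1].append(X[y == 1].mean(axis=0))
        if (y == 0).any():
            neg_blocks.append(X[y == 0])
            centers[0].append(X[y == 0].mean(axis=0))
    if not pos_blocks or not neg_blocks:
        raise ValueError("training fold lacks one of the classes")
    model = train_ensemble(
        np.vstack(pos_blocks), np.vstack(neg_blocks), ga_config, ens_config, master_seed
    )
    model.encoding = {"w_flank": w_flank, "w_mid": w_mid}
    model.test_centers = {
        "1": np.mean(centers[1], axis=0),
        "0": np.mean(centers[0], axis=0),
    }
    return model


def predict_chain(
    model: EnsembleModel,
    chain: ChainData,
    w_flank: int = feat.DEFAULT_W_FLANK,
    w_mid: int = feat.DEFAULT_W_MID,
) -> PredictionSet:
    """Score and label every long-range pair of one chain; records are
    sorted most-contact-like first (ties by pair order)."""
    pairs, X, _ = _encode_chain(chain, w_flank, w_mid)
    expected_dim = 20 * (2 * w_flank + w_mid)
    if model.input_dim != expected_dim:
        raise ValueError(
            f"model input dim {model.input_dim} != encoding dim {expected_dim}"
        )
    if len(pairs) == 0:
        return PredictionSet(
            chain_id=chain.chain_id,
            records=[],
            metadata=_prediction_metadata(model, chain),
        )
    scores = ensemble_score_matrix(model, X)
    labels = ensemble_label_matrix(model, X)
    order = sorted(
        range(len(pairs)), key=lambda k: (scores[k], pairs[k].i, pairs[k].j)
    )
    records = [
        (pairs[k].i, pairs[k].j, float(scores[k]), int(labels[k])) for k in order
    ]
    return PredictionSet(
        chain_id=chain.chain_id,
        records=records,
        metadata=_prediction_metadata(model, chain),
    )


def _prediction_metadata(model: EnsembleModel, chain: ChainData) -> dict:
    return {
        "cutoff": chain.contact_map.cutoff,
        "min_sep": chain.contact_map.min_sep,
        "model_id": f"ensemble-n{len(model.gacs)}-seed{model.master_seed}",
        "vote_rule": model.vote_rule,
    }
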