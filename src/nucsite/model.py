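"""Per-ligand support-vector-regression models for binding-site prediction.

Each residue of every protein in a ligand category is a training
example: the 105-dimensional PSSM-window feature vector with target 1
for binding residues and 0 otherwise.  An RBF-kernel SVR is fitted on
the pooled residues; its real-valued output is thresholded downstream
for binary calls and swept for ROC analysis.

Evaluation protocols:

* jackknife leave-one-protein-out — each protein is scored by a model
  that never saw it; scores are pooled (or averaged per protein) for
  the reported metrics;
* cross-prediction — a model trained on the *full* dataset of ligand A
  scores the dataset of ligand B for every ordered pair; the diagonal
  (A on A) deliberately reuses the training data to expose the
  over-learning ceiling.

SVR hyperparameters are the documented defaults below
(C=1, ε=0.1, RBF γ="scale"); fitting is deterministic given the fixed
data order sorted by (structure_id, chain_id, seq_index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .alphabet import AA_ORDER
from .contacts import ResidueLabelSet
from .features import WINDOW_HALF_WIDTH, SequenceProfile, encode_chain
from .metrics import best_f_scan, roc_auc
from .structure_io import ProteinChain

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SVR_PARAMS",
    "DatasetEntry",
    "LigandDataset",
    "ScoreSet",
    "TrainedModel",
    "train",
    "jackknife_evaluate",
    "cross_predict",
    "save_model",
    "load_model",
]

#: Documented SVR defaults; treated as configuration, overridable in train().
DEFAULT_SVR_PARAMS = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, "gamma": "scale"}

MODEL_FORMAT_VERSION = 1


@dataclass
class DatasetEntry:
    """(chain, profile, labels) for one protein, keyed by structure+chain id."""

    chain: ProteinChain
    profile: SequenceProfile
    labels: ResidueLabelSet

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain.structure_id, self.chain.chain_id)

    def __post_init__(self) -> None:
        n = len(self.chain)
        if len(self.profile) != n or len(self.labels) != n:
            raise ValueError(
                f"{self.key}: chain ({n}), profile ({len(self.profile)}) and "
                f"labels ({len(self.labels)}) lengths must agree"
            )


class LigandDataset:
    """All (chain, profile, labels) triples of one ligand category.

    The unit of training, jackknife evaluation and cross-prediction.
    Entries are kept sorted by key so that fits are reproducible.
    """

    def __init__(self, ligand_het: str, entries: list[DatasetEntry]):
        keys = [e.key for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (structure_id, chain_id) keys in dataset")
        self.ligand_het = ligand_het
        self.entries = sorted(entries, key=lambda e: e.key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_binding(self) -> int:
        return sum(e.labels.n_binding for e in self.entries)

    @property
    def n_nonbinding(self) -> int:
        return sum(e.labels.n_nonbinding for e in self.entries)

    def features(
        self, half_width: int = WINDOW_HALF_WIDTH
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
        """Pooled (X, y, per-row protein keys) over all entries."""
        blocks, targets, groups = [], [], []
        for entry in self.entries:
            X = encode_chain(entry.profile, half_width)
            blocks.append(X)
            targets.append(entry.labels.overall.astype(float))
            groups.extend([entry.key] * len(entry.chain))
        return np.vstack(blocks), np.concatenate(targets), groups

    def subset(self, keys) -> "LigandDataset":
        keys = set(keys)
        return LigandDataset(
            self.ligand_het, [e for e in self.entries if e.key in keys]
        )


@dataclass
class ScoreSet:
    """Real-valued predictions paired with true labels, grouped by protein."""

    scores: np.ndarray
    labels: np.ndarray
    groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")

    def __len__(self) -> int:
        return len(self.scores)

    def auc(self, mode: str = "pooled") -> float:
        """AUC in [0,1]: pooled over residues (default) or averaged per protein."""
        if mode == "pooled":
            return roc_auc(self.scores, self.labels)
        if mode == "per_protein":
            aucs = []
            for key in dict.fromkeys(self.groups):
                mask = np.array([g == key for g in self.groups])
                lab = self.labels[mask]
                if len(np.unique(lab)) < 2:
                    logger.warning("protein %s has a single class; skipped in "
                                   "per-protein AUC average", key)
                    continue
                aucs.append(roc_auc(self.scores[mask], lab))
            if not aucs:
                raise ValueError("no protein had both classes present")
            return float(np.mean(aucs))
        raise ValueError(f"unknown AUC mode {mode!r}")

    def report(self, f_mode: str = "harmonic"):
        """Metrics at the best-F cutoff (accuracy, sens, spec, F, AUC in %)."""
        _, rep = best_f_scan(self.scores, self.labels, f_mode)
        return rep


@dataclass
class TrainedModel:
    """A fitted per-ligand SVR plus the configuration that produced it."""

    ligand_het: str
    svr: SVR
    params: dict
    half_width: int = WINDOW_HALF_WIDTH
    alphabet: str = AA_ORDER
    logistic_scaled: bool = False
    format_version: int = MODEL_FORMAT_VERSION

    def score_dataset(self, dataset: LigandDataset) -> ScoreSet:
        X, y, groups = dataset.features(self.half_width)
        return ScoreSet(self.svr.predict(X), y, groups)


def train(
    dataset: LigandDataset,
    half_width: int = WINDOW_HALF_WIDTH,
    **svr_overrides,
) -> TrainedModel:
    """Fit an RBF SVR on all residues of the dataset (targets 1/0)."""
    if len(dataset) < 1:
        raise ValueError("cannot train on an empty dataset")
    X, y, _ = dataset.features(half_width)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"dataset for {dataset.ligand_het} contains a single class; "
            "both binding and non-binding residues are required"
        )
    params = {**DEFAULT_SVR_PARAMS, **svr_overrides}
    svr = SVR(**params)
    svr.fit(X, y)
    return TrainedModel(dataset.ligand_het, svr, params, half_width)


def jackknife_evaluate(
    dataset: LigandDataset,
    half_width: int = WINDOW_HALF_WIDTH,
    **svr_overrides,
) -> ScoreSet:
    """Leave-one-protein-out evaluation.

    Each protein's residues are scored by a model trained on all the
    other proteins; scores over all folds are concatenated so every
    residue is scored exactly once.  A fold whose training set has a
    single class yields the training base rate as a constant score, with
    a warning.
    """
    if len(dataset) < 3:
        raise ValueError("jackknife needs at least 3 proteins")
    all_scores, all_labels, all_groups = [], [], []
    for held_out in dataset.entries:
        train_keys = [e.key for e in dataset.entries if e.key != held_out.key]
        fold = dataset.subset(train_keys)
        X_tr, y_tr, _ = fold.features(half_width)
        X_te = encode_chain(held_out.profile, half_width)
        if len(np.unique(y_tr)) < 2:
            logger.warning(
                "fold leaving out %s has single-class training data; "
                "scoring with base rate", held_out.key
            )
            scores = np.full(len(held_out.chain), float(y_tr.mean()))
        else:
            params = {**DEFAULT_SVR_PARAMS, **svr_overrides}
            svr = SVR(**params)
            svr.fit(X_tr, y_tr)
            scores = svr.predict(X_te)
        all_scores.append(scores)
        all_labels.append(held_out.labels.overall.astype(int))
        all_groups.extend([held_out.key] * len(held_out.chain))
    return ScoreSet(
        np.concatenate(all_scores), np.concatenate(all_labels), all_groups
    )


def cross_predict(
    models: Mapping[str, TrainedModel],
    datasets: Mapping[str, LigandDataset],
) -> pd.DataFrame:
    """AUC (%) matrix: rows = trained ligand, columns = tested ligand.

    Models are expected to be trained on the *full* dataset of their
    ligand, so the diagonal reflects self-prediction on the training
    data (the over-learning ceiling), matching the cross-prediction
    protocol used for real data.
    """
    missing = [lig for lig in models if lig not in datasets]
    if missing:
        raise ValueError(f"no dataset supplied for trained ligand(s) {missing}")
    rows = {}
    for trained_lig, model in models.items():
        row = {}
        for tested_lig, dataset in datasets.items():
            row[tested_lig] = 100.0 * model.score_dataset(dataset).auc("pooled")
        rows[trained_lig] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "trained"
    frame.columns.name = "tested"
    return frame


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model with its configuration (joblib archive)."""
    payload = {
        "format_version": model.format_version,
        "ligand_het": model.ligand_het,
        "params": model.params,
        "half_width": model.half_width,
        "alphabet": model.alphabet,
        "logistic_scaled": model.logistic_scaled,
        "svr": model.svr,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return TrainedModel(
        ligand_het=payload["ligand_het"],
        svr=payload["svr"],
        params=payload["params"],
        half_width=payload["half_width"],
        alphabet=payload["alphabet"],
        logistic_scaled=payload["logistic_scaled"],
    )
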