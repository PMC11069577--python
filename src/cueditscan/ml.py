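"""Random-forest editing-site classifier over 50-bit window encodings.

Each 26-nt site window is reduced to its 25 context nucleotides (15 upstream,
10 downstream; the invariant central C carries no information) and encoded
position-major with two bits per nucleotide:

    isPurine : 1 for A/G        pairsGC : 1 for G/C

    A -> (1, 0)   G -> (1, 1)   C -> (0, 1)   U -> (0, 0)

Padding encodes as (0, 0), identical to U, so truncated windows remain valid
inputs.  The code is bijective on {A, C, G, U}, so unpadded windows decode
exactly.

Training-set construction addresses the extreme class imbalance of real
editing data (roughly 1 positive per 468 cytosines): all positives are kept,
negatives are downsampled to a configurable ratio, and a configurable
fraction of the sampled negatives is drawn from "hard" negatives -- sites the
rules-based scorer rates highly but that are not edited.  SMOTE-style
interpolation oversampling of the minority class is available but off by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import rules
from .seqio import SiteWindow, UPSTREAM_LEN, DOWNSTREAM_LEN

__all__ = [
    "FEATURE_LEN",
    "TrainingConfig",
    "LabeledSite",
    "encode_window",
    "decode_vector",
    "build_training_set",
    "train_model",
    "predict_prob",
    "ml_classify",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FEATURE_LEN = 2 * (UPSTREAM_LEN + DOWNSTREAM_LEN)  # 50

_ENCODE = {"A": (1, 0), "G": (1, 1), "C": (0, 1), "U": (0, 0)}
_DECODE = {v: k for k, v in _ENCODE.items()}

#: probability threshold: call positive iff P(editing) is strictly over 0.5
PROB_THRESHOLD = 0.5


@dataclass(frozen=True)
class LabeledSite:
    """A site window with its editing label.

    ``label`` is 1 for an editing site, 0 for a non-editing site;
    ``provenance`` distinguishes curated from synthetic sites.
    """

    window: SiteWindow
    label: int
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Imbalance-aware training-set construction parameters.

    ``neg_pos_ratio``           sampled negatives per positive (default 3)
    ``hard_negative_fraction``  share of sampled negatives drawn from the
                                high-rules-score pool (default 0.5)
    ``hard_negative_min_score`` rules total at or above which a negative
                                counts as hard (default 6)
    ``use_smote``               interpolate synthetic positives up to class
                                balance (default off)
    ``n_estimators`` / ``max_depth`` / ``max_features``  forest shape
    ``seed``                    drives sampling, SMOTE and the forest
    """

    neg_pos_ratio: float = 3.0
    hard_negative_fraction: float = 0.5
    hard_negative_min_score: int = 6
    use_smote: bool = False
    smote_k: int = 5
    split_fraction: float = 0.7
    n_estimators: int = 500
    max_depth: int | None = None
    max_features: str | int = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be positive")
        if not 0.0 <= self.hard_negative_fraction <= 1.0:
            raise ValueError("hard_negative_fraction must be in [0, 1]")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


def encode_window(window: SiteWindow) -> np.ndarray:
    """50-bit feature vector for one window (dtype uint8).

    Padding positions encode as (0, 0); everything else per the 2-bit code.
    """
    bits = np.zeros(FEATURE_LEN, dtype=np.uint8)
    ctx = window.context25
    for i, base in enumerate(ctx):
        if i < window.n_pad_up:
            continue  # padding stays (0, 0)
        if i >= UPSTREAM_LEN + DOWNSTREAM_LEN - window.n_pad_down:
            continue
        try:
            p, g = _ENCODE[base]
        except KeyError:
            raise ValueError(f"cannot encode residue {base!r}") from None
        bits[2 * i] = p
        bits[2 * i + 1] = g
    return bits


def decode_vector(bits: np.ndarray, gene: str = "decoded",
                  c_pos: int = UPSTREAM_LEN + 1) -> SiteWindow:
    """Inverse of :func:`encode_window` for unpadded windows."""
    if len(bits) != FEATURE_LEN:
        raise ValueError(f"expected {FEATURE_LEN} bits, got {len(bits)}")
    residues = []
    for i in range(FEATURE_LEN // 2):
        key = (int(bits[2 * i]), int(bits[2 * i + 1]))
        residues.append(_DECODE[key])
    ctx = "".join(residues)
    return SiteWindow(gene=gene, c_pos=c_pos,
                      upstream=ctx[:UPSTREAM_LEN],
                      downstream=ctx[UPSTREAM_LEN:])


def _smote(X_pos: np.ndarray, n_new: int, k: int,
           rng: np.random.Generator) -> np.ndarray:
    """Minimal SMOTE: new minority samples by interpolating each seed point
    toward one of its k nearest minority neighbours (Euclidean)."""
    n = len(X_pos)
    if n < 2 or n_new <= 0:
        return np.empty((0, X_pos.shape[1]))
    Xf = X_pos.astype(float)
    d2 = ((Xf[:, None, :] - Xf[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, n - 1)
    nn = np.argsort(d2, axis=1)[:, :k_eff]
    seeds = rng.integers(0, n, size=n_new)
    picks = nn[seeds, rng.integers(0, k_eff, size=n_new)]
    gaps = rng.random(size=(n_new, 1))
    return Xf[seeds] + gaps * (Xf[picks] - Xf[seeds])


def build_training_set(
    sites: list[LabeledSite],
    cfg: TrainingConfig,
    rules_cfg: rules.RulesConfig = rules.DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and labels with downsampled, hard-negative-enriched
    negatives.

    All positives are retained.  ``round(neg_pos_ratio * n_pos)`` negatives
    are sampled without replacement; of those, ``hard_negative_fraction`` are
    drawn uniformly from negatives whose rules total is at least
    ``hard_negative_min_score`` (falling back to random negatives, with a
    warning, when the hard pool is too small).  Optionally SMOTE-inflates
    positives to class balance.  Output order is shuffled by the seed.
    """
    pos = [s for s in sites if s.label == 1]
    neg = [s for s in sites if s.label == 0]
    if not pos or not neg:
        raise ValueError("need at least one site of each label")
    rng = np.random.default_rng(cfg.seed)

    n_neg_want = int(round(cfg.neg_pos_ratio * len(pos)))
    if n_neg_want > len(neg):
        logger.warning("requested %d negatives but only %d available; "
                       "taking all", n_neg_want, len(neg))
        n_neg_want = len(neg)

    n_hard_want = int(round(cfg.hard_negative_fraction * n_neg_want))
    scores = np.array([rules.rules_score(s.window, rules_cfg).rank for s in neg])
    hard_idx = np.flatnonzero(scores >= cfg.hard_negative_min_score)
    easy_idx = np.flatnonzero(scores < cfg.hard_negative_min_score)
    if len(hard_idx) < n_hard_want:
        logger.warning("hard-negative pool has %d sites, %d requested; "
                       "falling back to random negatives", len(hard_idx),
                       n_hard_want)
        n_hard_want = len(hard_idx)
    chosen_hard = rng.choice(hard_idx, size=n_hard_want, replace=False)
    rest_pool = np.concatenate([easy_idx,
                                np.setdiff1d(hard_idx, chosen_hard)])
    n_rest = n_neg_want - n_hard_want
    chosen_rest = rng.choice(rest_pool, size=min(n_rest, len(rest_pool)),
                             replace=False)
    neg_take = [neg[i] for i in np.concatenate([chosen_hard, chosen_rest])]

    X = np.array([encode_window(s.window) for s in pos + neg_take], dtype=float)
    y = np.array([1] * len(pos) + [0] * len(neg_take))

    if cfg.use_smote and len(neg_take) > len(pos):
        X_new = _smote(X[y == 1], len(neg_take) - len(pos), cfg.smote_k, rng)
        if len(X_new):
            X = np.vstack([X, X_new])
            y = np.concatenate([y, np.ones(len(X_new), dtype=int)])

    order = rng.permutation(len(y))
    return X[order], y[order]


def train_model(X: np.ndarray, y: np.ndarray,
                cfg: TrainingConfig) -> RandomForestClassifier:
    """Fit the random forest with the configured hyperparameters and seed."""
    clf = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def predict_prob(model: RandomForestClassifier,
                 window: SiteWindow | np.ndarray) -> float:
    """Probability that the site is an editing site."""
    x = encode_window(window) if isinstance(window, SiteWindow) else window
    proba = model.predict_proba(np.asarray(x, dtype=float).reshape(1, -1))[0]
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return float(proba[pos_col])


def predict_prob_many(model: RandomForestClassifier,
                      windows: list[SiteWindow]) -> np.ndarray:
    """Vectorized probabilities for many windows."""
    X = np.array([encode_window(w) for w in windows], dtype=float)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(X)[:, pos_col]


def ml_classify(prob: float, threshold: float = PROB_THRESHOLD) -> bool:
    """True iff the probability is strictly over the threshold (0.5)."""
    return prob > threshold


def save_model(model: RandomForestClassifier, cfg: TrainingConfig,
               path) -> None:
    """Persist the classifier with its training config and a version stamp."""
    from . import __version__
    joblib.dump({"model": model, "config": cfg, "version": __version__,
                 "feature_len": FEATURE_LEN}, path)


def load_model(path) -> tuple[RandomForestClassifier, TrainingConfig]:
    payload = joblib.load(path)
    if payload.get("feature_len") != FEATURE_LEN:
        raise ValueError("model artifact has incompatible feature layout")
    return payload["model"], payload["config"]
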