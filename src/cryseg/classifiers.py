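"""Statistical frame classifiers: per-class GMMs and HMMs.

Each acoustic class in {EXP, INS, BKG, NOR} gets its own generative model — a
diagonal-covariance Gaussian mixture p(o|lambda) = sum_j w_j N(o; mu_j, S_j),
or a hidden Markov model lambda = {A, B, pi} whose state emissions are such
mixtures.  Classification of a frame sequence is either a per-frame
log-likelihood argmax (GMM bank, optional majority smoothing) or a Viterbi
decode through a composite network in which the class models are connected
ergodically.

Model fitting is delegated to scikit-learn (EM) and hmmlearn (Baum-Welch);
scoring and composite decoding are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GMMHMM
from scipy.special import logsumexp
from sklearn import mixture as _sk_mixture
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "CLASS_ORDER",
    "GaussianMixture",
    "HmmModel",
    "ClassifierBank",
    "gmm_fit_em",
    "gmm_score",
    "hmm_fit_baumwelch",
    "viterbi_decode",
    "classify_frames",
    "train_gmm_bank",
    "train_hmm_bank",
]

#: Fixed class order; doubles as the deterministic tie-break (earlier wins).
CLASS_ORDER = ("EXP", "INS", "BKG", "NOR")

VARIANCE_FLOOR = 1e-6


@dataclass
class GaussianMixture:
    """Diagonal-covariance Gaussian mixture."""

    weights: np.ndarray          # (J,)
    means: np.ndarray            # (J, D)
    covars: np.ndarray           # (J, D) diagonal entries
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.covars = np.atleast_2d(np.asarray(self.covars, dtype=np.float64))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.covars < VARIANCE_FLOOR):
            raise ValueError(f"variances must be >= floor {VARIANCE_FLOOR}")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class HmmModel:
    """lambda = {A, B, pi} with Gaussian-mixture emissions per state."""

    startprob: np.ndarray                 # (S,)
    transmat: np.ndarray                  # (S, S)
    emissions: list[GaussianMixture]      # length S
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        self.transmat = np.asarray(self.transmat, dtype=np.float64)
        if abs(self.startprob.sum() - 1.0) > 1e-8:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("every transition-matrix row must sum to 1")

    @property
    def n_states(self) -> int:
        return self.startprob.size

    @property
    def dim(self) -> int:
        return self.emissions[0].dim


def gmm_fit_em(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> GaussianMixture:
    """Fit a diagonal GMM by EM (k-means initialization, fixed seed).

    The EM loop is stepped one iteration at a time so the per-iteration
    log-likelihood trace (monotone non-decreasing) is recorded in
    ``ll_history``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} frames cannot support {n_components} components"
        )
    gm = _sk_mixture.GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        reg_covar=VARIANCE_FLOOR,
        max_iter=1,
        tol=0.0,
        warm_start=True,
        init_params="kmeans",
        random_state=seed,
    )
    history: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            history.append(float(gm.lower_bound_))
            if len(history) >= 2 and abs(history[-1] - history[-2]) < tol:
                break
    covars = np.maximum(gm.covariances_, VARIANCE_FLOOR)
    return GaussianMixture(gm.weights_, gm.means_, covars, history)


def gmm_score(model: GaussianMixture, X: np.ndarray) -> np.ndarray:
    """Per-frame log p(o_t | lambda) under the mixture density."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.dim}"
        )
    # log N(o; mu_j, diag S_j) for all frames x components
    log_det = np.sum(np.log(model.covars), axis=1)                 # (J,)
    diff = X[:, None, :] - model.means[None, :, :]                 # (T, J, D)
    maha = np.sum(diff**2 / model.covars[None, :, :], axis=2)      # (T, J)
    log_comp = -0.5 * (model.dim * np.log(2.0 * np.pi) + log_det + maha)
    return logsumexp(log_comp + np.log(model.weights), axis=1)


class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the whole log-likelihood trace."""

    def _reset(self):
        super()._reset()
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        if not hasattr(self, "full_history"):
            self.full_history = []
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def hmm_fit_baumwelch(
    sequences: list[np.ndarray],
    n_states: int,
    n_mix: int = 1,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> HmmModel:
    """Fit an HMM with mixture emissions by Baum-Welch (hmmlearn backend)."""
    if not sequences:
        raise ValueError("empty training set")
    seqs = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in sequences]
    for s in seqs:
        if s.shape[0] < n_states:
            raise ValueError("every sequence must be at least n_states long")
    X = np.vstack(seqs)
    lengths = [s.shape[0] for s in seqs]
    hmm = GMMHMM(
        n_components=n_states,
        n_mix=n_mix,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        random_state=seed,
        min_covar=VARIANCE_FLOOR,
    )
    hmm.monitor_ = _TraceMonitor(tol, max_iter, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(X, lengths)
    emissions = []
    for s in range(n_states):
        covars = np.maximum(hmm.covars_[s], VARIANCE_FLOOR)
        emissions.append(GaussianMixture(hmm.weights_[s], hmm.means_[s], covars))
    startprob = hmm.startprob_ / hmm.startprob_.sum()
    transmat = hmm.transmat_ / hmm.transmat_.sum(axis=1, keepdims=True)
    return HmmModel(startprob, transmat, emissions,
                    list(getattr(hmm.monitor_, "full_history", [])))


@dataclass
class ClassifierBank:
    """Per-class models sharing one feature recipe.

    ``kind`` is "gmm" (one mixture per class) or "hmm" (one HMM per class);
    ``recipe`` names the features the bank was trained on ("fft-mfcc" or
    "emd-mfcc").
    """

    models: dict[str, object]
    kind: str
    recipe: str = "fft-mfcc"

    def __post_init__(self) -> None:
        if self.kind not in ("gmm", "hmm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        missing = [c for c in CLASS_ORDER if c not in self.models]
        if missing:
            raise ValueError(f"bank is missing classes: {missing}")
        dims = {m.dim for m in self.models.values()}
        if len(dims) != 1:
            raise ValueError("all class models must share the feature dimension")

    @property
    def dim(self) -> int:
        return next(iter(self.models.values())).dim

    def save(self, path: str | Path) -> None:
        def _gmm(g: GaussianMixture) -> dict:
            return {
                "weights": g.weights.tolist(),
                "means": g.means.tolist(),
                "covars": g.covars.tolist(),
            }

        payload = {"kind": self.kind, "recipe": self.recipe, "classes": {}}
        for cls, model in self.models.items():
            if self.kind == "gmm":
                payload["classes"][cls] = _gmm(model)
            else:
                payload["classes"][cls] = {
                    "startprob": model.startprob.tolist(),
                    "transmat": model.transmat.tolist(),
                    "emissions": [_gmm(e) for e in model.emissions],
                }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierBank":
        payload = json.loads(Path(path).read_text())

        def _gmm(d: dict) -> GaussianMixture:
            return GaussianMixture(
                np.array(d["weights"]), np.array(d["means"]), np.array(d["covars"])
            )

        models: dict[str, object] = {}
        for name, d in payload["classes"].items():
            if payload["kind"] == "gmm":
                models[name] = _gmm(d)
            else:
                models[name] = HmmModel(
                    np.array(d["startprob"]),
                    np.array(d["transmat"]),
                    [_gmm(e) for e in d["emissions"]],
                )
        return cls(models=models, kind=payload["kind"], recipe=payload["recipe"])


def _as_hmm(model) -> HmmModel:
    if isinstance(model, HmmModel):
        return model
    return HmmModel(np.array([1.0]), np.array([[1.0]]), [model])


def viterbi_decode(
    bank: ClassifierBank, X: np.ndarray, switch_penalty: float = 0.0
) -> np.ndarray:
    """Most-probable class path through the composite ergodic network.

    The per-class HMMs are joined into one network: intra-class transitions
    follow each model's A; from any state the decoder may jump to the entry
    distribution of any class with uniform inter-class probability, minus a
    log-domain ``switch_penalty``.  States map back to their owning class, so
    the decoded path yields one class label per frame.  Ties resolve to the
    earlier class in ``CLASS_ORDER``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    classes = [c for c in CLASS_ORDER if c in bank.models]
    hmms = {c: _as_hmm(bank.models[c]) for c in classes}

    state_class: list[int] = []
    log_b_cols: list[np.ndarray] = []
    entry: list[float] = []           # log pi within class (composite indexing)
    for ci, c in enumerate(classes):
        h = hmms[c]
        for s in range(h.n_states):
            state_class.append(ci)
            log_b_cols.append(gmm_score(h.emissions[s], X))
            with np.errstate(divide="ignore"):
                entry.append(float(np.log(h.startprob[s])))
    log_b = np.column_stack(log_b_cols)                # (T, S_total)
    n_total = len(state_class)
    if not np.all(np.isfinite(np.max(log_b, axis=1))):
        bad = int(np.argmin(np.isfinite(np.max(log_b, axis=1))))
        raise ValueError(f"frame {bad} has -inf likelihood under every state")

    entry = np.array(entry)
    state_class_arr = np.array(state_class)
    log_switch = -np.log(len(classes)) - switch_penalty
    # composite log-transition matrix
    log_t = np.full((n_total, n_total), -np.inf)
    offsets = np.cumsum([0] + [hmms[c].n_states for c in classes])
    with np.errstate(divide="ignore"):
        for ci, c in enumerate(classes):
            o = offsets[ci]
            h = hmms[c]
            log_t[o : o + h.n_states, o : o + h.n_states] = np.log(h.transmat)
        for cj in range(len(classes)):
            oj = offsets[cj]
            nj = hmms[classes[cj]].n_states
            inter = log_switch + entry[oj : oj + nj]
            mask = state_class_arr != cj
            log_t[np.ix_(mask, np.arange(oj, oj + nj))] = inter

    T = X.shape[0]
    delta = -np.log(len(classes)) + entry + log_b[0]
    back = np.zeros((T, n_total), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_t                  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(n_total)] + log_b[t]
    path = np.zeros(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return np.array([classes[state_class[s]] for s in path])


def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return labels
    half = window // 2
    out = labels.copy()
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    for t in range(labels.size):
        lo, hi = max(0, t - half), min(labels.size, t + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        best = counts.max()
        winners = sorted((v for v, c in zip(vals, counts) if c == best),
                         key=lambda v: order.get(v, len(order)))
        out[t] = winners[0]
    return out


def classify_frames(
    bank: ClassifierBank,
    X: np.ndarray,
    smooth_window: int = 1,
    switch_penalty: float = 0.0,
) -> np.ndarray:
    """Initial per-frame class labels.

    GMM bank: per-frame argmax of the class log-likelihoods, optionally
    followed by majority smoothing over ``smooth_window`` frames.  HMM bank:
    Viterbi decode of the composite network.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != bank.dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match bank ({bank.dim})"
        )
    if bank.kind == "hmm":
        return viterbi_decode(bank, X, switch_penalty)
    classes = [c for c in CLASS_ORDER if c in bank.models]
    scores = np.column_stack([gmm_score(bank.models[c], X) for c in classes])
    labels = np.array([classes[i] for i in np.argmax(scores, axis=1)])
    return _majority_smooth(labels, smooth_window)


def train_gmm_bank(
    features_by_class: dict[str, np.ndarray],
    n_components: int = 40,
    seed: int = 0,
    recipe: str = "fft-mfcc",
    **em_kwargs,
) -> ClassifierBank:
    models = {
        cls: gmm_fit_em(X, n_components, seed=seed, **em_kwargs)
        for cls, X in features_by_class.items()
    }
    return ClassifierBank(models=models, kind="gmm", recipe=recipe)


def train_hmm_bank(
    sequences_by_class: dict[str, list[np.ndarray]],
    n_states: int = 4,
    n_mix: int = 10,
    seed: int = 0,
    recipe: str = "emd-mfcc",
    **bw_kwargs,
) -> ClassifierBank:
    """One HMM per class; 40 Gaussians at the defaults (4 states x 10 mixtures)."""
    models = {
        cls: hmm_fit_baumwelch(seqs, n_states, n_mix, seed=seed, **bw_kwargs)
        for cls, seqs in sequences_by_class.items()
    }
    return ClassifierBank(models=models, kind="hmm", recipe=recipe)
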