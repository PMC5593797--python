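"""Exhaustive-enumeration oracle for composite-network decoding.

Scores every possible state path through the ergodically connected class
models with literal loops, independent of the dynamic-programming decoder.
Only feasible for tiny instances (a handful of total states, short T).
"""

from itertools import product
from types import SimpleNamespace

import numpy as np

from cryseg.classifiers import CLASS_ORDER, GaussianMixture, HmmModel, gmm_score


def random_small_bank(rng, dim=2):
    """A random bank of 2-4 classes with <= 4 composite states in total."""
    n_classes = int(rng.integers(2, 5))
    classes = list(CLASS_ORDER[:n_classes])
    budget = 4
    models = {}
    for i, cls in enumerate(classes):
        remaining = len(classes) - i - 1
        max_states = max(1, min(2, budget - remaining))
        n_states = int(rng.integers(1, max_states + 1))
        budget -= n_states
        start = rng.dirichlet(np.ones(n_states))
        trans = np.vstack([rng.dirichlet(np.ones(n_states)) for _ in range(n_states)])
        emissions = []
        for _ in range(n_states):
            j = int(rng.integers(1, 3))
            emissions.append(GaussianMixture(
                rng.dirichlet(np.ones(j)),
                rng.normal(scale=3.0, size=(j, dim)),
                rng.uniform(0.2, 1.5, size=(j, dim)),
            ))
        models[cls] = HmmModel(start, trans, emissions)
    return SimpleNamespace(models=models, kind="hmm", dim=dim)


def enumerate_best_path(bank, X, switch_penalty=0.0):
    """Best class-label sequence and score by scoring every state path.

    The per-step scores are assembled with literal loops over the class
    models; every possible state path is then scored (vectorized indexing,
    still a full enumeration) and the argmax taken.
    """
    classes = [c for c in CLASS_ORDER if c in bank.models]
    states = [(c, s) for c in classes for s in range(bank.models[c].n_states)]
    n = len(states)
    T = X.shape[0]
    log_b = np.column_stack([
        gmm_score(bank.models[c].emissions[s], X) for (c, s) in states
    ])  # (T, n)
    log_n_classes = np.log(len(classes))

    with np.errstate(divide="ignore"):
        init = np.array([
            -log_n_classes + np.log(bank.models[c].startprob[s])
            for (c, s) in states
        ])
        step = np.empty((n, n))
        for i, (ci, si) in enumerate(states):
            for j, (cj, sj) in enumerate(states):
                if ci == cj:
                    step[i, j] = np.log(bank.models[ci].transmat[si, sj])
                else:
                    step[i, j] = (-log_n_classes - switch_penalty
                                  + np.log(bank.models[cj].startprob[sj]))

    paths = np.array(list(product(range(n), repeat=T)))  # (n^T, T)
    scores = init[paths[:, 0]] + log_b[0, paths[:, 0]]
    for t in range(1, T):
        scores += step[paths[:, t - 1], paths[:, t]] + log_b[t, paths[:, t]]
    best = int(np.argmax(scores))
    labels = np.array([states[s][0] for s in paths[best]])
    return labels, float(scores[best])
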