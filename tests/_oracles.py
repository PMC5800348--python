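"""Independent brute-force oracles used by the test suite.

These deliberately share no code path with the package implementations they
check: path likelihoods are evaluated by exhaustive enumeration over all 3^n
state sequences.
"""

import itertools

import numpy as np


def enumerate_paths(n: int, k: int = 3) -> np.ndarray:
    return np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int8)


def all_path_logliks(log_emis: np.ndarray, log_pi: np.ndarray,
                     log_T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(paths, joint log likelihood of every state path)."""
    n = log_emis.shape[0]
    paths = enumerate_paths(n)
    with np.errstate(invalid="ignore"):
        ll = log_pi[paths[:, 0]] + log_emis[0, paths[:, 0]].astype(float)
        for t in range(1, n):
            ll = ll + log_T[paths[:, t - 1], paths[:, t]] + log_emis[t, paths[:, t]]
    return paths, ll


def best_path_brute_force(log_emis, log_pi, log_T) -> tuple[np.ndarray, float]:
    paths, ll = all_path_logliks(log_emis, log_pi, log_T)
    i = int(np.argmax(ll))
    return paths[i], float(ll[i])


def loglik_of_path_brute_force(states, log_emis, log_pi, log_T) -> float:
    states = np.asarray(states)
    paths, ll = all_path_logliks(log_emis, log_pi, log_T)
    match = np.all(paths == states[None, :], axis=1)
    return float(ll[match][0])
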