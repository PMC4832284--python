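"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the library's vectorized code paths: inner
products by exact summation (math.fsum), argmax by explicit scan with
the documented tie rule, matching by literal repetition of the greedy
rule.
"""

import math

import numpy as np


def naive_inner(a, b):
    """Exact-summation inner product."""
    return math.fsum(float(x) * float(y) for x, y in zip(a, b))


def bruteforce_select(atoms, norms, residual, normalize=True):
    """Scan every atom; return (index, score, coefficient).

    Ties broken by the first (earliest-onset) atom, as documented.
    """
    best_j, best_score = None, -math.inf
    for j in range(atoms.shape[0]):
        ip = naive_inner(atoms[j], residual)
        score = ip / norms[j] if normalize else ip
        if score > best_score:
            best_j, best_score = j, score
    a = naive_inner(atoms[best_j], residual) / norms[best_j] ** 2
    return best_j, best_score, a


def replay_mp(data, dictionary, result, normalize=True):
    """Re-derive every MP iteration by brute force; verify selections.

    Returns the sequence of residual norms (including the initial one).
    Raises AssertionError on any disagreement with ``result``.
    """
    residual = np.asarray(data, dtype=float).copy()
    norms_track = [float(np.linalg.norm(residual))]
    for i in range(result.n_iterations):
        j, _, a = bruteforce_select(dictionary.atoms, dictionary.norms, residual, normalize)
        assert dictionary.onsets[j] == result.selected_onsets[i], (
            f"iteration {i}: oracle selects onset {dictionary.onsets[j]}, "
            f"implementation selected {result.selected_onsets[i]}"
        )
        assert abs(a - result.greedy_coefficients[i]) < 1e-10 * max(1.0, abs(a))
        residual -= a * dictionary.atoms[j]
        norms_track.append(float(np.linalg.norm(residual)))
    assert np.allclose(residual, result.residual.values, atol=1e-9)
    return norms_track


def greedy_match_oracle(true_onsets, est_onsets):
    """Literal restatement of the matching rule, without sorting tricks."""
    t = sorted(float(x) for x in true_onsets)
    e = sorted(float(x) for x in est_onsets)
    free_t = set(range(len(t)))
    free_e = set(range(len(e)))
    pairs = []
    while free_t and free_e:
        best = None
        for i in sorted(free_t):
            for j in sorted(free_e):
                key = (abs(e[j] - t[i]), t[i], e[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        free_t.remove(i)
        free_e.remove(j)
        pairs.append((i, j, e[j] - t[i]))
    return pairs
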