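"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — explicit loops and
exhaustive enumeration — so it shares no code path with the package.
"""

import itertools

import numpy as np


def ni_sm_side_oracle(A: np.ndarray, S: np.ndarray, sigma: float) -> np.ndarray:
    """Double-loop neighborhood score using SM-SM similarity."""
    ns, nm = A.shape
    out = np.zeros((ns, nm))
    for i in range(ns):
        for j in range(nm):
            num = den = 0.0
            for d in range(ns):
                if d != i and S[d, i] >= sigma:
                    num += A[d, j] * S[d, i]
                    den += S[d, i]
            out[i, j] = num / den if den > 0 else 0.0
    return out


def ni_mirna_side_oracle(A: np.ndarray, S: np.ndarray, sigma: float) -> np.ndarray:
    """Double-loop neighborhood score using miRNA-miRNA similarity."""
    ns, nm = A.shape
    out = np.zeros((ns, nm))
    for i in range(ns):
        for j in range(nm):
            num = den = 0.0
            for t in range(nm):
                if t != j and S[t, j] >= sigma:
                    num += A[i, t] * S[t, j]
                    den += S[t, j]
            out[i, j] = num / den if den > 0 else 0.0
    return out


def rbm_energy_oracle(W, b, c, v, h) -> float:
    """Triple-sum energy, term by term."""
    e = 0.0
    for i in range(len(v)):
        e -= b[i] * v[i]
    for j in range(len(h)):
        e -= c[j] * h[j]
    for i in range(len(v)):
        for j in range(len(h)):
            e -= W[i, j] * v[i] * h[j]
    return e


def rbm_enumerate(W, b, c):
    """Exhaustive joint distribution over all binary (v, h) states.

    Returns (states, probabilities, Z) where states is a list of
    (v, h) tuples covering all 2^(nv+nh) configurations.
    """
    nv, nh = W.shape
    states, weights = [], []
    for v in itertools.product((0, 1), repeat=nv):
        for h in itertools.product((0, 1), repeat=nh):
            states.append((np.array(v), np.array(h)))
            weights.append(np.exp(-rbm_energy_oracle(W, b, c, v, h)))
    Z = float(np.sum(weights))
    return states, np.array(weights) / Z, Z


def enumerated_hidden_conditional(W, b, c, v, j) -> float:
    """P(h_j = 1 | v) from the enumerated joint distribution."""
    states, probs, _ = rbm_enumerate(W, b, c)
    num = sum(p for (sv, sh), p in zip(states, probs)
              if np.array_equal(sv, v) and sh[j] == 1)
    den = sum(p for (sv, _), p in zip(states, probs) if np.array_equal(sv, v))
    return num / den


def auc_pair_counting(pos, neg) -> float:
    """Concordant-pair counting with half credit for ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def jaccard_oracle(P: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard over row feature sets via Python sets."""
    n = P.shape[0]
    sets = [set(np.nonzero(P[i])[0].tolist()) for i in range(n)]
    S = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                S[a, b] = 1.0
            elif sets[a] | sets[b]:
                S[a, b] = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
    return S
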