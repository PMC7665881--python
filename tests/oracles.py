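"""Independent oracles used by several test modules.

These deliberately avoid the code paths they check: the CCA oracle goes
through the generalized-eigenvalue formulation instead of whitened SVD, and
the Shapley oracle is a literal double enumeration over features and subsets.
"""

import itertools
import math

import numpy as np


def cca_eigen_oracle(X, Y):
    """Canonical correlations as square roots of the eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx (direct matrix algebra)."""
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    Sxx = Xs.T @ Xs / n
    Syy = Ys.T @ Ys / n
    Sxy = Xs.T @ Ys / n
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eig = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eig[:k], 0, 1))


def simulate_latent(n, seed, rho=0.8, p=4, q=6):
    """Two variable sets sharing one latent factor; the first canonical
    correlation is rho by construction (equal noise on both sides)."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    s = np.sqrt(1 / rho - 1)  # corr(x1, y1) = 1 / (1 + s^2)
    x = rng.normal(size=(n, p))
    y = rng.normal(size=(n, q))
    x[:, 0] = z + s * rng.normal(size=n)
    y[:, 0] = z + s * rng.normal(size=n)
    return x, y


def brute_force_shapley(model_fn, x, background):
    """Literal Shapley enumeration: for each feature, loop over all subsets of
    the remaining features and average the weighted marginal contributions,
    with the coalition value as a mean over explicit background rows."""
    M = len(x)
    phi = np.zeros(M)
    for i in range(M):
        rest = [j for j in range(M) if j != i]
        for k in range(len(rest) + 1):
            for S in itertools.combinations(rest, k):
                w = (
                    math.factorial(len(S))
                    * math.factorial(M - len(S) - 1)
                    / math.factorial(M)
                )
                vals_with, vals_without = [], []
                for b in background:
                    z = b.copy()
                    for j in S:
                        z[j] = x[j]
                    vals_without.append(model_fn(z[None, :])[0])
                    z[i] = x[i]
                    vals_with.append(model_fn(z[None, :])[0])
                phi[i] += w * (np.mean(vals_with) - np.mean(vals_without))
    return phi
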