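"""Independent numerical oracles used by the test-suite.

These deliberately avoid the package's own code paths: plain quadrature and
longhand Bayes formulas only.
"""

import numpy as np
from scipy import integrate
from scipy.stats import norm


def two_class_gaussian_mi(mu0: float, mu1: float, sd: float,
                          w0: float, w1: float) -> float:
    """Mutual information (bits) of a binary label with priors (w0, w1) and
    Gaussian class conditionals, by direct quadrature."""
    h = -(w0 * np.log2(w0) + w1 * np.log2(w1))
    f0 = lambda x: norm.pdf(x, mu0, sd)
    f1 = lambda x: norm.pdf(x, mu1, sd)

    def post(x, which):
        num = (w0 * f0(x)) if which == 0 else (w1 * f1(x))
        return num / (w0 * f0(x) + w1 * f1(x))

    lo = min(mu0, mu1) - 12 * sd
    hi = max(mu0, mu1) + 12 * sd
    e0 = integrate.quad(lambda x: f0(x) * np.log2(post(x, 0)), lo, hi, limit=200)[0]
    e1 = integrate.quad(lambda x: f1(x) * np.log2(post(x, 1)), lo, hi, limit=200)[0]
    return h + w0 * e0 + w1 * e1


def loo_gaussian_log2_posteriors(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force leave-one-out Gaussian-template Bayes, computed longhand.

    For each held-out observation, class means/SDs are estimated with the n-1
    denominator on the remaining points and the maximum-likelihood (uniform
    prior) posterior evaluated with explicit normal pdfs.  Returns the
    (n, 2) matrix of log2 posteriors for classes (0, 1).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty((n, 2))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xt, yt = x[keep], y[keep]
        dens = []
        for c in (0, 1):
            g = xt[yt == c]
            mu = g.mean()
            sd = np.sqrt(((g - mu) ** 2).sum() / (len(g) - 1))
            dens.append(norm.pdf(x[i], mu, sd))
        total = dens[0] + dens[1]
        out[i, 0] = np.log2(dens[0] / total)
        out[i, 1] = np.log2(dens[1] / total)
    return out
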