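"""Independent reference computations used to check the package's results.

These deliberately avoid the package's optimizer: the exposure oracle works
in beta-space with a generic bound-constrained quasi-Newton solver on the
convex Poisson objective, evaluating the likelihood from its definition.
"""

import numpy as np
from scipy.optimize import minimize


def oracle_fractions(bulk, signals, intercept=True):
    """Normalized signal fractions via direct convex minimization in beta.

    The Poisson NLL is convex in the non-negative exposures, so L-BFGS-B
    with positivity bounds finds the global optimum; the intercept exposure
    is converted to its flat-signal equivalent (times m) before normalizing.
    """
    y = bulk.fragment_counts
    lengths = bulk.effective_lengths
    S = signals.signals
    m = S.shape[0]
    k = S.shape[1] + (1 if intercept else 0)
    out = np.zeros((y.shape[1], k))
    for p in range(y.shape[1]):

        def nll(beta):
            lam = S @ beta[: S.shape[1]]
            if intercept:
                lam = lam + beta[-1]
            lam = np.maximum(lam * lengths[:, p], 1e-10)
            return np.sum(lam - y[:, p] * np.log(lam))

        x0 = np.full(k, (y[:, p].sum() / lengths[:, p].sum()) / k)
        res = minimize(nll, x0, bounds=[(1e-14, None)] * k, method="L-BFGS-B")
        beta = res.x.copy()
        if intercept:
            beta[-1] *= m
        out[p] = beta / beta.sum()
    return out
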