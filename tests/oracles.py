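"""Independent oracles used by the test suite.

These deliberately avoid the library's own fitting code path: plain
normal-equation least squares with t-tests assembled from scipy, used to
verify the stepwise selector against brute-force enumeration of term
subsets.
"""

from itertools import combinations

import numpy as np
from scipy import stats

TERMS = ("gender", "ln_age", "ln_height", "ln_weight")


def ols_pvalues(table, terms):
    """Closed-form OLS of ln_y on terms + intercept; returns (coef, p) dicts."""
    y = table["ln_y"].to_numpy()
    X = np.column_stack([np.ones(len(y))] + [table[t].to_numpy() for t in terms])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    names = ["const", *terms]
    return dict(zip(names, beta)), dict(zip(names, pvals))


def all_subsets(terms=TERMS):
    for k in range(len(terms) + 1):
        for sub in combinations(terms, k):
            yield sub


def verify_stepwise_fixed_point(table, selected, p_enter, p_remove, terms=TERMS):
    """Check the forward/backward fixed-point conditions for ``selected``
    using p-values enumerated independently over all term subsets.

    Returns a list of violated conditions (empty when the fixed point holds):
    every retained term keeps p < p_remove in the final model, and every
    excluded candidate would show p >= p_enter if entered.
    """
    subset_p = {sub: ols_pvalues(table, list(sub))[1] for sub in all_subsets(terms)}
    selected = tuple(sorted(selected, key=terms.index))
    violations = []
    final_p = subset_p[selected]
    for term in selected:
        if final_p[term] >= p_remove:
            violations.append(f"retained {term} has p={final_p[term]:.3g} >= p_remove")
    for cand in terms:
        if cand in selected:
            continue
        with_cand = tuple(sorted([*selected, cand], key=terms.index))
        p = subset_p[with_cand][cand]
        if p < p_enter:
            violations.append(f"excluded {cand} would enter with p={p:.3g} < p_enter")
    return violations
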