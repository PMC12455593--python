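"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementation: plain
python loops over itertools subsets, so they stay a trustworthy reference
for the vectorized estimators.
"""

import itertools
import math

import numpy as np
import pandas as pd


def brute_shapley(predict_fn, instance: pd.Series, background: pd.DataFrame):
    """Interventional Shapley values by direct subset enumeration.

    v(S) = mean over background rows of predict(row with features in S taken
    from the instance); phi_p = sum over subsets S of the factorially
    weighted marginal contribution of p.
    """
    features = list(background.columns)
    n = len(features)

    def value(subset):
        preds = []
        for _, bg_row in background.iterrows():
            hybrid = bg_row.copy()
            for f in subset:
                hybrid[f] = instance[f]
            preds.append(float(predict_fn(hybrid.to_frame().T)[0]))
        return sum(preds) / len(preds)

    phi = {}
    for p in features:
        others = [f for f in features if f != p]
        total = 0.0
        for size in range(n):
            w = math.factorial(size) * math.factorial(n - size - 1) / math.factorial(n)
            for subset in itertools.combinations(others, size):
                total += w * (value(set(subset) | {p}) - value(set(subset)))
        phi[p] = total
    return pd.Series(phi), value(set())


def brute_willmott(p, o):
    """Metric decomposition computed with plain-python sums."""
    p, o = list(map(float, p)), list(map(float, o))
    n = len(o)
    o_bar = sum(o) / n
    p_bar = sum(p) / n
    var_o = sum((x - o_bar) ** 2 for x in o) / n
    if var_o == 0:
        b, a = 0.0, p_bar
    else:
        b = sum((pi - p_bar) * (oi - o_bar) for pi, oi in zip(p, o)) / n / var_o
        a = p_bar - b * o_bar
    p_hat = [a + b * oi for oi in o]
    rmse = math.sqrt(sum((pi - oi) ** 2 for pi, oi in zip(p, o)) / n)
    rmse_s = math.sqrt(sum((ph - oi) ** 2 for ph, oi in zip(p_hat, o)) / n)
    rmse_u = math.sqrt(sum((pi - ph) ** 2 for pi, ph in zip(p, p_hat)) / n)
    denom = sum((abs(pi - o_bar) + abs(oi - o_bar)) ** 2 for pi, oi in zip(p, o))
    d = 1.0 if denom == 0 else 1.0 - sum((pi - oi) ** 2 for pi, oi in zip(p, o)) / denom
    return rmse, rmse_s, rmse_u, d
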