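"""Naive direct-from-formula recomputation of the similarity measures.

Deliberately independent of the package's vectorised implementation:
plain per-pair, per-attribute loops over the raw table, with frequencies
and ranges recomputed from scratch.
"""

import math

import numpy as np


def _missing(v):
    return v is None or (isinstance(v, float) and math.isnan(v))


def oracle_matrix(values, types, measure, zero_levels=None,
                  include_double_zero=None):
    """values: list of rows (lists); types: list of 'categorical'/'continuous'."""
    zero_levels = zero_levels or {}
    n = len(values)
    M = len(types)

    # per-attribute side information
    counts, rng_lo, rng_hi, sds = [], [], [], []
    for m in range(M):
        col = [row[m] for row in values]
        obs = [v for v in col if not _missing(v)]
        if types[m] == "categorical":
            c = {}
            for v in obs:
                c[v] = c.get(v, 0) + 1
            counts.append(c)
            rng_lo.append(None)
            rng_hi.append(None)
            sds.append(None)
        else:
            counts.append(None)
            rng_lo.append(min(obs))
            rng_hi.append(max(obs))
            mu = sum(obs) / len(obs)
            sds.append(math.sqrt(sum((v - mu) ** 2 for v in obs) / len(obs)))

    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0
            for m in range(M):
                a, b = values[i][m], values[j][m]
                if measure == "gower":
                    if _missing(a) or _missing(b):
                        continue
                    if types[m] == "categorical":
                        zl = zero_levels.get(m)
                        exclude = (include_double_zero is False
                                   or (include_double_zero is None
                                       and zl is not None))
                        if exclude and zl is not None and a == zl and b == zl:
                            continue
                        s = 1.0 if a == b else 0.0
                    else:
                        r = rng_hi[m] - rng_lo[m]
                        s = 1.0 if r == 0 else 1.0 - abs(a - b) / r
                    num += s
                    den += 1
                elif measure == "wilson":
                    if _missing(a) or _missing(b):
                        s = 0.0
                    elif types[m] == "categorical":
                        s = 1.0 - abs(counts[m][a] - counts[m][b]) / n
                    else:
                        s = max(1.0 - abs(a - b) / (4.0 * sds[m]), 0.0)
                    num += s
                    den += 1
                else:  # dimrs
                    if _missing(a) or _missing(b):
                        continue
                    if types[m] == "categorical":
                        if a != b:
                            s = 0.0
                        else:
                            s = 1.0 - (counts[m][a] * (counts[m][b] - 1)
                                       / (n * (n - 1)))
                    else:
                        r = rng_hi[m] - rng_lo[m]
                        s = 1.0 if r == 0 else 1.0 - abs(a - b) / r
                    num += s
                    den += 1
            if den == 0:
                S[i, j] = 0.0
            else:
                S[i, j] = min(max(num / den, 0.0), 1.0)
    for i in range(n):
        any_obs = any(not _missing(values[i][m]) for m in range(M))
        S[i, i] = 1.0 if any_obs else 0.0
    return S
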