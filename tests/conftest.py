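import numpy as np
import pandas as pd
import pytest

from dimr.attributes import AttributeTable


def random_mixed_table(rng, n=None, m=None, missing_rate=0.15):
    """Random small mixed-type attribute table plus its raw cell lists.

    Returns ``(AttributeTable, values_rows, types, zero_levels_by_index)``
    where the raw pieces feed the naive oracle.
    """
    n = n if n is not None else int(rng.integers(3, 9))
    m = m if m is not None else int(rng.integers(1, 5))
    cols, types_map, zero_levels = {}, {}, {}
    types_list, zl_by_idx = [], {}
    rows = [[] for _ in range(n)]
    for j in range(m):
        name = f"a{j}"
        kind = rng.choice(["categorical", "continuous", "boolean"])
        if kind == "continuous":
            col = rng.normal(size=n).round(3)
            # ensure at least two observed values with distinct entries
            col[0], col[1] = -1.5, 1.5
            vals = [float(v) for v in col]
            types_map[name] = "continuous"
            types_list.append("continuous")
        elif kind == "categorical":
            levels = [f"L{t}" for t in range(int(rng.integers(2, 4)))]
            vals = [str(rng.choice(levels)) for _ in range(n)]
            types_map[name] = "categorical"
            types_list.append("categorical")
        else:
            vals = [bool(rng.random() < 0.4) for _ in range(n)]
            types_map[name] = "categorical"
            types_list.append("categorical")
            zero_levels[name] = False
            zl_by_idx[j] = False
        for i in range(n):
            if i > 1 and rng.random() < missing_rate:
                vals[i] = float("nan")
        for i in range(n):
            rows[i].append(vals[i])
        cols[name] = vals
    idx = [f"g{i}" for i in range(n)]
    values = pd.DataFrame(
        {k: pd.Series(v, index=idx, dtype=object) for k, v in cols.items()})
    table = AttributeTable(values, types=types_map, zero_levels=zero_levels)
    return table, rows, types_list, zl_by_idx


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
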