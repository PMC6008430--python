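"""Preliminary statistics: per-class summaries, pairwise ANOVA, separability.

These are the analyses run before any classifier: a per-class mean ± SD
table of the ten peak variables (at peak granularity), one-way ANOVA for
every class pair and variable (60 tests with four classes, flagged at the
two reported thresholds p < 0.001 and p < 0.02, raw p values with a
Bonferroni column added for transparency), and a class-separability
("scatter power") score in [0, 1].

The separability score is a documented variant of the Scatter method, not
a replication of the original algorithm: after z-scoring, a
nearest-neighbor chain visits every case once; the number of label
changes L along the chain is compared with its mean over random label
permutations, giving ``power = 1 - L / E[L_perm]`` clipped to [0, 1].
Well-separated classes make the chain dwell inside one class at a time
(small L, power near 1); label-independent geometry gives power near 0.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import f_oneway

from .signal_io import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


def summarize(
    table: pd.DataFrame, label_col: str = "label",
    variables: tuple[str, ...] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Per-class mean, SD and case count for each variable.

    ``table`` holds one row per peak (or per signal); classes without any
    rows are omitted with a warning.
    """
    rows = []
    for label, grp in table.groupby(label_col, sort=False, observed=True):
        if grp.empty:
            logger.warning("summarize: class %s has no cases; omitted", label)
            continue
        for var in variables:
            vals = grp[var].to_numpy(dtype=float)
            rows.append({
                "label": label, "variable": var, "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "n": len(vals),
            })
    return pd.DataFrame(rows)


def pairwise_anova(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    label_col: str = "label",
    variables: tuple[str, ...] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """One-way ANOVA F and p for every class pair and variable.

    With four classes this yields the full 6 pairs x 10 variables = 60
    tests.  Flags are raised at p < 0.001 and p < 0.02; ``p_bonferroni``
    multiplies by the number of tests.  Two constant groups with equal
    means get F = 0, p = 1 by convention.
    """
    labels = list(dict.fromkeys(table[label_col]))
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for la, lb in pairs:
        ga = table.loc[table[label_col] == la]
        gb = table.loc[table[label_col] == lb]
        if len(ga) < 2 or len(gb) < 2:
            raise ValueError(f"pair ({la}, {lb}): each class needs >= 2 cases")
        for var in variables:
            xa = ga[var].to_numpy(dtype=float)
            xb = gb[var].to_numpy(dtype=float)
            if xa.var() == 0 and xb.var() == 0:
                F, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
            else:
                F, p = f_oneway(xa, xb)
            rows.append({"pair": f"{la} vs {lb}", "variable": var,
                         "F": float(F), "p": float(p)})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["significant_p001"] = out["p"] < 0.001
    out["significant_p02"] = out["p"] < 0.02
    out["p_bonferroni"] = np.minimum(out["p"] * n_tests, 1.0)
    return out


def _chain_order(X: np.ndarray) -> np.ndarray:
    """Visit order of the nearest-neighbor chain through standardized data.

    Starts at the case closest to the grand centroid and repeatedly hops
    to the nearest unvisited case (euclidean; index order breaks exact
    ties).  Depends only on the geometry, never on the labels.
    """
    n = X.shape[0]
    D = squareform(pdist(X, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    start = int(np.argmin(np.linalg.norm(X - X.mean(axis=0), axis=1)))
    order = np.empty(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cur = start
    for i in range(n):
        order[i] = cur
        visited[cur] = True
        if i < n - 1:
            d = D[cur].copy()
            d[visited] = np.inf
            cur = int(np.argmin(d))
    return order


def _label_changes(labels_in_order: np.ndarray) -> int:
    return int(np.sum(labels_in_order[1:] != labels_in_order[:-1]))


def _power(order: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
           n_permutations: int) -> float:
    lab = labels[order]
    L = _label_changes(lab)
    perm_counts = np.empty(n_permutations)
    shuffled = labels.copy()
    for i in range(n_permutations):
        rng.shuffle(shuffled)
        perm_counts[i] = _label_changes(shuffled[order])
    baseline = perm_counts.mean()
    if baseline == 0:
        return 0.0
    return float(np.clip(1.0 - L / baseline, 0.0, 1.0))


def scatter_power(
    table: pd.DataFrame,
    label_col: str = "label",
    variables: tuple[str, ...] = FEATURE_COLUMNS,
    n_permutations: int = 200,
    seed: int = 0,
) -> dict:
    """Separability of the labeled classes in standardized variable space.

    Returns ``{"overall": float, "per_class": {label: float},
    "per_variable": {variable: float}}``; all values in [0, 1], higher =
    more separated.  Per-class scores use one-vs-rest labels on the full
    space; per-variable scores rebuild the chain on the single variable.
    Classes with fewer than 2 cases are excluded with a warning.
    """
    counts = table[label_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning("scatter_power: excluding singleton classes %s", small)
        table = table.loc[~table[label_col].isin(small)]
    labels = table[label_col].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("scatter_power needs >= 2 classes with >= 2 cases each")
    X = table.loc[:, list(variables)].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sds

    rng = np.random.default_rng(seed)
    order = _chain_order(Z)
    overall = _power(order, labels, rng, n_permutations)
    per_class = {
        lbl: _power(order, (labels == lbl), rng, n_permutations)
        for lbl in dict.fromkeys(labels)
    }
    per_variable = {}
    for j, var in enumerate(variables):
        order_j = _chain_order(Z[:, [j]])
        per_variable[var] = _power(order_j, labels, rng, n_permutations)
    return {"overall": overall, "per_class": per_class, "per_variable": per_variable}
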