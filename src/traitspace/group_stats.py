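"""Mann–Whitney U tests with Monte-Carlo permutation p-values.

The U statistic counts, over all (x, y) pairs, the pairs where the group-1
value exceeds the group-2 value (ties contribute 1/2).  Because the positive
group here can be as small as half a dozen documents, the p-value is not
taken from the normal approximation but from label permutations: the pooled
values are randomly re-split m times and the p-value is the add-one
estimator (b + 1) / (m + 1), which can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["MWUResult", "mann_whitney_mc", "compare_groups"]

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class MWUResult:
    """One Mann–Whitney comparison: statistic, Monte-Carlo p, and sizes."""

    U: float
    p_mc: float
    n1: int
    n2: int
    n_permutations: int
    seed: int
    alternative: str


def _u_statistic(rank_sum_1: float, n1: int) -> float:
    return rank_sum_1 - n1 * (n1 + 1) / 2.0


def mann_whitney_mc(
    x,
    y,
    n_permutations: int = 10000,
    alternative: str = "two_sided",
    seed: int = 0,
) -> MWUResult:
    """Mann–Whitney U of group x vs group y with a permutation p-value.

    ``alternative='greater'`` tests whether x tends larger than y; the
    two-sided p doubles the smaller tail, capped at 1.  Deterministic for a
    given seed.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties; sums of halves are exact
    u_obs = _u_statistic(ranks[:n1].sum(), n1)

    rng = np.random.default_rng(seed)
    n = n1 + n2
    m = n_permutations
    b_greater = 0
    b_less = 0
    # Random n1-subsets via argpartition of iid uniforms, in chunks to
    # bound memory for large pooled samples.
    chunk = max(1, min(m, int(2_000_000 / max(n, 1))))
    done = 0
    while done < m:
        c = min(chunk, m - done)
        noise = rng.random((c, n))
        idx = np.argpartition(noise, n1 - 1, axis=1)[:, :n1]
        u_perm = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        b_greater += int((u_perm >= u_obs).sum())
        b_less += int((u_perm <= u_obs).sum())
        done += c
    p_greater = (b_greater + 1) / (m + 1)
    p_less = (b_less + 1) / (m + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return MWUResult(
        U=float(u_obs),
        p_mc=float(p),
        n1=n1,
        n2=n2,
        n_permutations=m,
        seed=seed,
        alternative=alternative,
    )


def compare_groups(
    scores,
    labels: pd.Series | None = None,
    n_permutations: int = 10000,
    seed: int = 0,
    alternative: str = "two_sided",
    positive_label: str = "positive",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-trait Mann–Whitney comparison of positive vs comparison scores.

    ``scores`` is a :class:`~traitspace.trait_scoring.ScoreMatrix` (or a
    doc x trait DataFrame with ``labels`` given separately).  Undefined
    cells are excluded pairwise per trait; a trait whose exclusions empty a
    group yields a NaN row without aborting the batch.  Group 1 is the
    positive class, so large U / small one-sided "greater" p means the
    positive texts score higher.  ``adjust='bh'`` appends
    Benjamini–Hochberg adjusted p-values.
    """
    frame = scores.scores if hasattr(scores, "scores") else scores
    if labels is None and hasattr(scores, "labels"):
        labels = scores.labels
    if labels is None:
        raise ValueError("labels are required (in the ScoreMatrix or explicitly)")
    labels = pd.Series(labels).reindex(frame.index)
    if positive_label not in set(labels.dropna()):
        raise ValueError(f"no rows labeled {positive_label!r}")

    rows = []
    for j, trait in enumerate(frame.columns):
        col = frame[trait]
        ok = col.notna() & labels.notna()
        x = col[ok & (labels == positive_label)].to_numpy()
        y = col[ok & (labels != positive_label)].to_numpy()
        trait_seed = (seed + 1_000_003 * (j + 1)) % (2**31)
        if len(x) == 0 or len(y) == 0:
            rows.append(
                {"trait": trait, "U": np.nan, "p_mc": np.nan, "n1": len(x), "n2": len(y)}
            )
            continue
        res = mann_whitney_mc(
            x, y, n_permutations=n_permutations, alternative=alternative, seed=trait_seed
        )
        rows.append(
            {"trait": trait, "U": res.U, "p_mc": res.p_mc, "n1": res.n1, "n2": res.n2}
        )
    table = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = table["p_mc"].notna()
        adjusted = np.full(len(table), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = multipletests(
                table.loc[mask, "p_mc"], method="fdr_bh"
            )[1]
        table["p_bh"] = adjusted
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
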