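"""Exact association tests between subtype labels and clinical categories.

Conditional exact tests on r x c contingency tables with both margins
fixed.  Two orderings of the table space are offered:

* ``"prob"`` — the Freeman-Halton criterion: the two-sided p-value sums
  the multivariate hypergeometric probabilities of all tables whose
  probability does not exceed the observed table's (the classical
  generalization of Fisher's exact test).
* ``"pearson"`` — tables at least as extreme as observed under the
  Pearson chi-square statistic.  This is the ordering used by the
  chi-square row of common clinical statistics packages' exact modules,
  and is the one that reproduces the association table this package
  ships as a fixture.

The exact path enumerates all tables for 2 x c (or r x 2) margins; larger
tables use Monte-Carlo sampling of tables with fixed margins (Patefield
algorithm via :func:`scipy.stats.random_table`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

__all__ = [
    "ContingencyTable",
    "fisher_exact_rxc",
    "mc_vs_exact_check",
    "table1_report",
    "load_reference_counts",
    "EnumerationGuardError",
]

#: Relative slack when comparing table probabilities / statistics at ties,
#: avoiding platform-dependent p-values.
TIE_SLACK = 1e-7

#: Maximum number of candidate tables the exact path will enumerate.
ENUMERATION_GUARD = 10**8


class EnumerationGuardError(ValueError):
    """Exact enumeration would exceed the guard; use method='monte_carlo'."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative counts with labeled margins."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least a 2x2 table")
        if np.any(counts < 0) or counts.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")


def _log_table_prob(tables, row_sums, col_sums, total):
    """Log multivariate hypergeometric probability of tables with fixed margins."""
    const = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
    )
    return const - gammaln(np.asarray(tables, float) + 1).sum(axis=(-2, -1))


def _pearson_stat(tables, row_sums, col_sums, total):
    expected = np.outer(row_sums, col_sums) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (np.asarray(tables, float) - expected) ** 2 / expected
    return np.nansum(term, axis=(-2, -1))


def _criterion(tables, observed, rs, cs, n, ordering):
    """Boolean mask of tables at least as extreme as the observed one."""
    if ordering == "prob":
        lp = _log_table_prob(tables, rs, cs, n)
        lp_obs = _log_table_prob(observed, rs, cs, n)
        return lp <= lp_obs + TIE_SLACK, lp
    if ordering == "pearson":
        st = _pearson_stat(tables, rs, cs, n)
        st_obs = _pearson_stat(observed, rs, cs, n)
        return st >= st_obs * (1 - TIE_SLACK) - TIE_SLACK, None
    raise ValueError(f"unknown ordering {ordering!r}")


def _enumerate_2xc(row_sums, col_sums):
    """All 2 x c tables with the given margins, as an (m, 2, c) array."""
    c = len(col_sums)
    n_candidates = int(np.prod([col_sums[j] + 1 for j in range(c - 1)]))
    if n_candidates > ENUMERATION_GUARD:
        raise EnumerationGuardError(
            f"{n_candidates} candidate tables exceed the enumeration guard; "
            "use method='monte_carlo'"
        )
    grids = np.meshgrid(
        *[np.arange(col_sums[j] + 1) for j in range(c - 1)], indexing="ij"
    )
    last = row_sums[0] - sum(grids)
    ok = (last >= 0) & (last <= col_sums[-1])
    first_rows = np.stack([g[ok] for g in grids] + [last[ok]], axis=-1)
    return np.stack([first_rows, col_sums - first_rows], axis=1)


def fisher_exact_rxc(table, method="auto", ordering="prob", reps=10**6, seed=0):
    """Two-sided conditional exact test on an r x c table.

    Parameters
    ----------
    table : ContingencyTable or array-like of counts
    method : 'exact', 'monte_carlo' or 'auto'
        'exact' enumerates all tables (2 x c / r x 2 margins only, within
        the enumeration guard); 'monte_carlo' estimates the same
        quantity by sampling ``reps`` tables with fixed margins; 'auto'
        chooses 'exact' when either margin has two levels, otherwise
        'monte_carlo'.
    ordering : 'prob' (Freeman-Halton) or 'pearson' (chi-square-ordered)
    reps, seed : Monte-Carlo settings (``reps`` must be >= 10**4).

    Returns the p-value in (0, 1].
    """
    counts = table.counts if isinstance(table, ContingencyTable) else None
    if counts is None:
        counts = ContingencyTable(np.asarray(table)).counts
    rs, cs, n = counts.sum(axis=1), counts.sum(axis=0), counts.sum()
    # degenerate margins: only one table is possible
    if (rs > 0).sum() < 2 or (cs > 0).sum() < 2:
        return 1.0

    if method == "auto":
        method = "exact" if 2 in counts.shape else "monte_carlo"

    if method == "exact":
        transposed = False
        work = counts
        if work.shape[0] != 2 and work.shape[1] == 2:
            work, transposed = work.T, True
        if work.shape[0] != 2:
            raise EnumerationGuardError(
                "exact enumeration supports 2 x c (or r x 2) margins only; "
                "use method='monte_carlo'"
            )
        wrs, wcs = work.sum(axis=1), work.sum(axis=0)
        tables = _enumerate_2xc(wrs, wcs)
        extreme, lp = _criterion(tables, work, wrs, wcs, n, ordering)
        if lp is None:
            lp = _log_table_prob(tables, wrs, wcs, n)
        weights = np.exp(lp - lp.max())
        p = weights[extreme].sum() / weights.sum()
        return float(min(p, 1.0))

    if method == "monte_carlo":
        if reps < 10**4:
            raise ValueError("monte_carlo requires reps >= 10**4")
        rng = np.random.default_rng(seed)
        sampled = random_table(rs, cs).rvs(reps, random_state=rng)
        if sampled.ndim == 2:
            sampled = sampled[None]
        extreme, _ = _criterion(sampled, counts, rs, cs, n, ordering)
        # add-one estimator keeps p in (0, 1]
        return float((np.count_nonzero(extreme) + 1) / (reps + 1))

    raise ValueError(f"unknown method {method!r}")


def mc_vs_exact_check(table, reps=10**5, seed=0, ordering="prob"):
    """Agreement report between the exact and Monte-Carlo p-values.

    The Monte-Carlo estimate should lie within three binomial standard
    errors of the exact p at the given number of replicates.
    """
    p_exact = fisher_exact_rxc(table, method="exact", ordering=ordering)
    p_mc = fisher_exact_rxc(
        table, method="monte_carlo", ordering=ordering, reps=reps, seed=seed
    )
    se = float(np.sqrt(p_exact * (1 - p_exact) / reps))
    return {
        "p_exact": p_exact,
        "p_mc": p_mc,
        "binomial_se": se,
        "agrees": bool(abs(p_mc - p_exact) <= max(3 * se, 2 / reps)),
    }


#: Covariates of the reference association table, in its row order.
REFERENCE_VARIABLES = (
    "age_group", "sex", "stage", "pT", "pN", "pM", "grade", "location",
    "histology",
)


def load_reference_counts():
    """Published covariate-by-subtype counts shipped with the package.

    Returns a dict mapping covariate name to a
    :class:`ContingencyTable` (rows: covariate levels, columns: the four
    subtype labels).
    """
    path = resources.files("cmslike").joinpath("data/table1_counts.json")
    raw = json.loads(path.read_text())
    out = {}
    for var, entry in raw["variables"].items():
        out[var] = ContingencyTable(
            np.asarray(entry["counts"], dtype=np.int64),
            row_labels=tuple(entry["levels"]),
            col_labels=tuple(raw["subtypes"]),
        )
    return out


def table1_report(patients, variables=None, ordering="pearson", reps=10**6,
                  seed=0):
    """Association table: covariate x subtype counts, column %, p-value.

    ``patients`` must carry ``cms_label`` plus the covariate columns;
    unclassified patients and missing covariate values are dropped
    row-wise.  Exact enumeration is used for two-level covariates,
    Monte-Carlo otherwise.  Returns a data frame with one row per
    covariate level and the per-covariate p on its first row.
    """
    if variables is None:
        variables = [v for v in REFERENCE_VARIABLES if v in patients.columns]
    classified = patients[patients["cms_label"] != "unclassified"]
    subtype_labels = ["CMS1-like", "CMS2-like", "CMS3-like", "CMS4-like"]
    rows = []
    for var in variables:
        sub = classified.dropna(subset=[var])
        levels = sorted(sub[var].unique())
        if len(levels) < 2:
            continue
        counts = np.array(
            [
                [
                    int(((sub[var] == lev) & (sub["cms_label"] == lab)).sum())
                    for lab in subtype_labels
                ]
                for lev in levels
            ]
        )
        tab = ContingencyTable(counts, tuple(levels), tuple(subtype_labels))
        p = fisher_exact_rxc(tab, method="auto", ordering=ordering, reps=reps,
                             seed=seed)
        col_tot = counts.sum(axis=0)
        for i, lev in enumerate(levels):
            row = {"variable": var, "level": lev,
                   "p_value": p if i == 0 else np.nan}
            for j, lab in enumerate(subtype_labels):
                row[f"{lab} n"] = counts[i, j]
                row[f"{lab} %"] = (
                    100.0 * counts[i, j] / col_tot[j] if col_tot[j] else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
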