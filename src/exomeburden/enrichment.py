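"""Hypergeometric gene-set enrichment with subsampling sensitivity analysis.

Overlap-based enrichment: for each set, the p-value is the upper tail of
the hypergeometric distribution (probability of at least the observed
overlap when |query| genes are drawn from the universe), adjusted across
sets with Benjamini-Hochberg.  Stability of a significant term is
quantified by re-running the enrichment on many random subsets of the query
of variable size and recording how often the term stays significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetLibrary:
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("library contains no gene sets")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if not self.universe:
            self.universe = set().union(*self.sets.values())
        clipped = {n: s & self.universe for n, s in self.sets.items()}
        empty = [n for n, s in clipped.items() if not s]
        if empty:
            raise ValueError(
                f"gene set(s) disjoint from the universe after harmonization: {empty}"
            )
        self.sets = clipped


def load_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetLibrary:
    """Read a GMT library (set name, description, tab-separated members).

    Member identifiers are uppercased and deduplicated within each set.  The
    universe defaults to the union of all sets unless supplied.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {line_no}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name = fields[0]
            members = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not members:
                raise ValueError(f"{path}, line {line_no}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    universe = {g.upper() for g in universe} if universe else set()
    return GeneSetLibrary(sets=sets, universe=universe)


def write_gmt(library: GeneSetLibrary, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def enrich(query: set[str] | list[str], library: GeneSetLibrary) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query gene list.

    Returns one row per library set with overlap counts, raw p and BH
    adjusted p, sorted by adjusted p.  The query is first intersected with
    the universe; a disjoint query is an error.
    """
    q = {str(g).upper() for g in query} & library.universe
    if not q:
        raise ValueError("query is disjoint from the library universe")
    m = len(library.universe)
    nq = len(q)
    rows = []
    for name, members in library.sets.items():
        k = len(q & members)
        # P(overlap >= k) drawing nq genes from a universe with |set| successes
        p = float(stats.hypergeom.sf(k - 1, m, len(members), nq))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": nq,
                "universe_size": m,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(sorted(q & members)),
            }
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["adjusted_p", "p_value", "set_name"]).reset_index(drop=True)


@dataclass
class SensitivityReport:
    proportions: pd.DataFrame  # per set: proportion of subsamples significant
    per_size: pd.DataFrame     # set x subsample size breakdown
    n_subsamples: int
    size_range: tuple[int, int]
    alpha: float


def subsample_sensitivity(
    query: set[str] | list[str],
    library: GeneSetLibrary,
    n_subsamples: int = 71_000,
    size_range: tuple[int, int] = (30, 100),
    alpha: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """Stability of enrichment under random subsampling of the query.

    Each subsample draws a uniform size from ``size_range`` (clamped to the
    query size) and that many query genes without replacement, re-runs the
    enrichment, and records which sets reach adjusted p < ``alpha``.
    Deterministic given ``seed``.
    """
    if n_subsamples < 1:
        raise ValueError(f"n_subsamples must be >= 1, got {n_subsamples}")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size_range {size_range}")
    q = sorted({str(g).upper() for g in query} & library.universe)
    if not q:
        raise ValueError("query is disjoint from the library universe")
    if lo > len(q):
        raise ValueError(
            f"minimum subsample size {lo} exceeds the query size {len(q)}"
        )
    hi = min(hi, len(q))
    rng = np.random.default_rng([seed, 0x5E5])
    set_names = list(library.sets)
    sig_counts = {name: 0 for name in set_names}
    size_hits: dict[tuple[str, int], int] = {}
    size_totals: dict[int, int] = {}
    q_arr = np.array(q)
    for _ in range(n_subsamples):
        size = int(rng.integers(lo, hi + 1))
        sub = q_arr[rng.choice(len(q_arr), size=size, replace=False)]
        res = enrich(set(sub), library)
        size_totals[size] = size_totals.get(size, 0) + 1
        for r in res.itertuples():
            if r.adjusted_p < alpha:
                sig_counts[r.set_name] += 1
                key = (r.set_name, size)
                size_hits[key] = size_hits.get(key, 0) + 1
    proportions = pd.DataFrame(
        {
            "set_name": set_names,
            "proportion_significant": [
                sig_counts[n] / n_subsamples for n in set_names
            ],
        }
    )
    per_size_rows = []
    for name in set_names:
        for size in sorted(size_totals):
            per_size_rows.append(
                {
                    "set_name": name,
                    "size": size,
                    "n_subsamples": size_totals[size],
                    "proportion_significant": size_hits.get((name, size), 0)
                    / size_totals[size],
                }
            )
    return SensitivityReport(
        proportions=proportions,
        per_size=pd.DataFrame(per_size_rows),
        n_subsamples=n_subsamples,
        size_range=(lo, hi),
        alpha=alpha,
    )
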