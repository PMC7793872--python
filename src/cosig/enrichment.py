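"""Right-tailed Fisher (hypergeometric) gene-set enrichment against GMT sets.

The enrichment p-value for an overlap of k genes between a signature of
size n and a set of size K inside a universe of N genes is the upper tail
P(X >= k) of a hypergeometric distribution — identical to the one-sided
Fisher exact test on the 2x2 overlap table.  Scores are -log10(p), so the
conventional score >= 1.3 significance rule corresponds to p <= 0.05.

The default universe is the measured transcriptome (the genes surviving the
annotation filter), not the union of the gene sets: the background for an
enrichment question should be the assayable set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, FormatError

__all__ = [
    "GeneSetCollection",
    "load_gmt",
    "write_gmt",
    "hypergeom_right_tail",
    "score_from_p",
    "fisher_enrichment",
    "overlap_fraction",
]

MIN_TESTABLE_SET = 3  # sets smaller than this after universe intersection are untested
_TINY = 5e-324  # smallest subnormal double; floors p before taking -log10


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    "GMT line needs name, description and at least one member",
                    line=lineno,
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"duplicate set name {name!r}", line=lineno)
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"gene set {name!r} has no members", line=lineno)
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_right_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def score_from_p(p: float) -> float:
    """Enrichment score -log10(p); p is floored at the smallest positive double."""
    return -math.log10(max(p, _TINY))


def fisher_enrichment(
    signature: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_score: float = 1.3,
) -> pd.DataFrame:
    """Right-tailed Fisher enrichment of ``signature`` in every set.

    Each set is intersected with the universe before testing; sets smaller
    than ``MIN_TESTABLE_SET`` after intersection are reported with
    ``tested = False`` and NaN p.  Returns a DataFrame sorted by score
    descending with columns set, k, K, n, N, p_right, p_bh, score,
    significant, tested, overlap_genes.
    """
    signature = set(signature)
    universe = set(universe)
    offenders = signature - universe
    if offenders:
        raise ConsistencyError(
            f"signature gene(s) outside universe: {sorted(offenders)[:10]}"
        )
    N = len(universe)
    n = len(signature)
    rows = []
    for name, members in collection.sets.items():
        members_in = members & universe
        K = len(members_in)
        overlap = sorted(members_in & signature)
        k = len(overlap)
        tested = K >= MIN_TESTABLE_SET
        if tested:
            p = hypergeom_right_tail(N, K, n, k)
            score = score_from_p(p)
        else:
            p, score = np.nan, np.nan
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_right": p,
                "score": score,
                "significant": bool(tested and score >= min_score),
                "tested": tested,
                "overlap_genes": "|".join(overlap),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set", "k", "K", "n", "N", "p_right", "score",
            "significant", "tested", "overlap_genes",
        ],
    )
    tested_mask = result["tested"].to_numpy(dtype=bool)
    p_bh = np.full(len(result), np.nan)
    if tested_mask.any():
        p_bh[tested_mask] = multipletests(
            result.loc[tested_mask, "p_right"], method="fdr_bh"
        )[1]
    result.insert(6, "p_bh", p_bh)
    result = result.sort_values(
        ["score", "set"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return result


def overlap_fraction(k: int, K: int) -> float:
    """Percentage of a gene set covered by the signature overlap: 100 * k / K."""
    if K == 0:
        raise ZeroDivisionError("overlap fraction undefined for an empty set (K = 0)")
    if not 0 <= k <= K:
        raise ValueError("need 0 <= k <= K")
    return 100.0 * k / K
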