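"""Hypergeometric term enrichment and Fisher-exact gene-set overlap.

The enrichment core mirrors the hypergeometric over-representation model
used throughout functional genomics: for a query of n genes drawn from a
universe of N, a term with K members in the universe and k in the query has
upper-tail p = P(X >= k) with X ~ Hypergeometric(N, K, n). Overlap between
two gene lists is tested with a one-sided (greater) Fisher exact test on
the 2×2 membership table. Both use BH adjustment across terms or sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .diffexpr import adjust_bh


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are evaluated against."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def restricted(self) -> dict[str, set[str]]:
        """Each set intersected with the universe."""
        return {name: s & self.universe for name, s in self.sets.items()}


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (term, description, members, tab-separated).

    Duplicate members within a term are collapsed. If ``universe`` is not
    given, the union of all members is used.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has < 3 fields")
            term, description, *members = fields
            sets[term] = set(m for m in members if m)
            desc[term] = description
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, members in collection.sets.items():
            desc = collection.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(query, collection: GeneSetCollection,
                     p_cutoff: float = 0.05,
                     min_term_size: int = 3,
                     max_term_frac: float = 0.5) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query.

    The query is intersected with the universe first; terms smaller than
    ``min_term_size`` or larger than ``max_term_frac`` of the universe are
    skipped (uninformative extremes). Rows are BH-adjusted across all tested
    terms, flagged significant at ``padj < p_cutoff`` and sorted by p.
    """
    universe = collection.universe
    n_univ = len(universe)
    if n_univ == 0:
        raise ValueError("empty universe")
    q = set(query) & universe
    n = len(q)
    rows = []
    for term, members in collection.restricted().items():
        K = len(members)
        if K < min_term_size or K > max_term_frac * n_univ:
            continue
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, n_univ, K, n))
        fold = (k / n) / (K / n_univ) if n > 0 else np.nan
        rows.append({"term": term,
                     "description": collection.descriptions.get(term, ""),
                     "k": k, "n": n, "K": K, "N": n_univ,
                     "p": p, "fold_enrichment": fold})
    out = pd.DataFrame(rows, columns=["term", "description", "k", "n", "K",
                                      "N", "p", "fold_enrichment"])
    if len(out):
        out["padj"] = adjust_bh(out["p"].to_numpy())
        out["significant"] = out["padj"] < p_cutoff
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Fisher-exact overlap
# ---------------------------------------------------------------------------

def fisher_overlap(set_a, set_b, universe_n: int,
                   alternative: str = "greater"
                   ) -> tuple[float, float]:
    """Fisher exact test of the overlap between two gene sets.

    Builds the 2×2 table ``[[o, |a|-o], [|b|-o, N-|a|-|b|+o]]`` and returns
    ``(odds_ratio, p)``. The sample odds ratio uses a 0.5 continuity
    correction when any cell is zero. The default one-sided "greater"
    alternative asks for over-enrichment of the overlap.
    """
    a, b = set(set_a), set(set_b)
    o = len(a & b)
    n11 = o
    n12 = len(a) - o
    n21 = len(b) - o
    n22 = universe_n - len(a) - len(b) + o
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("inconsistent sizes: universe smaller than sets")
    table = np.array([[n11, n12], [n21, n22]])
    _, p = fisher_exact(table, alternative=alternative)
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def overlap_matrix(candidates, external_sets: dict[str, set[str]],
                   universe_n: int, alpha: float = 0.05,
                   alternative: str = "greater") -> pd.DataFrame:
    """Fisher-exact overlap of the candidate set with each external set,
    BH-adjusted across sets."""
    if not external_sets:
        raise ValueError("need at least one external set")
    cand = set(candidates)
    rows = []
    for name, genes in external_sets.items():
        odds, p = fisher_overlap(cand, genes, universe_n,
                                 alternative=alternative)
        rows.append({"dataset": name, "n_set": len(set(genes)),
                     "overlap": len(cand & set(genes)),
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["padj"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out
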