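"""Classification of disproportionately differentially expressed genes.

Genes whose expression difference between jerboa and mouse is specific to
the disproportionately elongating vertebra (TV6) fall into two categories:

* **set A** — significant between species in TV6 but not in TV1;
* **set B** — significant in both vertebrae, but with a TV6 log2FC outside
  the 95% prediction interval of the OLS regression of TV6 log2FC on TV1
  log2FC fitted over the both-significant genes (most both-significant
  genes are near-equivalently differentially expressed and lie on the line).

The union D = A ∪ B is then intersected with the intra-jerboa TV6-vs-TV1
contrast, requiring the same direction of change, to produce the final
candidate set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import t as student_t


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def build_pair_table(de_tv1: pd.DataFrame, de_tv6: pd.DataFrame,
                     de_intra: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-gene contrast table from three DE results.

    Columns: ``lfc_x, padj_x`` (interspecies TV1), ``lfc_y, padj_y``
    (interspecies TV6), ``lfc_intra, padj_intra`` (jerboa TV6 vs TV1).
    Genes appearing in any input are kept; missing padj counts as not
    significant downstream.
    """
    genes = de_tv1.index.union(de_tv6.index).union(de_intra.index)
    out = pd.DataFrame(index=genes)
    out["lfc_x"] = de_tv1["lfc"].reindex(genes)
    out["padj_x"] = de_tv1["padj"].reindex(genes)
    out["lfc_y"] = de_tv6["lfc"].reindex(genes)
    out["padj_y"] = de_tv6["padj"].reindex(genes)
    out["lfc_intra"] = de_intra["lfc"].reindex(genes)
    out["padj_intra"] = de_intra["padj"].reindex(genes)
    out.index.name = "gene_id"
    return out


def _sig(padj: pd.Series, alpha: float) -> pd.Series:
    return padj.notna() & (padj < alpha)


# ---------------------------------------------------------------------------
# set A: TV6-only
# ---------------------------------------------------------------------------

def classify_tv6_only(pairs: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes significant between species in TV6 but not in TV1."""
    in_a = _sig(pairs["padj_y"], alpha) & ~_sig(pairs["padj_x"], alpha)
    return set(pairs.index[in_a])


# ---------------------------------------------------------------------------
# OLS fit + prediction interval
# ---------------------------------------------------------------------------

@dataclass
class PIFit:
    """OLS fit of TV6 log2FC on TV1 log2FC with prediction-interval state.

    Stores everything the textbook interval for a new observation needs:
    ``halfwidth(x0) = t_crit * s_e * sqrt(1 + 1/n + (x0 - x_mean)^2 / Sxx)``.
    """

    intercept: float
    slope: float
    n: int
    x_mean: float
    sxx: float
    s_e: float
    r2: float
    level: float = 0.95
    t_crit: float = 0.0

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def fit_lfc_regression(pairs: pd.DataFrame, alpha: float = 0.05,
                       level: float = 0.95) -> PIFit:
    """OLS of TV6 log2FC (y) on TV1 log2FC (x) over the both-significant set.

    The fit is single-pass: planted or real outliers are not excluded before
    fitting, matching an intersect-then-classify workflow.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    both = _sig(pairs["padj_x"], alpha) & _sig(pairs["padj_y"], alpha)
    x = pairs.loc[both, "lfc_x"].to_numpy(dtype=float)
    y = pairs.loc[both, "lfc_y"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 both-significant genes to fit")
    x_mean = float(x.mean())
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate x: no spread in TV1 log2FCs")
    slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    s_e = float(np.sqrt(sse / (n - 2)))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    t_crit = float(student_t.ppf(0.5 + level / 2.0, df=n - 2))
    return PIFit(intercept=intercept, slope=slope, n=n, x_mean=x_mean,
                 sxx=sxx, s_e=s_e, r2=r2, level=level, t_crit=t_crit)


def prediction_interval(fit: PIFit, x0) -> tuple[np.ndarray, np.ndarray]:
    """Prediction interval for a new observation at ``x0`` (lo, hi)."""
    if fit.n < 3:
        raise ValueError("fit must use >= 3 points")
    x0 = np.asarray(x0, dtype=float)
    yhat = fit.predict(x0)
    hw = fit.t_crit * fit.s_e * np.sqrt(
        1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx)
    return yhat - hw, yhat + hw


def classify_outside_pi(pairs: pd.DataFrame, fit: PIFit,
                        alpha: float = 0.05) -> set[str]:
    """Both-significant genes whose TV6 log2FC falls outside the prediction
    interval at their TV1 log2FC; boundary-exact values count as inside."""
    both = _sig(pairs["padj_x"], alpha) & _sig(pairs["padj_y"], alpha)
    x = pairs.loc[both, "lfc_x"].to_numpy(dtype=float)
    y = pairs.loc[both, "lfc_y"].to_numpy(dtype=float)
    lo, hi = prediction_interval(fit, x)
    outside = (y < lo) | (y > hi)
    return set(pairs.index[both][outside])


# ---------------------------------------------------------------------------
# sign-consistent intersection
# ---------------------------------------------------------------------------

def sign_consistent_intersection(pairs: pd.DataFrame, set_d: set[str],
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Intersect D = A ∪ B with the intra-jerboa contrast, keeping genes
    whose intra-jerboa TV6-vs-TV1 change shares the sign of their
    interspecies TV6 change.

    Returns a DataFrame indexed by candidate gene with a ``direction``
    column (``up_in_jerboa_TV6`` / ``down_in_jerboa_TV6``).
    """
    d_idx = pairs.index.intersection(sorted(set_d))
    sub = pairs.loc[d_idx]
    sig_intra = _sig(sub["padj_intra"], alpha)
    sign_y = np.sign(sub["lfc_y"].to_numpy(dtype=float))
    sign_i = np.sign(sub["lfc_intra"].to_numpy(dtype=float))
    zero = (sign_y == 0) | (sign_i == 0)
    if (zero & sig_intra.to_numpy()).any():
        warnings.warn("gene with zero log2FC but significant padj excluded "
                      "from the candidate set", stacklevel=2)
    keep = sig_intra.to_numpy() & (sign_y == sign_i) & ~zero
    cand = sub.index[keep]
    direction = np.where(sign_y[keep] > 0, "up_in_jerboa_TV6",
                         "down_in_jerboa_TV6")
    return pd.DataFrame({"direction": direction}, index=cand)


# ---------------------------------------------------------------------------
# full classification
# ---------------------------------------------------------------------------

@dataclass
class DisproportionalityResult:
    """All gene sets of the intersection analysis plus the fitted line."""

    set_A: set[str]
    set_pairs: set[str]
    set_B: set[str]
    set_D: set[str]
    candidates: pd.DataFrame      # index gene_id, column direction
    fit: PIFit

    def category_table(self, all_genes) -> pd.DataFrame:
        """Per-gene category ∈ {A, B, equivalent, none}, candidate flag and
        direction, over ``all_genes``."""
        idx = pd.Index(all_genes, name="gene_id")
        cat = pd.Series("none", index=idx, dtype=object)
        cat[idx.isin(sorted(self.set_pairs - self.set_B))] = "equivalent"
        cat[idx.isin(sorted(self.set_A))] = "A"
        cat[idx.isin(sorted(self.set_B))] = "B"
        out = pd.DataFrame({"category": cat})
        out["candidate"] = idx.isin(self.candidates.index)
        out["direction"] = self.candidates["direction"].reindex(idx)
        return out


def classify(pairs: pd.DataFrame, alpha: float = 0.05,
             level: float = 0.95) -> DisproportionalityResult:
    """Run the full TV6-only / outside-PI / sign-consistency classification."""
    set_a = classify_tv6_only(pairs, alpha)
    both = _sig(pairs["padj_x"], alpha) & _sig(pairs["padj_y"], alpha)
    set_pairs = set(pairs.index[both])
    fit = fit_lfc_regression(pairs, alpha=alpha, level=level)
    set_b = classify_outside_pi(pairs, fit, alpha)
    set_d = set_a | set_b
    candidates = sign_consistent_intersection(pairs, set_d, alpha)
    return DisproportionalityResult(set_A=set_a, set_pairs=set_pairs,
                                    set_B=set_b, set_D=set_d,
                                    candidates=candidates, fit=fit)


# ---------------------------------------------------------------------------
# collation against external datasets
# ---------------------------------------------------------------------------

def collate_candidates(candidates,
                       external_sets: dict[str, set[str]],
                       phenotype_genes: set[str] | None = None,
                       highlight_min_datasets: int = 3) -> pd.DataFrame:
    """Collate candidate genes against external gene lists.

    Gene matching is case-insensitive exact string match. Per candidate, the
    table records membership in each external set, the tail-phenotype flag,
    the number of external datasets hit, a ``highlight`` flag (phenotype OR
    membership in >= ``highlight_min_datasets`` datasets) and whether the
    gene is common to every provided external set.
    """
    if not external_sets:
        raise ValueError("need at least one external set")
    phenotype_genes = phenotype_genes or set()
    cand = list(candidates)
    low = [g.lower() for g in cand]
    sets_low = {name: {g.lower() for g in genes}
                for name, genes in external_sets.items()}
    pheno_low = {g.lower() for g in phenotype_genes}

    out = pd.DataFrame(index=pd.Index(cand, name="gene_id"))
    for name, genes in sets_low.items():
        out[name] = [g in genes for g in low]
    out["n_datasets"] = out[list(sets_low)].sum(axis=1)
    out["phenotype"] = [g in pheno_low for g in low]
    out["highlight"] = out["phenotype"] | (
        out["n_datasets"] >= highlight_min_datasets)
    out["in_all_sets"] = out[list(sets_low)].all(axis=1)
    return out
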