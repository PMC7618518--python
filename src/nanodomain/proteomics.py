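"""Proximity-labeling hit calling from spectral-count matrices.

Antibody-anchored peroxidase labeling biotinylates proteins within a short
radius of the target; captured proteins are identified by MS and
semi-quantified by spectral counts.  Hits are proteins whose mean count in
the target-antibody condition exceeds the isotype-control condition by at
least max(2, global capture ratio), after removing contaminants and
single-peptide identifications.

Count matrices are DataFrames with columns ``protein_id``, ``gene``,
``unique_peptides`` followed by ``<condition>_rep<k>`` count columns for
the ``target`` and ``isotype`` conditions.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

META_COLUMNS = ["protein_id", "gene", "unique_peptides"]
_REP_RE = re.compile(r"^(?P<cond>[A-Za-z0-9]+)_rep(?P<k>\d+)$")


def replicate_columns(matrix: pd.DataFrame) -> dict:
    """Map condition name -> ordered list of its replicate columns."""
    conds: dict = {}
    for col in matrix.columns:
        m = _REP_RE.match(col)
        if m:
            conds.setdefault(m.group("cond"), []).append(col)
    for cols in conds.values():
        cols.sort(key=lambda c: int(_REP_RE.match(c).group("k")))
    return conds


def default_contaminants() -> set:
    """Packaged contaminant gene symbols (keratins and common cRAP-style
    adventitious proteins), upper-cased."""
    text = resources.files("nanodomain.data").joinpath(
        "contaminants.txt").read_text()
    return {line.strip().upper() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}


def load_gene_list(path) -> set:
    """One gene symbol per line; '#' comments and blanks ignored."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh
                if line.strip() and not line.startswith("#")}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def preprocess_counts(matrix: pd.DataFrame, contaminant_genes=None,
                      min_unique_peptides: int = 2) -> pd.DataFrame:
    """Remove contaminant genes (case-insensitive) and proteins identified
    by fewer than ``min_unique_peptides`` unique peptides."""
    if contaminant_genes is None:
        contaminant_genes = default_contaminants()
    contaminant_genes = {g.upper() for g in contaminant_genes}
    keep = (~matrix["gene"].astype(str).str.upper().isin(contaminant_genes)
            & (matrix["unique_peptides"] >= min_unique_peptides))
    out = matrix.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("preprocessing removed every protein", UserWarning,
                      stacklevel=2)
    return out


def enrichment_table(matrix: pd.DataFrame,
                     zero_isotype: str = "inf",
                     pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-protein enrichment: mean(target reps) / mean(isotype reps).

    A zero isotype mean with positive target mean gives +inf (absence in
    the control is maximal enrichment) and sets ``zero_isotype``;
    0/0 gives 0 and sets ``undetected``.  ``zero_isotype="pseudocount"``
    instead adds ``pseudocount`` to both means.
    """
    conds = replicate_columns(matrix)
    for cond in ("target", "isotype"):
        if cond not in conds:
            raise ValueError(f"matrix lacks {cond!r} replicate columns")
    mt = matrix[conds["target"]].mean(axis=1).to_numpy(float)
    mi = matrix[conds["isotype"]].mean(axis=1).to_numpy(float)
    if zero_isotype == "pseudocount":
        enr = (mt + pseudocount) / (mi + pseudocount)
        zflag = np.zeros(len(mt), dtype=bool)
    elif zero_isotype == "inf":
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(mi > 0, mt / np.where(mi > 0, mi, 1.0),
                           np.where(mt > 0, np.inf, 0.0))
        zflag = (mi == 0) & (mt > 0)
    else:
        raise ValueError("zero_isotype must be 'inf' or 'pseudocount'")
    out = matrix[META_COLUMNS].copy()
    out["mean_target"] = mt
    out["mean_isotype"] = mi
    out["enrichment"] = enr
    out["zero_isotype"] = zflag
    out["undetected"] = (mi == 0) & (mt == 0)
    return out


def global_capture_ratio(matrix: pd.DataFrame,
                         mode: str = "total") -> float:
    """Total target-condition counts over total isotype-condition counts
    (summed across proteins and replicates); ``mode="replicate_mean"``
    averages per-replicate totals instead."""
    conds = replicate_columns(matrix)
    t = matrix[conds["target"]].to_numpy(float)
    i = matrix[conds["isotype"]].to_numpy(float)
    if i.sum() == 0:
        raise ValueError("isotype condition has zero total counts")
    if mode == "total":
        return float(t.sum() / i.sum())
    if mode == "replicate_mean":
        return float(t.sum(axis=0).mean() / i.sum(axis=0).mean())
    raise ValueError("mode must be 'total' or 'replicate_mean'")


def call_hits(enrichments: pd.DataFrame, global_ratio: float) -> pd.DataFrame:
    """Flag hits: enrichment >= max(2, global capture ratio); +inf
    enrichment (absent from the isotype) is always a hit."""
    out = enrichments.copy()
    threshold = max(2.0, float(global_ratio))
    out["global_ratio"] = float(global_ratio)
    out["threshold"] = threshold
    out["hit"] = out["enrichment"] >= threshold
    return out


def intersect_hits(hit_lists: dict) -> dict:
    """Exact set algebra over per-cell-line hit sets.

    Returns ``classes`` (frozenset of line names -> genes exactly in those
    lines), ``at_least`` (k -> genes in >= k lines), ``all`` and
    per-line ``unique`` sets.
    """
    if len(hit_lists) < 2:
        raise ValueError("need at least two hit lists to intersect")
    names = list(hit_lists)
    sets = {n: set(hit_lists[n]) for n in names}
    universe = set().union(*sets.values())
    classes: dict = {}
    counts: dict = {}
    for g in universe:
        members = frozenset(n for n in names if g in sets[n])
        classes.setdefault(members, set()).add(g)
        counts[g] = len(members)
    at_least = {k: {g for g, c in counts.items() if c >= k}
                for k in range(1, len(names) + 1)}
    unique = {n: classes.get(frozenset([n]), set()) for n in names}
    return {"classes": classes, "at_least": at_least,
            "all": at_least[len(names)], "unique": unique}


def rbp_fraction(hit_set, rbp_genes) -> float:
    """Percentage of hits annotated as RNA-binding proteins
    (case-insensitive gene-symbol match); NaN for an empty hit set."""
    hits = {str(g).upper() for g in hit_set}
    rbps = {str(g).upper() for g in rbp_genes}
    if not hits:
        warnings.warn("empty hit set: RBP fraction undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return 100.0 * len(hits & rbps) / len(hits)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class EnrichmentHitCaller(BaseEstimator):
    """Spectral-count enrichment hit calling as a fit-style estimator.

    ``fit`` runs contaminant / unique-peptide preprocessing, per-protein
    enrichment over the isotype, the global capture ratio, and the
    max(2, ratio) hit threshold on one count matrix.

    Attributes
    ----------
    hit_table_ : DataFrame with per-protein enrichment and hit flags.
    hits_ : set of hit protein_ids.
    hit_genes_ : set of hit gene symbols.
    global_ratio_, threshold_ : floats used for the decision rule.
    """

    def __init__(self, min_unique_peptides: int = 2,
                 contaminant_genes=None, zero_isotype: str = "inf",
                 pseudocount: float = 0.5, ratio_mode: str = "total"):
        self.min_unique_peptides = min_unique_peptides
        self.contaminant_genes = contaminant_genes
        self.zero_isotype = zero_isotype
        self.pseudocount = pseudocount
        self.ratio_mode = ratio_mode

    def fit(self, X: pd.DataFrame, y=None):
        clean = preprocess_counts(X, self.contaminant_genes,
                                  self.min_unique_peptides)
        enr = enrichment_table(clean, self.zero_isotype, self.pseudocount)
        self.global_ratio_ = global_capture_ratio(clean, self.ratio_mode)
        self.hit_table_ = call_hits(enr, self.global_ratio_)
        self.threshold_ = float(self.hit_table_["threshold"].iloc[0]) if len(
            self.hit_table_) else max(2.0, self.global_ratio_)
        hits = self.hit_table_.loc[self.hit_table_["hit"]]
        self.hits_ = set(hits["protein_id"])
        self.hit_genes_ = set(hits["gene"].astype(str))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Hit flags for the rows of X under the fitted threshold."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "threshold_")
        enr = enrichment_table(X, self.zero_isotype, self.pseudocount)
        return (enr["enrichment"] >= self.threshold_).to_numpy()


__all__ = [
    "META_COLUMNS", "replicate_columns", "default_contaminants",
    "load_gene_list", "preprocess_counts", "enrichment_table",
    "global_capture_ratio", "call_hits", "intersect_hits", "rbp_fraction",
    "EnrichmentHitCaller",
]
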