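"""Frequency and redundancy analysis over collections of minimal networks.

The central quantity is a gene's retention fraction (its *NED degree*):
the fraction of minimal metabolic networks in a collection that retain
the gene.  Non-essential genes retained in more than 95% of MMNs form
the NED (Network Efficiency Determinant) class; genes never retained
are fully redundant; the remainder are variably retained.  Genes
flagged essential were never deletion candidates and are reported
separately with retention 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ContractError
from .evolve import MMNCollection
from .model import MetabolicModel, ModelSummary, summarise

__all__ = [
    "retention_frequencies",
    "classify_genes",
    "ned_genes",
    "always_retained",
    "pairwise_shared_reactions",
    "search_space_size",
    "genes_per_mmn",
]

NED_THRESHOLD_DEFAULT = 0.95


def retention_frequencies(collection: MMNCollection) -> pd.DataFrame:
    """Per-gene fraction of MMNs retaining the gene.

    Returns a DataFrame indexed by gene with columns
    ``retention_fraction`` and ``essential``.  Essential genes are
    reported with fraction 1 (they are retained by construction).
    """
    if len(collection) == 0:
        raise ContractError("collection is empty")
    model = collection.model
    retained = collection.retention_matrix().mean(axis=0)
    retained = np.where(model.essential_flags, 1.0, retained)
    return pd.DataFrame({
        "retention_fraction": retained,
        "essential": model.essential_flags,
    }, index=pd.Index(model.gene_ids, name="gene"))


def classify_genes(report: pd.DataFrame,
                   threshold: float = NED_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Assign each gene a class and a NED flag.

    ``is_ned`` is True for non-essential genes with retention strictly
    above ``threshold`` (the ">95%" rule).  The ``gene_class`` column
    partitions genes: essential_excluded, always_active (retention 1,
    a subset of the NED flag), NED, always_KO (retention 0), variable.
    """
    if not 0.0 < threshold < 1.0:
        raise ContractError("threshold must lie strictly in (0, 1)")
    out = report.copy()
    frac = out["retention_fraction"]
    out["is_ned"] = (frac > threshold) & ~out["essential"]
    cls = np.select(
        [
            out["essential"],
            frac == 1.0,
            out["is_ned"],
            frac == 0.0,
        ],
        ["essential_excluded", "always_active", "NED", "always_KO"],
        default="variable",
    )
    out["gene_class"] = cls
    out.attrs["ned_threshold"] = threshold
    return out


def ned_genes(report: pd.DataFrame) -> set[str]:
    """The NED gene set of a classified report."""
    if "is_ned" not in report:
        raise ContractError("report is not classified; call classify_genes")
    return set(report.index[report["is_ned"]])


def always_retained(collections: list[MMNCollection]) -> set[str]:
    """Genes with retention fraction 1 in *every* collection.

    With collections from different growth conditions this yields the
    invariably retained core (the paper's seven-for-yeast analogue).
    """
    if not collections:
        raise ContractError("need at least one collection")
    sets = []
    for col in collections:
        rep = retention_frequencies(col)
        keep = rep.index[(rep["retention_fraction"] == 1.0)
                         & ~rep["essential"]]
        sets.append(set(keep))
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def pairwise_shared_reactions(collection: MMNCollection,
                              method: str = "jaccard") -> pd.DataFrame:
    """Fraction of shared active reactions for every MMN pair.

    ``jaccard`` uses |A∩B| / |A∪B|; ``min`` uses |A∩B| / min(|A|, |B|).
    The diagonal is 1 by convention.
    """
    if method not in ("jaccard", "min"):
        raise ContractError(f"unknown method {method!r}")
    sets = [set(r.active_reactions) for r in collection.records]
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if method == "jaccard":
                denom = len(sets[i] | sets[j])
            else:
                denom = min(len(sets[i]), len(sets[j]))
            mat[i, j] = mat[j, i] = inter / denom if denom else 0.0
    labels = [f"MMN{i}" for i in range(n)]
    return pd.DataFrame(mat, index=labels, columns=labels)


def search_space_size(model: MetabolicModel | ModelSummary) -> tuple[int, float]:
    """Size of the raw deletion-state space.

    Returns (n_deletable, log10 of 2**n_deletable).  For the yeast-scale
    case of 1133 genes with 157 essential this is (976, ~293.8): the
    space of about 10**293 states that makes exhaustive search
    impossible and motivates the evolutionary approach.
    """
    s = model if isinstance(model, ModelSummary) else summarise(model)
    n = s.n_deletable
    return n, n * math.log10(2.0)


def genes_per_mmn(collection: MMNCollection) -> pd.Series:
    """Histogram of retained-gene counts across MMNs; mass = #MMNs."""
    sizes = [len(r.retained_genes) for r in collection.records]
    return pd.Series(sizes, name="n_genes_retained").value_counts().sort_index()
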