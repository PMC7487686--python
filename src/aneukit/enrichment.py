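"""Threshold selection, hypergeometric enrichment, and cross-strain intersections.

Upregulated (or downregulated) genes are selected by a log2 fold-change
cutoff among genes on nonduplicated chromosomes; term enrichment uses the
upper-tail hypergeometric test with Bonferroni correction over the terms
tested; genes upregulated in common across strains are intersected and
tallied against a curated functional-category table shipped with the
package.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import Karyotype
from .expression import _drop_mito

#: Selection cutoffs: a 1.5-fold change and the relaxed 30% change, in log2.
STRICT_FOLD_CUTOFF_LOG2 = round(np.log2(1.5), 3)   # 0.585
RELAXED_FOLD_CUTOFF_LOG2 = round(np.log2(1.3), 2)  # 0.38


def select_regulated_genes(
    log2_fc: pd.Series,
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    threshold_log2: float = STRICT_FOLD_CUTOFF_LOG2,
    direction: str = "up",
    exclude_chromosomes: Iterable[str] = (),
) -> set[str]:
    """Genes changed by at least ``threshold_log2`` on nonduplicated chromosomes.

    ``up`` keeps genes with log2FC >= threshold, ``down`` those <= -threshold
    (the boundary is inclusive: "at least" a 1.5-fold change). Genes on
    duplicated or explicitly excluded chromosomes are removed.
    """
    if threshold_log2 < 0:
        raise ValueError("threshold_log2 must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    ann = _drop_mito(annotation).set_index("gene_id")
    banned = karyotype.duplicated | set(exclude_chromosomes)
    fc = log2_fc.reindex(ann.index)
    eligible = ~ann["chromosome"].isin(banned)
    if direction == "up":
        hit = fc >= threshold_log2
    else:
        hit = fc <= -threshold_log2
    return set(ann.index[eligible & hit.fillna(False)])


def hypergeometric_enrichment(
    query: set[str],
    terms: Mapping[str, set[str] | frozenset],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the query set.

    For a term with K members in the universe of size N and a query of size
    n overlapping it in k genes, p = P(X >= k) for X hypergeometric(N, K, n).
    Bonferroni multiplies by the number of testable terms (K >= 1 in the
    universe), capped at 1. Results are sorted by p.
    """
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for term_id, members in terms.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    n_tested = len(out)
    out["p_bonferroni"] = np.minimum(out["p_value"] * n_tested, 1.0)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def load_functional_categories() -> pd.DataFrame:
    """The packaged curated table mapping upregulated genes to one of twelve
    functional categories (gene_id, category)."""
    ref = resources.files("aneukit.data") / "upregulated_gene_categories.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def categorize_genes(
    genes: Iterable[str], categories: pd.DataFrame | None = None
) -> pd.Series:
    """Count genes per curated functional category.

    Genes absent from the category table are tallied under ``Unassigned``.
    """
    cat = categories if categories is not None else load_functional_categories()
    mapping = dict(zip(cat["gene_id"], cat["category"]))
    labels = [mapping.get(g, "Unassigned") for g in genes]
    return pd.Series(labels, dtype="object").value_counts()


def common_upregulated(
    log2_fc_tables: Mapping[str, pd.Series],
    annotation: pd.DataFrame,
    karyotypes: Mapping[str, Karyotype],
    threshold_log2: float = RELAXED_FOLD_CUTOFF_LOG2,
    strains: list[str] | None = None,
    exclude_chromosomes: Iterable[str] = ("chrII",),
    categories: pd.DataFrame | None = None,
) -> tuple[list[str], pd.Series]:
    """Genes upregulated in every listed strain, with category counts.

    Per strain, genes above the (relaxed) cutoff on nonduplicated,
    non-excluded chromosomes are selected; the intersection over strains is
    returned sorted, together with its tally over the curated categories.
    """
    names = strains if strains is not None else list(log2_fc_tables)
    if not names:
        raise ValueError("no strains given")
    common: set[str] | None = None
    for name in names:
        sel = select_regulated_genes(
            log2_fc_tables[name],
            annotation,
            karyotypes[name],
            threshold_log2,
            "up",
            exclude_chromosomes,
        )
        common = sel if common is None else (common & sel)
    genes = sorted(common)
    return genes, categorize_genes(genes, categories)
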