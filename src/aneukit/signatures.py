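"""Stress-response gene-set scoring.

Named expression programs (environmental stress response induced/repressed,
heat shock response, oxidative stress response, UPR, Yap1 and H2O2 targets)
are scored per strain as the average log2 fold change of member genes that
lie on nonduplicated chromosomes — duplicated-chromosome members are
excluded so a copy-number gain cannot masquerade as pathway activation.
A shared heatmap matrix restricts further to genes nonduplicated in every
strain and measured in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .core import Karyotype
from .expression import _drop_mito


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with an optional regulation direction."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    direction: str = "none"  # induced / repressed / none

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.direction not in ("induced", "repressed", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    set_name: str
    assay: str
    mean_log2_fc: float
    n_genes_used: int


def score_gene_set(
    log2_fc: pd.Series,
    gene_set: GeneSet,
    karyotype: Karyotype,
    annotation: pd.DataFrame,
    assay: str = "mRNA",
    sample_id: str = "",
) -> SignatureScore:
    """Average log2 fold change over eligible gene-set members.

    Eligible members (a) lie on chromosomes carried at base ploidy in this
    strain and (b) have a defined fold change. Raises if no member is
    eligible rather than silently returning NaN.
    """
    ann = _drop_mito(annotation).set_index("gene_id")
    present = [g for g in gene_set.members if g in ann.index]
    nondup = [g for g in present if ann.loc[g, "chromosome"] not in karyotype.duplicated]
    vals = log2_fc.reindex(nondup).dropna()
    if vals.empty:
        raise ValueError(
            f"no eligible members of {gene_set.name!r} for {karyotype.strain_id}"
        )
    return SignatureScore(
        sample_id or karyotype.strain_id,
        gene_set.name,
        assay,
        float(vals.mean()),
        int(len(vals)),
    )


def signature_matrix(
    log2_fc_tables: Mapping[str, pd.Series],
    gene_set: GeneSet,
    karyotypes: Mapping[str, Karyotype],
    annotation: pd.DataFrame,
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Gene x sample fold-change matrix for a heatmap.

    Rows are the gene-set members that are nonduplicated in ALL strains and
    have a defined fold change in ALL samples; columns follow
    ``sample_order`` (default: the mapping's order), typically strain labels
    with replicate suffixes like ``D2_1``.
    """
    order = list(sample_order) if sample_order is not None else list(log2_fc_tables)
    missing = set(order) - set(log2_fc_tables)
    if missing:
        raise ValueError(f"no fold-change table for sample(s): {sorted(missing)}")
    ann = _drop_mito(annotation).set_index("gene_id")
    dup_any = set()
    for sample in order:
        dup_any |= karyotypes[sample].duplicated
    rows = [
        g
        for g in sorted(gene_set.members)
        if g in ann.index and ann.loc[g, "chromosome"] not in dup_any
    ]
    mat = pd.DataFrame(
        {sample: log2_fc_tables[sample].reindex(rows) for sample in order},
        index=pd.Index(rows, name="gene_id"),
    )
    return mat.dropna(axis=0, how="any")


def score_all(
    log2_fc_tables: Mapping[str, pd.Series],
    gene_sets: list[GeneSet],
    karyotypes: Mapping[str, Karyotype],
    annotation: pd.DataFrame,
    assay: str = "mRNA",
) -> pd.DataFrame:
    """Score every (sample, gene set) pair into a tidy table."""
    rows = []
    for sample, fc in log2_fc_tables.items():
        for gs in gene_sets:
            s = score_gene_set(fc, gs, karyotypes[sample], annotation, assay, sample)
            rows.append((s.sample_id, s.set_name, s.assay, s.mean_log2_fc, s.n_genes_used))
    return pd.DataFrame(
        rows, columns=["sample_id", "set_name", "assay", "mean_log2_fc", "n_genes_used"]
    )
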