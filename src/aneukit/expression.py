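"""RPKM, euploid-anchored median-ratio normalization, and dosage summaries.

Abundance of each gene is quantified as reads per kilobase of coding
sequence per million mapped reads (RPKM), separately for mRNA-seq and
ribosome-footprint (FP) libraries. To compare an aneuploid strain with its
euploid reference despite the copy-number-driven shift in library
composition, every aneuploid RPKM is divided by the median of
RPKM(aneuploid)/RPKM(euploid) over genes on nonduplicated chromosomes, so
that the typical unamplified gene has ratio exactly 1. Fold changes, the
ribosome density (FP/mRNA), and per-chromosome medians against the
copy-number expectation follow from the normalized values.

Mitochondrial genes are excluded from the analysis, including from the
mapped-read totals used as RPKM denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MITO_CHROMOSOME, Karyotype


def _drop_mito(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation[annotation["chromosome"] != MITO_CHROMOSOME]


def compute_rpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """RPKM per gene per sample: count / (CDS kb) / (sample total / 1e6).

    ``counts`` is a genes x samples matrix indexed by gene_id. Mitochondrial
    genes are dropped before computing per-sample totals and are absent from
    the result. Raises on samples with zero total reads.
    """
    ann = _drop_mito(annotation).set_index("gene_id")
    missing = ann.index.difference(counts.index)
    if len(missing):
        raise ValueError(f"counts matrix lacks annotated genes, e.g. {list(missing[:5])}")
    sub = counts.loc[ann.index]
    if (sub.to_numpy() < 0).any():
        raise ValueError("counts contain negative values")
    totals = sub.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    kb = ann["cds_length_bp"].to_numpy(dtype=float) / 1000.0
    rpkm = sub.div(kb, axis=0).div(totals / 1e6, axis=1)
    return rpkm


def normalize_to_euploid(
    aneu: pd.Series, eu: pd.Series, karyotype: Karyotype, annotation: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Median-ratio normalization of one aneuploid sample to its euploid pair.

    The scale factor is the median of aneu/eu over genes on nonduplicated
    chromosomes with euploid RPKM > 0; all aneuploid RPKM values are divided
    by it, pinning the post-normalization median ratio over those genes to 1.
    Returns (scale_factor, normalized aneuploid series).
    """
    ann = _drop_mito(annotation).set_index("gene_id")
    shared = aneu.index.intersection(eu.index).intersection(ann.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between samples and annotation")
    nondup_chroms = set(ann["chromosome"]) - karyotype.duplicated
    eligible = shared[
        ann.loc[shared, "chromosome"].isin(nondup_chroms).to_numpy()
        & (eu.loc[shared] > 0).to_numpy()
    ]
    if len(eligible) == 0:
        raise ValueError("no eligible nonduplicated genes with positive euploid RPKM")
    scale = float((aneu.loc[eligible] / eu.loc[eligible]).median())
    if scale <= 0:
        raise ValueError("non-positive normalization scale factor")
    return scale, aneu / scale


def log2_fold_changes(aneu_normalized: pd.Series, eu: pd.Series) -> pd.Series:
    """Per-gene log2(aneuploid_normalized / euploid).

    Genes where either side is 0 (or missing) get NaN rather than +/-inf:
    no pseudocount is applied, absent expression yields no fold change.
    """
    shared = aneu_normalized.index.intersection(eu.index)
    a = aneu_normalized.loc[shared].to_numpy(dtype=float)
    e = eu.loc[shared].to_numpy(dtype=float)
    ok = (a > 0) & (e > 0)
    out = np.full(len(shared), np.nan)
    out[ok] = np.log2(a[ok] / e[ok])
    return pd.Series(out, index=shared, name="log2_fc")


def ribosome_density(
    fp_normalized: pd.Series,
    mrna_normalized: pd.Series,
    fp_log2_fc: pd.Series | None = None,
    mrna_log2_fc: pd.Series | None = None,
) -> pd.DataFrame:
    """Ribosome density (RD) = FP / mRNA normalized RPKM per gene.

    Where fold changes are supplied, rd_log2_fc = FP log2FC - mRNA log2FC
    (defined only where both are defined).
    """
    shared = fp_normalized.index.intersection(mrna_normalized.index)
    m = mrna_normalized.loc[shared].to_numpy(dtype=float)
    f = fp_normalized.loc[shared].to_numpy(dtype=float)
    rd = np.where(m > 0, f / np.where(m > 0, m, 1.0), np.nan)
    out = pd.DataFrame({"rd": rd}, index=shared)
    if fp_log2_fc is not None and mrna_log2_fc is not None:
        out["rd_log2_fc"] = fp_log2_fc.reindex(shared) - mrna_log2_fc.reindex(shared)
    return out


@dataclass(frozen=True)
class DosageSummary:
    """Per-chromosome summary of fold changes against the copy-number expectation."""

    chromosome: str
    n_genes: int
    median_log2_fc: float
    expected_log2_fc: float
    deviation: float
    compensated: bool


def chromosome_dosage_summary(
    log2_fc: pd.Series,
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    tolerance: float = 0.3,
) -> list[DosageSummary]:
    """Median log2 fold change per chromosome vs log2(copy ratio).

    A duplicated chromosome is flagged ``compensated`` when its median falls
    short of the expected log2(copy ratio) by more than ``tolerance`` —
    i.e. expression has been pulled back toward euploid levels.
    """
    ann = _drop_mito(annotation).set_index("gene_id")
    fc = log2_fc.reindex(ann.index)
    out = []
    for chrom, sub in ann.groupby("chromosome", sort=True):
        vals = fc.loc[sub.index].dropna()
        expected = float(np.log2(karyotype.copies(str(chrom)) / karyotype.base_ploidy))
        median = float(vals.median()) if len(vals) else float("nan")
        deviation = median - expected
        compensated = expected > 0 and median < expected - tolerance
        out.append(DosageSummary(str(chrom), int(len(vals)), median, expected, deviation, compensated))
    return out


def dosage_summary_frame(summaries: list[DosageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chromosome, s.n_genes, s.median_log2_fc, s.expected_log2_fc, s.deviation, s.compensated)
            for s in summaries
        ],
        columns=["chromosome", "n_genes", "median_log2_fc", "expected_log2_fc", "deviation", "compensated"],
    )
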