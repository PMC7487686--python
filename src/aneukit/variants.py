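"""Variant filtering, wild-type subtraction, and coding-effect classification.

Haploid variant calls are filtered by base/mapping quality and allele
frequency: a 70% minimum frequency on single-copy chromosomes, relaxed to
40% on duplicated chromosomes where a heterozygous-like variant on one of
two copies sits near 50%. Calls shared with the isogenic euploid parent are
subtracted by exact (chromosome, position, ref, alt) match, and single-base
substitutions inside a CDS are classified by translating the affected codon.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

from .core import Karyotype

VARIANT_COLUMNS = [
    "chromosome", "position", "ref", "alt",
    "frequency", "base_quality", "mapping_quality",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _check_columns(records: pd.DataFrame, name: str = "variant table") -> None:
    missing = set(VARIANT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"{name} missing columns: {sorted(missing)}")


def filter_variants(
    records: pd.DataFrame,
    karyotype: Karyotype,
    min_basequal: float = 15.0,
    min_mapqual: float = 15.0,
    min_freq_haploid: float = 0.70,
    min_freq_duplicated: float = 0.40,
) -> pd.DataFrame:
    """Keep records meeting quality and frequency minima (all inclusive).

    The frequency cutoff is ``min_freq_duplicated`` on chromosomes the
    karyotype carries above base ploidy, ``min_freq_haploid`` elsewhere.
    """
    _check_columns(records)
    missing = set(records["chromosome"]) - set(karyotype.copy_number)
    if missing:
        raise ValueError(f"karyotype lacks chromosomes present in records: {sorted(missing)}")
    dup = records["chromosome"].isin(karyotype.duplicated)
    freq_min = dup.map({True: min_freq_duplicated, False: min_freq_haploid})
    keep = (
        (records["base_quality"] >= min_basequal)
        & (records["mapping_quality"] >= min_mapqual)
        & (records["frequency"] >= freq_min)
    )
    return records[keep].reset_index(drop=True)


def subtract_wt(strain_records: pd.DataFrame, wt_records: pd.DataFrame) -> pd.DataFrame:
    """Remove strain variants that exactly match a wild-type record.

    A match requires identical (chromosome, position, ref, alt); a shared
    position with a different alternate allele is retained.
    """
    key = ["chromosome", "position", "ref", "alt"]
    for tab, name in ((strain_records, "strain"), (wt_records, "wild-type")):
        missing = set(key) - set(tab.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    wt_keys = set(map(tuple, wt_records[key].itertuples(index=False, name=None)))
    mask = [
        tuple(row) not in wt_keys
        for row in strain_records[key].itertuples(index=False, name=None)
    ]
    return strain_records[mask].reset_index(drop=True)


def classify_coding_effect(
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    annotation: pd.DataFrame,
    cds_sequences: Mapping[str, str],
) -> str:
    """Effect of a variant: missense, synonymous, nonsense, intergenic, unclassified.

    Single-base substitutions falling inside an annotated CDS are classified
    by translating the affected codon before and after the change
    (strand-aware, standard genetic code, using the annotated CDS sequence as
    the reference). Indels are ``unclassified``; positions outside every CDS
    are ``intergenic``.
    """
    if len(ref) != 1 or len(alt) != 1:
        return "unclassified"
    hits = annotation[
        (annotation["chromosome"] == chromosome)
        & (annotation["cds_start"] <= position)
        & (annotation["cds_end"] >= position)
    ]
    if hits.empty:
        return "intergenic"
    gene = hits.iloc[0]
    seq = cds_sequences[gene["gene_id"]]
    if gene["strand"] == "+":
        offset = position - gene["cds_start"]
        new_base = alt.upper()
    else:
        offset = gene["cds_end"] - position
        new_base = alt.upper().translate(_COMPLEMENT)
    codon_start = (offset // 3) * 3
    within = offset - codon_start
    old_codon = seq[codon_start : codon_start + 3].upper()
    if len(old_codon) < 3:
        return "unclassified"
    new_codon = old_codon[:within] + new_base + old_codon[within + 1 :]
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    return "missense"


def classify_all(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    cds_sequences: Mapping[str, str],
) -> pd.DataFrame:
    """Add an ``effect`` column classifying every record."""
    effects = [
        classify_coding_effect(r.chromosome, r.position, r.ref, r.alt, annotation, cds_sequences)
        for r in records.itertuples(index=False)
    ]
    out = records.copy()
    out["effect"] = effects
    return out
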