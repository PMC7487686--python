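"""Tab-separated readers/writers for the pipeline's file formats.

All tables are TSV with a header row; chromosome names are normalized to the
``chrI``..``chrXVI`` / ``chrMito`` convention. Lines starting with ``#`` are
treated as provenance comments and skipped on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import Karyotype
from .simulate import validate_annotation
from .variants import VARIANT_COLUMNS

_COMMENT = "#"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment=_COMMENT, **kwargs)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed TSV {path}: {err}") from err


def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
               provenance: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"{_COMMENT} {line}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------- annotation

def write_annotation(annotation: pd.DataFrame, path: str | Path,
                     provenance: list[str] | None = None) -> None:
    _write_tsv(annotation, path, provenance=provenance)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = _read_tsv(path)
    validate_annotation(ann)
    return ann


def write_annotation_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Minimal GFF3 export of the CDS features (one line per gene)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.itertuples(index=False):
            fh.write(
                f"{r.chromosome}\taneukit\tCDS\t{r.cds_start}\t{r.cds_end}\t.\t"
                f"{r.strand}\t0\tID={r.gene_id}\n"
            )


# -------------------------------------------------------------------- counts

def write_counts(counts: pd.DataFrame, path: str | Path,
                 provenance: list[str] | None = None) -> None:
    _write_tsv(counts, path, index=True, provenance=provenance)


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = _read_tsv(path, index_col=0)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups[:5]}")
    for col in counts.columns:
        numeric = pd.to_numeric(counts[col], errors="coerce")
        bad = counts.index[numeric.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric count at gene {bad[0]!r}, sample {col!r}")
        neg = counts.index[numeric < 0]
        if len(neg):
            raise ValueError(f"{path}: negative count at gene {neg[0]!r}, sample {col!r}")
        counts[col] = numeric
    return counts


# ----------------------------------------------------------------- gene sets

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(set(members))]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets; duplicated members are deduplicated with a warning."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_COMMENT):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if len(members) != len(set(members)):
                warnings.warn(f"{path}:{lineno}: duplicated members in {name!r} deduplicated")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = set(members)
    return sets


# ------------------------------------------------------------------ variants

def write_variants(records: pd.DataFrame, path: str | Path,
                   provenance: list[str] | None = None) -> None:
    cols = [c for c in ["CHROM", "POS", "REF", "ALT", "FREQ", "BASEQ", "MAPQ"]]
    out = records.rename(
        columns=dict(zip(VARIANT_COLUMNS, cols))
    )
    _write_tsv(out, path, provenance=provenance)


def read_variants(path: str | Path) -> pd.DataFrame:
    tab = _read_tsv(path)
    rename = dict(zip(["CHROM", "POS", "REF", "ALT", "FREQ", "BASEQ", "MAPQ"], VARIANT_COLUMNS))
    tab = tab.rename(columns=rename)
    missing = set(VARIANT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns: {sorted(missing)}")
    bad = tab[(tab["frequency"] < 0) | (tab["frequency"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: variant frequency outside [0, 1] at row {bad.index[0]}")
    return tab


# ----------------------------------------------------------------- karyotype

def write_karyotype(karyotype: Karyotype, path: str | Path,
                    provenance: list[str] | None = None) -> None:
    df = pd.DataFrame(
        sorted(karyotype.copy_number.items()), columns=["chromosome", "copy_number"]
    )
    df.insert(0, "strain_id", karyotype.strain_id)
    df["base_ploidy"] = karyotype.base_ploidy
    _write_tsv(df, path, provenance=provenance)


def read_karyotype(path: str | Path) -> Karyotype:
    df = _read_tsv(path)
    missing = {"strain_id", "chromosome", "copy_number"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: karyotype table missing columns: {sorted(missing)}")
    strains = df["strain_id"].unique()
    if len(strains) != 1:
        raise ValueError(f"{path}: expected one strain per karyotype file, found {list(strains)}")
    base = int(df["base_ploidy"].iloc[0]) if "base_ploidy" in df.columns else 1
    return Karyotype(
        str(strains[0]),
        dict(zip(df["chromosome"], df["copy_number"].astype(int))),
        base,
    )


# ---------------------------------------------------------- qPCR and windows

def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table, path)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    tab = _read_tsv(path)
    missing = {"chromosome", "arm", "replicate", "ct"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: qPCR table missing columns: {sorted(missing)}")
    return tab


def write_windows(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table, path)


def read_windows(path: str | Path) -> pd.DataFrame:
    tab = _read_tsv(path)
    missing = {"chromosome", "window_start", "window_end", "rpkm"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: window table missing columns: {sorted(missing)}")
    return tab
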