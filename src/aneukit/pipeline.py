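"""End-to-end orchestration of the aneuploidy expression analysis.

A structured YAML config names every input (annotation, per-assay count
matrices, karyotypes — given directly or estimated from qPCR tables — gene
sets, GO-style term maps, variant tables) plus the sample-to-batch-euploid
pairing map and thresholds. ``run_pipeline`` validates the config up front,
runs normalization, dosage summaries, signature scoring, enrichment,
intersection and variant filtering, and writes TSV outputs plus a JSON
manifest carrying the seed, thresholds and input checksums so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import io as akio
from .core import Karyotype
from .enrichment import (
    RELAXED_FOLD_CUTOFF_LOG2,
    STRICT_FOLD_CUTOFF_LOG2,
    common_upregulated,
    hypergeometric_enrichment,
    select_regulated_genes,
)
from .expression import (
    chromosome_dosage_summary,
    compute_rpkm,
    dosage_summary_frame,
    log2_fold_changes,
    normalize_to_euploid,
)
from .karyotyping import estimate_copy_number_qpcr, estimates_to_karyotype
from .signatures import GeneSet, score_all
from .variants import filter_variants, subtract_wt

log = logging.getLogger("aneukit")

DEFAULT_THRESHOLDS = {
    "strict_log2": STRICT_FOLD_CUTOFF_LOG2,
    "relaxed_log2": RELAXED_FOLD_CUTOFF_LOG2,
    "min_freq_haploid": 0.70,
    "min_freq_duplicated": 0.40,
    "min_basequal": 15.0,
    "min_mapqual": 15.0,
}


@dataclass
class PipelineConfig:
    """Validated run configuration. See ``from_yaml`` for the file layout."""

    annotation: Path
    counts: dict[str, Path]                  # assay -> counts TSV
    karyotypes: dict[str, Any]               # strain -> path or {qpcr, reference}
    pairing: dict[str, str]                  # aneuploid sample -> euploid sample
    sample_strain: dict[str, str]            # sample column -> strain id
    out_dir: Path
    gene_sets: Path | None = None
    terms: Path | None = None
    variants: dict[str, Any] | None = None   # {strain:, records:, wt:}
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    exclude_chromosomes: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _p(rel: str) -> Path:
            p = Path(rel)
            return p if p.is_absolute() else base / p

        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds", {}))
        variants = raw.get("variants")
        if variants:
            variants = {
                "strain": variants["strain"],
                "records": _p(variants["records"]),
                "wt": _p(variants["wt"]) if variants.get("wt") else None,
            }
        karyotypes: dict[str, Any] = {}
        for strain, spec in raw["karyotypes"].items():
            if isinstance(spec, str):
                karyotypes[strain] = _p(spec)
            else:
                karyotypes[strain] = {k: _p(v) for k, v in spec.items()}
        cfg = cls(
            annotation=_p(raw["annotation"]),
            counts={a: _p(p) for a, p in raw["counts"].items()},
            karyotypes=karyotypes,
            pairing=dict(raw["pairing"]),
            sample_strain=dict(raw["sample_strain"]),
            out_dir=_p(raw["out_dir"]),
            gene_sets=_p(raw["gene_sets"]) if raw.get("gene_sets") else None,
            terms=_p(raw["terms"]) if raw.get("terms") else None,
            variants=variants,
            thresholds=thresholds,
            exclude_chromosomes=list(raw.get("exclude_chromosomes", [])),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Fail fast, before any computation, on missing inputs or bad values."""
        if not self.pairing:
            raise ValueError("config: pairing map is empty — every aneuploid sample "
                             "must name its batch euploid sample")
        paths: list[Path] = [self.annotation, *self.counts.values()]
        for spec in self.karyotypes.values():
            paths.extend([spec] if isinstance(spec, Path) else spec.values())
        for opt in (self.gene_sets, self.terms):
            if opt is not None:
                paths.append(opt)
        if self.variants:
            paths.append(self.variants["records"])
            if self.variants.get("wt"):
                paths.append(self.variants["wt"])
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        for sample in self.pairing:
            if sample not in self.sample_strain:
                raise ValueError(f"config: sample {sample!r} lacks a strain assignment")
        for key in ("strict_log2", "relaxed_log2"):
            if self.thresholds[key] < 0:
                raise ValueError(f"config: threshold {key} must be >= 0")
        for key in ("min_freq_haploid", "min_freq_duplicated"):
            if not 0 <= self.thresholds[key] <= 1:
                raise ValueError(f"config: threshold {key} must lie in [0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_karyotype(strain: str, spec: Any) -> Karyotype:
    if isinstance(spec, Path):
        return akio.read_karyotype(spec)
    est = estimate_copy_number_qpcr(akio.read_qpcr(spec["qpcr"]), akio.read_qpcr(spec["reference"]))
    return estimates_to_karyotype(est, strain)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns the output paths."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs: dict[str, str] = {str(config.annotation): _sha256(config.annotation)}
    for p in config.counts.values():
        inputs[str(p)] = _sha256(p)
    provenance = [
        f"aneukit {__version__} seed={config.seed}",
        "thresholds " + " ".join(f"{k}={v}" for k, v in sorted(config.thresholds.items())),
        *[f"input sha256:{h} {p}" for p, h in sorted(inputs.items())],
    ]

    log.info("stage: load inputs")
    annotation = akio.read_annotation(config.annotation)
    counts = {assay: akio.read_counts(p) for assay, p in config.counts.items()}
    karyotypes = {s: _load_karyotype(s, spec) for s, spec in config.karyotypes.items()}

    outputs: dict[str, Path] = {}

    kary_rows = []
    for strain, k in karyotypes.items():
        for chrom, cn in sorted(k.copy_number.items()):
            kary_rows.append((strain, chrom, cn, k.base_ploidy))
    kary_df = pd.DataFrame(kary_rows, columns=["strain_id", "chromosome", "copy_number", "base_ploidy"])
    outputs["karyotypes"] = out_dir / "karyotypes.tsv"
    akio._write_tsv(kary_df, outputs["karyotypes"], provenance=provenance)

    log.info("stage: normalization and fold changes")
    fc_by_assay: dict[str, dict[str, pd.Series]] = {}
    for assay, mat in counts.items():
        rpkm = compute_rpkm(mat, annotation)
        rows = []
        fc_by_assay[assay] = {}
        for sample, wt_sample in config.pairing.items():
            for col, role in ((sample, "aneuploid"), (wt_sample, "euploid")):
                if col not in rpkm.columns:
                    raise ValueError(f"{role} sample {col!r} absent from {assay} counts")
            strain = config.sample_strain[sample]
            scale, normed = normalize_to_euploid(
                rpkm[sample], rpkm[wt_sample], karyotypes[strain], annotation
            )
            fc = log2_fold_changes(normed, rpkm[wt_sample])
            fc_by_assay[assay][sample] = fc
            df = pd.DataFrame(
                {
                    "gene_id": rpkm.index,
                    "sample": sample,
                    "rpkm": rpkm[sample].to_numpy(),
                    "rpkm_normalized": normed.reindex(rpkm.index).to_numpy(),
                    "log2_fc": fc.reindex(rpkm.index).to_numpy(),
                    "scale_factor": scale,
                }
            )
            rows.append(df)
        prof = pd.concat(rows, ignore_index=True)
        outputs[f"profiles_{assay}"] = out_dir / f"profiles_{assay}.tsv"
        akio._write_tsv(prof, outputs[f"profiles_{assay}"], provenance=provenance)

    log.info("stage: chromosome dosage summaries")
    dos_rows = []
    for assay, fcs in fc_by_assay.items():
        for sample, fc in fcs.items():
            strain = config.sample_strain[sample]
            summ = dosage_summary_frame(
                chromosome_dosage_summary(fc, annotation, karyotypes[strain])
            )
            summ.insert(0, "sample", sample)
            summ.insert(0, "assay", assay)
            dos_rows.append(summ)
    outputs["dosage_summary"] = out_dir / "dosage_summary.tsv"
    akio._write_tsv(pd.concat(dos_rows, ignore_index=True), outputs["dosage_summary"],
                    provenance=provenance)

    if config.gene_sets:
        log.info("stage: signature scoring")
        sets = [GeneSet(name, frozenset(members)) for name, members in
                akio.read_gmt(config.gene_sets).items()]
        score_rows = []
        for assay, fcs in fc_by_assay.items():
            strain_karyos = {s: karyotypes[config.sample_strain[s]] for s in fcs}
            score_rows.append(score_all(fcs, sets, strain_karyos, annotation, assay))
        outputs["signature_scores"] = out_dir / "signature_scores.tsv"
        akio._write_tsv(pd.concat(score_rows, ignore_index=True), outputs["signature_scores"],
                        provenance=provenance)

    enrich_assay = "FP" if "FP" in fc_by_assay else next(iter(fc_by_assay))
    if config.terms:
        log.info("stage: enrichment")
        terms = akio.read_gmt(config.terms)
        enr_rows = []
        for sample, fc in fc_by_assay[enrich_assay].items():
            strain = config.sample_strain[sample]
            universe = set(fc.dropna().index)
            query = select_regulated_genes(
                fc, annotation, karyotypes[strain],
                config.thresholds["strict_log2"], "up",
            ) & universe
            res = hypergeometric_enrichment(query, terms, universe)
            res.insert(0, "sample", sample)
            enr_rows.append(res)
        outputs["enrichment"] = out_dir / "enrichment.tsv"
        akio._write_tsv(pd.concat(enr_rows, ignore_index=True), outputs["enrichment"],
                        provenance=provenance)

    log.info("stage: cross-strain intersection")
    strain_karyos = {s: karyotypes[config.sample_strain[s]] for s in fc_by_assay[enrich_assay]}
    genes, cat_counts = common_upregulated(
        fc_by_assay[enrich_assay],
        annotation,
        strain_karyos,
        config.thresholds["relaxed_log2"],
        exclude_chromosomes=config.exclude_chromosomes,
    )
    outputs["common_upregulated"] = out_dir / "common_upregulated.tsv"
    akio._write_tsv(pd.DataFrame({"gene_id": genes}), outputs["common_upregulated"],
                    provenance=provenance)
    outputs["category_counts"] = out_dir / "category_counts.tsv"
    akio._write_tsv(
        cat_counts.rename_axis("category").reset_index(name="n_genes"),
        outputs["category_counts"], provenance=provenance,
    )

    if config.variants:
        log.info("stage: variant filtering")
        recs = akio.read_variants(config.variants["records"])
        kary = karyotypes[config.variants["strain"]]
        filtered = filter_variants(
            recs, kary,
            config.thresholds["min_basequal"], config.thresholds["min_mapqual"],
            config.thresholds["min_freq_haploid"], config.thresholds["min_freq_duplicated"],
        )
        if config.variants.get("wt"):
            filtered = subtract_wt(filtered, akio.read_variants(config.variants["wt"]))
        outputs["variants_filtered"] = out_dir / "variants_filtered.tsv"
        akio.write_variants(filtered, outputs["variants_filtered"], provenance=provenance)

    manifest = {
        "aneukit_version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "pairing": config.pairing,
        "inputs_sha256": inputs,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest_path
    return outputs
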