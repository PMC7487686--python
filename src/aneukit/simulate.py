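"""Synthetic-data generators with known ground truth.

Every input the analysis consumes can be simulated here: a gene annotation,
copy-number-proportional mRNA / ribosome-footprint count matrices with
negative-binomial noise and an optional dosage-compensation dial, qPCR Ct
tables under a perfect-efficiency-2 amplification model, 1-kb windowed
sequencing depth, variant tables with frequency strata, and exponential
pulse-chase decay series. All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MITO_CHROMOSOME, Karyotype, chromosome_name

_ASSAYS = ("mRNA", "FP")
_BASES = np.array(list("ACGT"))

#: Ct of a single-copy locus in the simulated qPCR model (cycles).
REFERENCE_CT = 20.0


def _strain_key(strain_id: str) -> int:
    """Stable small integer derived from a strain label (for RNG streams)."""
    return sum(b * (i + 1) for i, b in enumerate(strain_id.encode())) % (2**31 - 1)


@dataclass
class ActivatedSet:
    """A gene program switched on in a simulated strain.

    ``members`` may be any iterable of gene ids (a plain set or a
    :class:`~aneukit.signatures.GeneSet`'s members). ``log2_effect`` is the
    log2 expression shift applied on top of copy-number scaling, restricted
    to the listed ``assays`` so translation-only effects can be simulated.
    """

    members: frozenset
    log2_effect: float
    assays: tuple[str, ...] = _ASSAYS

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        bad = set(self.assays) - set(_ASSAYS)
        if bad:
            raise ValueError(f"unknown assay(s) in ActivatedSet: {sorted(bad)}")


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    compensation_fraction interpolates between expression fully proportional
    to chromosome copy number (0, the behaviour observed in tolerant
    aneuploid strains) and complete dosage compensation (1): the expected
    expression of a gene scales as ``copy_number ** (1 - compensation_fraction)``.
    """

    library_size: int = 5_000_000
    nb_dispersion: float = 0.01
    compensation_fraction: float = 0.0
    activated_sets: list[ActivatedSet] = field(default_factory=list)
    n_replicates: int = 1
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.compensation_fraction <= 1.0:
            raise ValueError("compensation_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_genome(
    n_chromosomes: int = 16,
    genes_per_chromosome: int = 10,
    length_range: tuple[int, int] = (300, 3000),
    seed: int = 0,
    include_mito: bool = False,
    mito_genes: int = 8,
) -> pd.DataFrame:
    """Simulate a gene annotation table.

    Genes are non-overlapping within each chromosome, CDS lengths are
    codon-aligned (multiples of 3) and drawn uniformly from ``length_range``.
    Returns columns gene_id, chromosome, cds_start, cds_end, strand,
    cds_length_bp with 1-based inclusive coordinates.
    """
    min_bp, max_bp = length_range
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if min_bp < 3 or max_bp < min_bp:
        raise ValueError(f"invalid CDS length range: {length_range}")
    rng = np.random.default_rng(seed)
    chroms = [chromosome_name(i) for i in range(1, n_chromosomes + 1)]
    plan = [(c, genes_per_chromosome) for c in chroms]
    if include_mito:
        plan.append((MITO_CHROMOSOME, mito_genes))

    rows = []
    for chrom, n_genes in plan:
        pos = 1
        for i in range(n_genes):
            gap = int(rng.integers(100, 501))
            length = int(rng.integers(min_bp, max_bp + 1))
            length -= length % 3
            length = max(length, 3)
            start = pos + gap
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"{chrom}_g{i + 1:03d}", chrom, start, end, strand, length))
            pos = end + 1
    ann = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "cds_start", "cds_end", "strand", "cds_length_bp"]
    )
    validate_annotation(ann)
    return ann


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Raise ValueError on malformed annotation tables."""
    required = {"gene_id", "chromosome", "cds_start", "cds_end", "strand", "cds_length_bp"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["gene_id"].duplicated().any():
        dups = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if (annotation["cds_start"] > annotation["cds_end"]).any():
        raise ValueError("cds_start > cds_end for some genes")
    derived = annotation["cds_end"] - annotation["cds_start"] + 1
    if not (annotation["cds_length_bp"] == derived).all():
        raise ValueError("cds_length_bp inconsistent with coordinates")
    if (annotation["cds_length_bp"] <= 0).any():
        raise ValueError("non-positive CDS length")


def _expected_weights(
    annotation: pd.DataFrame, karyotype: Karyotype, config: SimulationConfig, assay: str
) -> np.ndarray:
    # mitochondrial copy number is not a karyotype concept; treat as base ploidy
    missing = set(annotation["chromosome"]) - set(karyotype.copy_number) - {MITO_CHROMOSOME}
    if missing:
        raise ValueError(
            f"karyotype {karyotype.strain_id!r} lacks chromosomes: {sorted(missing)}"
        )
    base_rng = np.random.default_rng([config.seed, 101])
    baseline = np.exp(base_rng.normal(0.0, config.baseline_log_sd, size=len(annotation)))
    cn = (
        annotation["chromosome"]
        .map(karyotype.copy_number)
        .fillna(karyotype.base_ploidy)
        .to_numpy(float)
    )
    cn /= karyotype.base_ploidy
    w = baseline * cn ** (1.0 - config.compensation_fraction)
    effect = np.zeros(len(annotation))
    gene_ids = annotation["gene_id"].to_numpy()
    for act in config.activated_sets:
        if assay in act.assays:
            effect += np.isin(gene_ids, list(act.members)) * act.log2_effect
    return w * 2.0**effect


def simulate_counts(
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    config: SimulationConfig,
    assay: str = "mRNA",
) -> pd.DataFrame:
    """Simulate a raw count matrix (genes x replicate samples) for one assay.

    Expected counts are proportional to a per-gene lognormal baseline (shared
    between assays and strains for a given config seed, so fold changes are
    meaningful) times the copy-number/compensation/activation terms, scaled to
    ``library_size``. Counts are negative binomial with the configured
    dispersion; dispersion 0 gives the Poisson limit.
    """
    if assay not in _ASSAYS:
        raise ValueError(f"assay must be one of {_ASSAYS}, got {assay!r}")
    w = _expected_weights(annotation, karyotype, config, assay)
    mu = config.library_size * w / w.sum()
    acode = _ASSAYS.index(assay)
    cols = {}
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(
            [config.seed, 7, acode, rep, _strain_key(karyotype.strain_id)]
        )
        if config.nb_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            n = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(n, n / (n + mu))
        cols[f"{karyotype.strain_id}_{rep + 1}"] = counts
    return pd.DataFrame(cols, index=pd.Index(annotation["gene_id"], name="gene_id"))


def simulate_qpcr(
    karyotype: Karyotype,
    ct_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 3,
    reference_ct: float = REFERENCE_CT,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table (chromosome, arm, replicate, ct).

    Under perfect amplification efficiency 2, each doubling of template
    advances detection by one cycle, so
    ``Ct = reference_ct - log2(copy / base_ploidy) + Normal(0, ct_sd)``.
    Both chromosome arms carry a probe, each with technical replicates.
    """
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    rng = np.random.default_rng([seed, 11, _strain_key(karyotype.strain_id)])
    rows = []
    for chrom in sorted(karyotype.copy_number):
        if chrom == MITO_CHROMOSOME:
            continue
        delta = math.log2(karyotype.copies(chrom) / karyotype.base_ploidy)
        for arm in ("L", "R"):
            for rep in range(1, n_replicates + 1):
                ct = reference_ct - delta + (rng.normal(0.0, ct_sd) if ct_sd else 0.0)
                rows.append((chrom, arm, rep, ct))
    return pd.DataFrame(rows, columns=["chromosome", "arm", "replicate", "ct"])


def simulate_wgs_depth(
    karyotype: Karyotype,
    windows_per_chromosome: int = 50,
    depth_noise_cv: float = 0.2,
    seed: int = 0,
    base_rpkm: float = 10.0,
) -> pd.DataFrame:
    """Simulate 1-kb windowed sequencing depth (RPKM per window).

    Window means are proportional to chromosome copy number with mean-one
    multiplicative lognormal noise of the given coefficient of variation.
    Exported coordinates are 1-based inclusive ([1, 1000], [1001, 2000], ...).
    """
    if depth_noise_cv < 0:
        raise ValueError("depth_noise_cv must be >= 0")
    if windows_per_chromosome < 1:
        raise ValueError("windows_per_chromosome must be >= 1")
    rng = np.random.default_rng([seed, 13, _strain_key(karyotype.strain_id)])
    sigma = math.sqrt(math.log1p(depth_noise_cv**2))
    rows = []
    for chrom in sorted(karyotype.copy_number):
        if chrom == MITO_CHROMOSOME:
            continue
        mean = base_rpkm * karyotype.copies(chrom) / karyotype.base_ploidy
        noise = (
            np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size=windows_per_chromosome))
            if sigma
            else np.ones(windows_per_chromosome)
        )
        for i in range(windows_per_chromosome):
            start = i * 1000 + 1
            rows.append((chrom, start, start + 999, mean * noise[i]))
    return pd.DataFrame(rows, columns=["chromosome", "window_start", "window_end", "rpkm"])


def simulate_variants(
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    n_true: int = 20,
    n_noise: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a variant table with ground-truth labels.

    True variants sit inside CDS regions with haploid-like frequencies
    (>= 0.9 on single-copy chromosomes, ~0.5 heterozygous-like on duplicated
    ones) and good qualities. Noise variants fail either the frequency or a
    quality threshold by construction. Columns: chromosome, position, ref,
    alt, frequency, base_quality, mapping_quality, is_true.
    """
    rng = np.random.default_rng([seed, 17])
    genes = annotation[annotation["chromosome"] != MITO_CHROMOSOME].reset_index(drop=True)
    if genes.empty:
        raise ValueError("annotation has no nuclear genes")
    taken: set[tuple[str, int]] = set()
    rows = []

    def _snv() -> tuple[str, str]:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return str(ref), str(alt)

    for _ in range(n_true):
        for _attempt in range(1000):
            g = genes.iloc[int(rng.integers(len(genes)))]
            pos = int(rng.integers(g["cds_start"], g["cds_end"] + 1))
            if (g["chromosome"], pos) not in taken:
                break
        taken.add((g["chromosome"], pos))
        duplicated = g["chromosome"] in karyotype.duplicated
        freq = rng.uniform(0.45, 0.55) if duplicated else rng.uniform(0.90, 1.0)
        ref, alt = _snv()
        rows.append(
            (g["chromosome"], pos, ref, alt, freq, rng.uniform(25, 40), rng.uniform(25, 40), True)
        )

    span = genes.groupby("chromosome")["cds_end"].max()
    chroms = list(span.index)
    for _ in range(n_noise):
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, span[chrom] + 1))
            if (chrom, pos) not in taken:
                break
        taken.add((chrom, pos))
        ref, alt = _snv()
        if rng.random() < 0.5:  # frequency failure
            freq, bq, mq = rng.uniform(0.02, 0.29), rng.uniform(25, 40), rng.uniform(25, 40)
        else:  # quality failure
            freq = rng.uniform(0.90, 1.0)
            if rng.random() < 0.5:
                bq, mq = rng.uniform(2, 14), rng.uniform(25, 40)
            else:
                bq, mq = rng.uniform(25, 40), rng.uniform(2, 14)
        rows.append((chrom, pos, ref, alt, freq, bq, mq, False))

    out = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "position", "ref", "alt",
            "frequency", "base_quality", "mapping_quality", "is_true",
        ],
    )
    return out.sort_values(["chromosome", "position"]).reset_index(drop=True)


def simulate_cds_sequences(annotation: pd.DataFrame, seed: int = 0) -> dict[str, str]:
    """Random coding sequences per gene: ATG, non-stop codons, terminal stop.

    Lengths follow ``cds_length_bp`` and must be codon-aligned.
    """
    rng = np.random.default_rng([seed, 19])
    stops = {"TAA", "TAG", "TGA"}
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    sense = [c for c in sense if c not in stops]
    seqs: dict[str, str] = {}
    for gene, length in zip(annotation["gene_id"], annotation["cds_length_bp"]):
        if length % 3:
            raise ValueError(f"CDS length of {gene} is not a multiple of 3")
        n_codons = length // 3
        body = [sense[i] for i in rng.integers(0, len(sense), size=max(n_codons - 2, 0))]
        parts = ["ATG"] + body + (["TAA"] if n_codons >= 2 else [])
        seqs[gene] = "".join(parts[:n_codons])
    return seqs


def simulate_decay(
    half_life_min: float,
    timepoints: Sequence[float],
    noise_sd: float = 5.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate pulse-chase band intensities under exponential decay.

    intensity(t) = 100 * 2**(-t / half_life) + Normal(0, noise_sd), floored
    at 0. Rows are timepoints (minutes), columns are replicates.
    """
    if half_life_min <= 0:
        raise ValueError("half_life_min must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed, 23])
    t = np.asarray(timepoints, dtype=float)
    ideal = 100.0 * 2.0 ** (-t / half_life_min)
    data = {}
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd else np.zeros(t.size)
        data[f"rep_{rep}"] = np.maximum(ideal + noise, 0.0)
    return pd.DataFrame(data, index=pd.Index(t, name="time_min"))
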