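"""Chromosome copy-number estimation from qPCR probes and windowed depth.

Two independent estimators: a delta-Ct method aggregating left- and
right-arm qPCR probes against a euploid reference, and a read-depth method
taking the per-chromosome median of 1-kb window log2 ratios. Both call
integer copy numbers by rounding and should agree on clean data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Karyotype


@dataclass(frozen=True)
class CopyEstimate:
    """Copy-number estimate for one chromosome.

    copy_mean averages the two arm estimates; copy_sd is the SD between the
    left-arm and right-arm means (the error bar convention for arm probes);
    call is the rounded integer copy number, never below 1.
    """

    chromosome: str
    copy_mean: float
    copy_sd: float
    call: int


def _round_call(copy_mean: float) -> int:
    return max(1, int(round(copy_mean)))


def estimate_copy_number_qpcr(
    ct_table: pd.DataFrame,
    reference_ct_table: pd.DataFrame,
    base_ploidy: int = 1,
) -> list[CopyEstimate]:
    """Estimate per-chromosome copies from strain and euploid-reference Ct tables.

    Per arm probe, the mean Ct over technical replicates is compared with the
    euploid reference under efficiency-2 amplification:
    ``copy = base_ploidy * 2 ** (reference_mean_ct - strain_mean_ct)``.
    The chromosome estimate averages the two arm copies; copy_sd is their SD.
    Tables need columns chromosome, arm, replicate, ct.
    """
    for name, tab in (("strain", ct_table), ("reference", reference_ct_table)):
        missing = {"chromosome", "arm", "ct"} - set(tab.columns)
        if missing:
            raise ValueError(f"{name} qPCR table missing columns: {sorted(missing)}")
        if (tab["ct"] <= 0).any():
            raise ValueError(f"{name} qPCR table contains non-positive Ct values")

    strain_means = ct_table.groupby(["chromosome", "arm"])["ct"].mean()
    ref_means = reference_ct_table.groupby(["chromosome", "arm"])["ct"].mean()

    estimates = []
    for chrom in sorted(strain_means.index.get_level_values("chromosome").unique()):
        arm_copies = []
        for arm in ("L", "R"):
            if (chrom, arm) not in strain_means.index:
                raise ValueError(f"missing arm {arm!r} for chromosome {chrom} in strain table")
            if (chrom, arm) not in ref_means.index:
                raise ValueError(f"missing arm {arm!r} for chromosome {chrom} in reference table")
            delta = ref_means[(chrom, arm)] - strain_means[(chrom, arm)]
            arm_copies.append(base_ploidy * 2.0**delta)
        mean = float(np.mean(arm_copies))
        sd = float(np.std(arm_copies, ddof=1))
        estimates.append(CopyEstimate(chrom, mean, sd, _round_call(mean)))
    return estimates


def wgs_window_copy_profile(
    strain_windows: pd.DataFrame,
    euploid_windows: pd.DataFrame,
    base_ploidy: int = 1,
    segment_min_windows: int = 50,
    segment_log2_threshold: float = 0.58,
) -> tuple[pd.DataFrame, list[CopyEstimate], dict[str, bool]]:
    """Copy profile from 1-kb windowed depth against a euploid reference.

    Returns (per-window profile with log2 ratios, per-chromosome estimates
    with ``copy = base_ploidy * 2 ** median(log2 ratio)``, and segmental
    flags). A segmental abnormality is flagged when a contiguous run of at
    least ``segment_min_windows`` windows deviates from the chromosome call
    by at least ``segment_log2_threshold`` in log2 — the screen for partial
    chromosome gains or losses. Windows with zero reference depth are
    excluded; their count is reported in the profile's attrs.
    """
    key = ["chromosome", "window_start", "window_end"]
    for name, tab in (("strain", strain_windows), ("euploid", euploid_windows)):
        missing = set(key + ["rpkm"]) - set(tab.columns)
        if missing:
            raise ValueError(f"{name} window table missing columns: {sorted(missing)}")
    a = strain_windows.sort_values(key).reset_index(drop=True)
    b = euploid_windows.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not a[key].equals(b[key]):
        raise ValueError("strain and euploid window grids do not match")

    prof = a[key].copy()
    prof["rpkm"] = a["rpkm"].to_numpy()
    eu = b["rpkm"].to_numpy(dtype=float)
    usable = eu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(usable, prof["rpkm"].to_numpy(dtype=float) / np.where(usable, eu, 1.0), np.nan)
        prof["log2_ratio"] = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)
    prof.attrs["n_excluded_zero_reference"] = int((~usable).sum())

    estimates = []
    flags: dict[str, bool] = {}
    for chrom, sub in prof.groupby("chromosome", sort=True):
        med = float(np.nanmedian(sub["log2_ratio"]))
        copy_mean = base_ploidy * 2.0**med
        call = _round_call(copy_mean)
        call_log2 = math.log2(call / base_ploidy)
        dev = np.abs(sub["log2_ratio"].to_numpy() - call_log2) >= segment_log2_threshold
        flags[chrom] = _has_run(dev, segment_min_windows)
        estimates.append(CopyEstimate(str(chrom), copy_mean, float("nan"), call))
    return prof, estimates, flags


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    """True if ``mask`` contains a run of True values of length >= min_len."""
    run = 0
    for v in mask:
        run = run + 1 if (v and not np.isnan(v)) else 0
        if run >= min_len:
            return True
    return False


def estimates_to_karyotype(
    estimates: list[CopyEstimate], strain_id: str, base_ploidy: int = 1
) -> Karyotype:
    """Assemble the integer calls into a Karyotype."""
    return Karyotype(strain_id, {e.chromosome: e.call for e in estimates}, base_ploidy)


def estimates_to_frame(estimates: list[CopyEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.chromosome, e.copy_mean, e.copy_sd, e.call) for e in estimates],
        columns=["chromosome", "copy_mean", "copy_sd", "call"],
    )
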