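import pandas as pd
import pytest

from aneukit.core import Karyotype, aneuploid_panel
from aneukit.expression import compute_rpkm, log2_fold_changes, normalize_to_euploid
from aneukit.simulate import SimulationConfig, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def annotation() -> pd.DataFrame:
    """16 chromosomes x 20 genes plus a mitochondrial chromosome."""
    return simulate_genome(16, 20, seed=11, include_mito=True)


@pytest.fixture(scope="session")
def d2() -> Karyotype:
    return aneuploid_panel()["D2"]


@pytest.fixture(scope="session")
def wt() -> Karyotype:
    return Karyotype.euploid("WT")


@pytest.fixture(scope="session")
def d2_fold_changes(annotation, d2, wt):
    """Simulated no-compensation disome-II fold changes vs the euploid pair."""
    cfg = SimulationConfig(seed=5)
    rpkm_a = compute_rpkm(simulate_counts(annotation, d2, cfg, "mRNA"), annotation)
    rpkm_w = compute_rpkm(simulate_counts(annotation, wt, cfg, "mRNA"), annotation)
    scale, normed = normalize_to_euploid(rpkm_a["D2_1"], rpkm_w["WT_1"], d2, annotation)
    fc = log2_fold_changes(normed, rpkm_w["WT_1"])
    return {"rpkm_a": rpkm_a["D2_1"], "rpkm_w": rpkm_w["WT_1"], "scale": scale,
            "normalized": normed, "fc": fc}
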