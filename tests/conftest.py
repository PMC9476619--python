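from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ncats_eval.genome import GenomicInterval, Guide, TargetRegion
from ncats_eval.sim import LlrModel, ReadLengthModel, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sim_config(
    seed: int = 0,
    n_reads: int = 500,
    on_target_fraction: float = 1.0,
    truth: float | dict[int, float] = 0.5,
    coupling: dict | None = None,
    llr_model: LlrModel | None = None,
    n_cpgs: int = 20,
    cpg_spacing: int = 100,
    samples: tuple[str, ...] = ("s1", "s2"),
    dmp_effects: dict | None = None,
    array_noise_sd: float = 0.0,
    array_edge_compression: float = 0.0,
) -> SimConfig:
    """One 100 kb chromosome with a single 20 kb target region."""
    chrom_size = 100_000
    region = GenomicInterval("chrT", 40_000, 60_000, "target")
    guides = (Guide(40_010, "+"), Guide(59_990, "-"))
    cpgs = np.arange(41_000, 41_000 + n_cpgs * cpg_spacing, cpg_spacing, dtype=np.int64)
    if isinstance(truth, dict):
        props = np.array([truth.get(int(p), 0.5) for p in cpgs])
    else:
        props = np.full(cpgs.size, float(truth))
    return SimConfig(
        seed=seed,
        chromosomes=[("chrT", chrom_size)],
        target_regions=[TargetRegion(region, guides)],
        n_reads=n_reads,
        on_target_fraction=on_target_fraction,
        read_length_model=ReadLengthModel(np.log(8000.0), 0.3, 500, 30_000),
        cpg_positions={"chrT": cpgs},
        true_methylation={s: {"chrT": props.copy()} for s in samples},
        dmp_effects=dmp_effects or {},
        llr_model=llr_model or LlrModel(),
        coupling=coupling or {},
        array_noise_sd=array_noise_sd,
        array_edge_compression=array_edge_compression,
    )


@pytest.fixture
def tiny_config() -> SimConfig:
    return make_sim_config()
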