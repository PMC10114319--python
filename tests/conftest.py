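import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pericfdna.models import SampleRecord, VariantCall
from pericfdna.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_variant(**overrides) -> VariantCall:
    """A valid SNV with any field overridden."""
    defaults = dict(
        sample_id="P001", origin="FLD", gene="KRAS", chrom="chr12",
        pos=25_398_284, ref="G", alt="T", variant_class="SNV",
        allele_fraction=0.10, depth=35_000, supporting_reads=3_500,
        population_frequency=0.0, is_driver=True)
    defaults.update(overrides)
    return VariantCall(**defaults)


def make_record(**overrides) -> SampleRecord:
    defaults = dict(
        sample_id="P001", arm="nonPM", cohort="training", pci_score=0,
        chemo_pretreated=False, surgery_date=datetime.date(2021, 1, 4),
        recurrence=False, recurrence_date=None,
        last_followup_date=datetime.date(2022, 3, 1), cfdna_positive=None)
    defaults.update(overrides)
    return SampleRecord(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Default training-cohort simulation (17 PM / 23 non-PM), seed 1."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_variants(rng, n: int, sample_id: str = "P001",
                    origin: str = "FLD") -> list[VariantCall]:
    """A heterogeneous variant fixture spanning classes, depths, supports
    and population frequencies around every filter boundary."""
    classes = ["SNV", "SNV", "SNV", "Indel", "Indel", "Fusion", "CNV", "LGR"]
    variants = []
    for i in range(n):
        vclass = classes[int(rng.integers(len(classes)))]
        depth = int(rng.integers(50, 2_000))
        support = int(rng.integers(0, depth + 1))
        variants.append(VariantCall(
            sample_id=sample_id, origin=origin,
            gene=f"GENE{int(rng.integers(1, 30)):03d}",
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(1, 10_000_000)),
            ref="A", alt="T" if vclass == "SNV" else "TGC",
            variant_class=vclass,
            allele_fraction=support / depth,
            depth=depth, supporting_reads=support,
            population_frequency=float(rng.choice(
                [0.0, 0.0005, 0.001, 0.002, 0.05]))))
    return variants
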