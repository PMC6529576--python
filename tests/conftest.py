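import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from exomeburden.dnds import count_opportunities, enumerate_coding_changes
from exomeburden.filtering import (
    classify_somatic,
    filter_flagged,
    merge_genotype_refilter,
    parse_calls,
)
from exomeburden.genome import GenomeModel, Gene, build_toy_exome
from exomeburden.signatures import synthetic_catalog


@pytest.fixture(scope="session")
def exome100():
    """The default-scale toy exome used by the heavier statistical tests."""
    return build_toy_exome(100, 900, seed=11)


@pytest.fixture(scope="session")
def changes100(exome100):
    return enumerate_coding_changes(exome100)


@pytest.fixture(scope="session")
def opportunities100(exome100, changes100):
    return count_opportunities(exome100, changes=changes100)


@pytest.fixture(scope="session")
def catalog30():
    return synthetic_catalog(30, seed=2019)


@pytest.fixture(scope="session")
def small_exome():
    return build_toy_exome(20, 300, seed=3)


def make_gene_genome(cds: str, strand: str = "+", pad: str = None):
    """A single-gene genome with explicit CDS, padded so flanks exist."""
    rng = np.random.default_rng(99)
    if pad is None:
        pad = "".join(rng.choice(list("ACGT"), size=30))
    seq = pad + cds + pad
    if strand == "-":
        from exomeburden.contexts import revcomp

        seq = pad + revcomp(cds) + pad
    gene = Gene("GX", "chr1", len(pad), len(pad) + len(cds), strand)
    return GenomeModel(chromosome_sequences={"chr1": seq}, genes=[gene])


def refine_to_somatic(vcf_paths):
    """Full filter chain: parse -> flag filter -> merge -> classify."""
    cohort = parse_calls(sorted(str(p) for p in vcf_paths))
    flagged = {k: filter_flagged(v)[0] for k, v in cohort.items()}
    merged = merge_genotype_refilter(flagged, original=cohort)
    return classify_somatic(merged)
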