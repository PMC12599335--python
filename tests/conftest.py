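import random

import pytest

from pellicle.genome_io import Contig, GeneFeature, Genome
from pellicle.similarity import AlignParams
from pellicle.synthetic_data import StrainSpec, build_refdb, generate_strain

AAS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def refdb():
    return build_refdb()


@pytest.fixture(scope="session")
def align_params():
    return AlignParams(prescreen_min_shared=0.05)


@pytest.fixture(scope="session")
def f_strain():
    """One F-like strain with an eps locus, default divergence."""
    spec = StrainSpec(strain_id="FIX1", cwps_template="F", eps_template="VI", seed=11)
    return generate_strain(spec)


@pytest.fixture(scope="session")
def f_strain_exact():
    """F-like strain implanted at 100% identity to the templates."""
    spec = StrainSpec(strain_id="FIX2", cwps_template="F", eps_template=None,
                      divergence_identity=100.0, seed=13)
    return generate_strain(spec)


def random_protein(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(AAS) for _ in range(length - 1))


@pytest.fixture()
def housekeeping_genome():
    """A genome of 50 housekeeping genes with no polysaccharide vocabulary."""
    rng = random.Random(5)
    products = ["30S ribosomal protein S4", "chaperonin GroEL",
                "translation elongation factor Tu", "DNA gyrase subunit A"]
    features = []
    pos = 200
    for i in range(50):
        prot = random_protein(rng, 200)
        start, end = pos, pos + 3 * (len(prot) + 1) - 1
        features.append(GeneFeature(
            contig_id="c1", start=start, end=end, strand="+",
            locus_tag=f"HK_{i:03d}", product=products[i % len(products)],
            protein=prot,
        ))
        pos = end + 150
    return Genome(id="HK", species="Test sp.",
                  contigs=[Contig(id="c1", length=pos + 500)], features=features)
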