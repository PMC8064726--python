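import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promomine.io_formats import GeneFeature, GenomeSequence
from promomine.synthetic_data import SyntheticGenomeSpec, generate_expression, generate_genome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_genome(sequence: str, contig_id: str = "c1") -> GenomeSequence:
    return GenomeSequence(contig_id=contig_id, sequence=sequence)


def make_gene(gene_id, start, end, strand="+", contig_id="c1",
              feature_class="CDS", product=""):
    return GeneFeature(
        gene_id=gene_id, contig_id=contig_id, start=start, end=end,
        strand=strand, feature_class=feature_class, product=product,
    )


def random_sorted_annotation(rng: np.random.Generator, n_genes: int,
                             products=("alcohol dehydrogenase subunit",
                                       "sugar transporter permease",
                                       "ribosomal protein")):
    """Non-overlapping random genes on one contig, sorted by start."""
    genes = []
    pos = int(rng.integers(0, 50))
    for i in range(n_genes):
        length = int(rng.integers(50, 400))
        genes.append(
            make_gene(
                f"g{i:03d}", pos, pos + length,
                strand="+" if rng.random() < 0.5 else "-",
                product=str(rng.choice(products)),
            )
        )
        pos += length + int(rng.integers(0, 120))
    return genes


@pytest.fixture(scope="session")
def default_synthetic():
    """The default 200-gene synthetic genome with noiseless expression."""
    from promomine.expression import compute_tpm

    sg = generate_genome(SyntheticGenomeSpec(seed=0))
    counts = generate_expression(sg.truth, seed=0, noiseless=True)
    records = compute_tpm(counts)
    return sg, records
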