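import numpy as np
import pytest

from sgmsig import annotate, signatures, simdata


@pytest.fixture(scope="session")
def catalog():
    return simdata.default_catalog()


@pytest.fixture(scope="session")
def tiny_study():
    """Small simulated study shared across tests (seeded, deterministic)."""
    config = simdata.SimConfig(
        seed=11, n_genes=25, n_samples=12, burden_mu=float(np.log(150))
    )
    return simdata.simulate_study(config)


@pytest.fixture(scope="session")
def tiny_annotated(tiny_study):
    return annotate.annotate_table(
        tiny_study.mutations, tiny_study.model, tiny_study.genome
    )


@pytest.fixture(scope="session")
def tiny_labeled(tiny_study, tiny_annotated, catalog):
    exposures = signatures.fit_cohort_exposures(tiny_annotated, catalog)
    labeled = signatures.assign_top_table(tiny_annotated, exposures, catalog)
    return labeled, exposures


def make_gene(cds, gene_id="G1", strand="+", pad="AATT"):
    """Build a single-exon gene with the given CDS embedded in padding."""
    from sgmsig import genetic_code as gc

    genomic = cds if strand == "+" else gc.reverse_complement(cds)
    genome = {"chr1": pad + genomic + pad}
    start = len(pad) + 1
    end = len(pad) + len(genomic)
    gene = annotate.build_gene(gene_id, "chr1", strand, [(start, end)], genome)
    return gene, genome
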