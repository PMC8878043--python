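import numpy as np
import pytest

from phagetax import nt_similarity as nts
from phagetax import protein_clustering as pc
from phagetax import synthetic_data as sd
from phagetax import taxonomy as tax
from phagetax.genome_io import all_proteins


@pytest.fixture(scope="session")
def demo_population():
    """The seed-42 demo population: 3 clusters x 2 genera x 3 genomes + 2
    singletons."""
    return sd.simulate_population(sd.PopulationConfig())


@pytest.fixture(scope="session")
def demo_results(demo_population):
    """Full pipeline products for the demo population, computed once."""
    genomes, truth = demo_population
    proteins = all_proteins(genomes)
    sim = nts.similarity_matrix(genomes)
    groups = pc.build_groups(proteins)
    shared = pc.shared_content(genomes, groups)
    assignments, clusters, lnk = tax.classify(sim, shared)
    protein_genomes = {p.protein_id: p.genome_id for p in proteins}
    summaries = tax.summarise_pangenome(assignments, groups, protein_genomes)
    return {
        "genomes": genomes,
        "truth": truth,
        "proteins": proteins,
        "protein_genomes": protein_genomes,
        "sim": sim,
        "groups": groups,
        "shared": shared,
        "assignments": assignments,
        "clusters": clusters,
        "linkage": lnk,
        "summaries": summaries,
    }


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def tiny_population():
    """A small, quick population: 2 clusters x 2 genera x 2 genomes + 1
    singleton."""
    cfg = sd.PopulationConfig(
        n_clusters=2,
        genera_per_cluster=2,
        genomes_per_genus=2,
        genes_per_genome=8,
        n_singletons=1,
        rng_seed=3,
    )
    return sd.simulate_population(cfg)
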