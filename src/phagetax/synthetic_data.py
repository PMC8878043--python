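"""Synthetic phage populations with planted taxonomy.

Genomes are simulated on a three-level tree — cluster (subfamily) ancestors,
genus ancestors, genomes — over a pool of ancestral gene families (random
codon sequences with no internal stops).  Gene content is controlled by
family subsetting: every genome of a cluster carries the cluster core
families, every genome of a genus additionally carries the genus accessory
families, and each genome may carry private (unique) families.  Divergence
is controlled by per-site substitution probabilities applied on the
genus branch (``inter_genus_divergence``) and on each genome branch
(``intra_genus_divergence``); substitutions never create in-frame stop
codons, so translated proteins remain valid orthologs.  Intergenic spacers
are drawn at genus level, hence two genomes of a genus with zero divergence
and no private genes are byte-identical.

Everything is driven by a single seeded generator: a fixed config yields a
byte-identical population.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import CDSRecord, GenomeRecord, reverse_complement, translate_cds

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for one synthetic population.

    The defaults generate the desk-scale demo population: 3 clusters of
    2 genera with 3 genomes each, plus 2 singletons, ~12 kb genomes of
    12 genes.  Divergences are per-site substitution probabilities per
    branch; with the defaults, within-genus similarity sits in the low 80s
    (well above the 65% genus threshold), between-genus similarity within a
    cluster in the 30s (well below it), and between-genus shared protein
    content around 50% (well above the 30% cluster threshold).
    """

    n_clusters: int = 3
    genera_per_cluster: int = 2
    genomes_per_genus: int = 3
    gene_pool_size: int = 200
    genes_per_genome: int = 12
    mean_gene_len_nt: int = 600
    intra_genus_divergence: float = 0.02
    inter_genus_divergence: float = 0.12
    inter_cluster_shared_gene_frac: float = 0.1
    intra_cluster_shared_gene_frac: float = 0.5
    private_genes_per_genome: int = 1
    n_singletons: int = 2
    spacer_len_range: tuple[int, int] = (20, 120)
    rng_seed: int = 42

    def validate(self) -> None:
        for name in ("intra_genus_divergence", "inter_genus_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.75:
                raise ValueError(f"{name} must be in [0, 0.75]")
        for name in (
            "inter_cluster_shared_gene_frac",
            "intra_cluster_shared_gene_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        counts = (
            self.n_clusters,
            self.genera_per_cluster,
            self.genomes_per_genus,
            self.gene_pool_size,
            self.genes_per_genome,
            self.mean_gene_len_nt,
            self.private_genes_per_genome,
            self.n_singletons,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.genes_per_genome > self.gene_pool_size:
            raise ValueError("genes_per_genome exceeds gene_pool_size")
        if self.private_genes_per_genome >= self.genes_per_genome:
            raise ValueError("private genes must be fewer than genes per genome")
        if self._families_needed() > self.gene_pool_size:
            raise ValueError(
                f"population needs {self._families_needed()} gene families "
                f"but gene_pool_size is {self.gene_pool_size}"
            )

    def _content(self) -> tuple[int, int, int]:
        """(cluster core, genus accessory, private) family counts per genome."""
        n_private = self.private_genes_per_genome
        shared = self.genes_per_genome - n_private
        n_core = round(self.intra_cluster_shared_gene_frac * shared)
        n_acc = shared - n_core
        return n_core, n_acc, n_private

    def _families_needed(self) -> int:
        n_core, n_acc, n_private = self._content()
        n_shared_global = round(self.inter_cluster_shared_gene_frac * n_core)
        per_cluster_own = n_core - n_shared_global
        genomes = self.n_clusters * self.genera_per_cluster * self.genomes_per_genus
        return (
            n_shared_global
            + self.n_clusters * per_cluster_own
            + self.n_clusters * self.genera_per_cluster * n_acc
            + genomes * n_private
            + self.n_singletons * self.genes_per_genome
        )


@dataclass
class PlantedTruth:
    """Ground truth for one simulated population."""

    #: genome_id -> (cluster, genus, species) labels
    taxa: dict[str, tuple[str, str, str]]
    #: protein_id -> ancestral gene family id
    gene_families: dict[str, str]
    #: genus label -> predicted within-genus similarity percent
    predicted_within_genus_sim: dict[str, float]
    config: PopulationConfig | None = None

    def partition(self, level: int) -> dict[str, str]:
        """genome_id -> label at level 0=cluster, 1=genus, 2=species."""
        return {g: t[level] for g, t in self.taxa.items()}


def expected_pair_identity(divergence: float) -> float:
    """Per-site identity of two sequences that each diverged by ``divergence``
    from a common ancestor (uniform substitution over 3 alternatives)."""
    return (1.0 - divergence) ** 2 + divergence**2 / 3.0


def _random_gene(rng: np.random.Generator, mean_len: int) -> str:
    n_codons = max(10, int(round(rng.uniform(0.7, 1.3) * mean_len / 3)))
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def _mutate_gene(seq: str, d: float, rng: np.random.Generator) -> str:
    """Point substitutions at rate d, keeping the frame stop-free and the
    start/stop codons intact."""
    if d == 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < d)[0]
    for pos in hits:
        if pos < 3 or pos >= len(chars) - 3:
            continue
        old = chars[pos]
        options = [b for b in "ACGT" if b != old]
        rng.shuffle(options)
        codon_start = 3 * (pos // 3)
        for new in options:
            chars[pos] = new
            codon = "".join(chars[codon_start : codon_start + 3])
            if codon not in _STOPS:
                break
            chars[pos] = old
    return "".join(chars)


def _mutate_spacer(seq: str, d: float, rng: np.random.Generator) -> str:
    if d == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < d
    n = int(hits.sum())
    if n:
        arr[hits] = _BASES[rng.integers(0, 4, size=n)]
    return "".join(arr)


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    return "".join(rng.choice(_BASES, size=int(rng.integers(lo, hi + 1))))


def simulate_population(
    config: PopulationConfig,
) -> tuple[list[GenomeRecord], PlantedTruth]:
    """Simulate a population; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_core, n_acc, n_private = config._content()
    n_shared_global = round(config.inter_cluster_shared_gene_frac * n_core)

    pool = [_random_gene(rng, config.mean_gene_len_nt) for _ in range(config.gene_pool_size)]
    family_ids = [f"F{i + 1:04d}" for i in range(config.gene_pool_size)]
    strand_of = ["+" if rng.random() < 0.7 else "-" for _ in range(config.gene_pool_size)]
    next_family = 0

    def take(n: int) -> list[int]:
        nonlocal next_family
        out = list(range(next_family, next_family + n))
        next_family += n
        return out

    global_shared = take(n_shared_global)
    lo, hi = config.spacer_len_range

    genomes: list[GenomeRecord] = []
    taxa: dict[str, tuple[str, str, str]] = {}
    gene_families: dict[str, str] = {}
    predicted_sim: dict[str, float] = {}

    for c in range(config.n_clusters):
        cluster_label = f"C{c + 1}"
        core = global_shared + take(n_core - n_shared_global)
        # cluster-level versions of the core genes
        cluster_genes = {
            f: _mutate_gene(pool[f], config.inter_genus_divergence, rng)
            if f in global_shared
            else pool[f]
            for f in core
        }
        for g in range(config.genera_per_cluster):
            genus_label = f"{cluster_label}G{g + 1}"
            acc = take(n_acc)
            genus_families = core + acc
            genus_versions = {
                f: _mutate_gene(
                    cluster_genes.get(f, pool[f]),
                    config.inter_genus_divergence,
                    rng,
                )
                for f in genus_families
            }
            spacers = [
                _spacer(rng, lo, hi) for _ in range(len(genus_families) + 1)
            ]
            shared_gene_len = sum(len(v) for v in genus_versions.values())
            shared_len = shared_gene_len + sum(len(s) for s in spacers)
            private_len_est = n_private * (config.mean_gene_len_nt + (lo + hi) / 2)
            total_len = shared_len + private_len_est
            ident = expected_pair_identity(config.intra_genus_divergence)
            predicted_sim[genus_label] = (
                100.0 * ident * (2 * shared_len) / (2 * total_len)
            )
            same_species = predicted_sim[genus_label] >= 95.0
            for n in range(config.genomes_per_genus):
                genome_id = f"{genus_label}N{n + 1}"
                species_label = (
                    f"{genus_label}S1" if same_species else f"{genome_id}.sp"
                )
                private = take(n_private)
                parts: list[str] = []
                cds: list[tuple[int, int, str, str]] = []  # start,end,strand,family
                pos = 0
                for k, f in enumerate(genus_families):
                    sp = _mutate_spacer(
                        spacers[k], config.intra_genus_divergence, rng
                    )
                    parts.append(sp)
                    pos += len(sp)
                    gene = _mutate_gene(
                        genus_versions[f], config.intra_genus_divergence, rng
                    )
                    placed = (
                        gene if strand_of[f] == "+" else reverse_complement(gene)
                    )
                    parts.append(placed)
                    cds.append((pos, pos + len(gene), strand_of[f], family_ids[f]))
                    pos += len(gene)
                parts.append(
                    _mutate_spacer(spacers[-1], config.intra_genus_divergence, rng)
                )
                pos += len(parts[-1])
                for f in private:
                    sp = _spacer(rng, lo, hi)
                    parts.append(sp)
                    pos += len(sp)
                    gene = pool[f]
                    placed = (
                        gene if strand_of[f] == "+" else reverse_complement(gene)
                    )
                    parts.append(placed)
                    cds.append((pos, pos + len(gene), strand_of[f], family_ids[f]))
                    pos += len(gene)
                genomes.append(
                    _assemble(genome_id, f"synthetic phage {genome_id}", parts, cds, gene_families)
                )
                taxa[genome_id] = (cluster_label, genus_label, species_label)

    for s in range(config.n_singletons):
        genome_id = f"S{s + 1}"
        fams = take(config.genes_per_genome)
        parts = []
        cds = []
        pos = 0
        for f in fams:
            sp = _spacer(rng, lo, hi)
            parts.append(sp)
            pos += len(sp)
            gene = pool[f]
            placed = gene if strand_of[f] == "+" else reverse_complement(gene)
            parts.append(placed)
            cds.append((pos, pos + len(gene), strand_of[f], family_ids[f]))
            pos += len(gene)
        parts.append(_spacer(rng, lo, hi))
        genomes.append(
            _assemble(genome_id, f"synthetic singleton phage {genome_id}", parts, cds, gene_families)
        )
        taxa[genome_id] = (f"SGL-{genome_id}", f"SGL-{genome_id}", f"SGL-{genome_id}")

    truth = PlantedTruth(
        taxa=taxa,
        gene_families=gene_families,
        predicted_within_genus_sim=predicted_sim,
        config=config,
    )
    return genomes, truth


def _assemble(
    genome_id: str,
    name: str,
    parts: list[str],
    cds: list[tuple[int, int, str, str]],
    gene_families: dict[str, str],
) -> GenomeRecord:
    sequence = "".join(parts)
    records = []
    for idx, (start, end, strand, family) in enumerate(cds):
        nt = sequence[start:end]
        if strand == "-":
            nt = reverse_complement(nt)
        pid = f"{genome_id}_{idx + 1:04d}"
        records.append(
            CDSRecord(
                genome_id=genome_id,
                cds_index=idx,
                start=start,
                end=end,
                strand=strand,
                protein_id=pid,
                aa_sequence=translate_cds(nt),
            )
        )
        gene_families[pid] = family
    return GenomeRecord(
        genome_id=genome_id, name=name, sequence=sequence, cds=records
    )


def demo_population(
    seed: int = 42,
) -> tuple[list[GenomeRecord], PlantedTruth]:
    """The default demo population (3 clusters x 2 genera x 3 genomes + 2
    singletons) under a caller-chosen seed."""
    return simulate_population(PopulationConfig(rng_seed=seed))


def write_fixture(
    genomes: list[GenomeRecord],
    truth: PlantedTruth,
    outdir: str | Path,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write genome FASTA, CDS GFF3, protein FASTA and truth TSV.

    Returns {filename: sha256}.  Refuses to touch a non-empty existing
    directory unless ``overwrite`` is set.
    """
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    from .genome_io import write_fasta, write_protein_fasta

    write_fasta(genomes, out / "genomes.fasta")
    write_protein_fasta(genomes, out / "proteins.faa")
    with open(out / "cds.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            for c in g.cds:
                fh.write(
                    f"{g.genome_id}\tphagetax_sim\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t0\tID={c.protein_id}\n"
                )
    with open(out / "truth.tsv", "w") as fh:
        fh.write("genome_id\tcluster\tgenus\tspecies\tprotein_id\tfamily\n")
        for g in genomes:
            cl, ge, sp = truth.taxa[g.genome_id]
            for c in g.cds:
                fam = truth.gene_families[c.protein_id]
                fh.write(f"{g.genome_id}\t{cl}\t{ge}\t{sp}\t{c.protein_id}\t{fam}\n")
    digests = {}
    for f in sorted(out.iterdir()):
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return digests
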