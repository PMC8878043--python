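"""Reading, validating and writing phage genome records.

Genomes arrive either as nucleotide FASTA (one genome per record) or as
GenBank flat files whose CDS features carry ``/translation`` qualifiers.
Both are normalised into :class:`GenomeRecord` / :class:`CDSRecord`, the
in-memory model used by every downstream stage.  For unannotated (typically
synthetic) genomes a deterministic naive ORF caller is provided.

Coordinates are 0-based half-open internally; written reports use 1-based
inclusive coordinates (GenBank convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Characters accepted in input nucleotide sequences (IUPAC DNA + U).
_IUPAC_DNA = set("ACGTUNRYSWKMBDHV")
#: Ambiguity codes (other than N) collapsed to N on ingest.
_AMBIGUOUS = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: NCBI translation table 11 (bacterial/phage convention).
TRANSLATION_TABLE = 11


@dataclass
class CDSRecord:
    """One protein-coding feature on a genome.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the genome; ``aa_sequence`` excludes the stop codon.
    """

    genome_id: str
    cds_index: int
    start: int
    end: int
    strand: str
    protein_id: str
    aa_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid CDS coordinates [{self.start}, {self.end}) "
                f"for {self.protein_id}"
            )
        if not self.aa_sequence:
            raise ValueError(f"empty translation for {self.protein_id}")
        if "*" in self.aa_sequence:
            raise ValueError(f"internal stop in translation of {self.protein_id}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One phage genome: identifier, sequence and its CDS complement."""

    genome_id: str
    name: str
    sequence: str
    cds: list[CDSRecord] = field(default_factory=list)
    #: Genomes flagged as partial are kept in similarity/cluster assignment
    #: but excluded from core-protein counts.
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"genome {self.genome_id}: non-ACGTN characters {sorted(bad)} "
                "(normalise with normalise_sequence first)"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        """GC content in percent; N excluded from the denominator."""
        acgt = sum(self.sequence.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return 100.0 * gc / acgt

    @property
    def n_cds(self) -> int:
        return len(self.cds)


def normalise_sequence(raw: str, genome_id: str = "?") -> str:
    """Uppercase, map U->T, collapse non-N ambiguity codes to N.

    Raises ``ValueError`` for characters outside the IUPAC DNA alphabet.
    """
    seq = raw.upper()
    bad = set(seq) - _IUPAC_DNA
    if bad:
        raise ValueError(
            f"genome {genome_id}: non-nucleotide characters {sorted(bad)}"
        )
    seq = seq.replace("U", "T")
    amb = set(seq) & _AMBIGUOUS
    if amb:
        logger.warning(
            "genome %s: ambiguity codes %s mapped to N",
            genome_id,
            "".join(sorted(amb)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in amb}))
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    return "fasta"


def read_genomes(
    paths: Sequence[str | Path],
    format: str | None = None,
) -> list[GenomeRecord]:
    """Read genomes from FASTA or GenBank flat files.

    Parameters
    ----------
    paths:
        Files to read; each may contain several records.
    format:
        ``"fasta"`` or ``"genbank"``; inferred from the file suffix when
        omitted.

    GenBank CDS features with a ``/translation`` qualifier become
    :class:`CDSRecord` entries.  Duplicate genome identifiers across all
    files are an error.
    """
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for p in paths:
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(str(path))
        fmt = format or _infer_format(path)
        if fmt not in ("fasta", "genbank"):
            raise ValueError(f"unsupported format {fmt!r}")
        records = list(SeqIO.parse(str(path), fmt))
        if not records:
            raise ValueError(f"no records in {path}")
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate genome identifier {rec.id!r}")
            seen.add(rec.id)
            seq = normalise_sequence(str(rec.seq), rec.id)
            cds_list: list[CDSRecord] = []
            if fmt == "genbank":
                cds_list = _cds_from_genbank(rec, rec.id)
            genomes.append(
                GenomeRecord(
                    genome_id=rec.id,
                    name=rec.description or rec.id,
                    sequence=seq,
                    cds=cds_list,
                )
            )
    return genomes


def _cds_from_genbank(rec, genome_id: str) -> list[CDSRecord]:
    cds_list = []
    idx = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        aa = feat.qualifiers.get("translation", [None])[0]
        if not aa:
            continue
        aa = aa.rstrip("*")
        pid = feat.qualifiers.get(
            "protein_id", [f"{genome_id}_{idx + 1:04d}"]
        )[0]
        strand = "-" if feat.location.strand == -1 else "+"
        cds_list.append(
            CDSRecord(
                genome_id=genome_id,
                cds_index=idx,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
                protein_id=pid,
                aa_sequence=aa,
            )
        )
        idx += 1
    return cds_list


def translate_cds(nt: str) -> str:
    """Translate an ORF (table 11); initial residue forced to M, stop dropped."""
    aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    return "M" + aa[1:] if aa else aa


def _scan_frame(seq: str, frame: int, min_len_nt: int) -> list[tuple[int, int]]:
    """ORFs (start..stop inclusive, 0-based half-open) in one forward frame.

    Within a frame, candidate ORFs sharing a stop keep only the longest
    (i.e. the earliest start since the previous stop).
    """
    orfs = []
    start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None and pos + 3 - start >= min_len_nt:
                orfs.append((start, pos + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = pos
    return orfs


def call_orfs(
    genome: GenomeRecord,
    min_len_nt: int = 120,
    overwrite: bool = False,
) -> GenomeRecord:
    """Naive six-frame ORF caller (start ATG/GTG/TTG to next in-frame stop).

    Keeps ORFs of at least ``min_len_nt`` nucleotides including the stop
    codon.  Deterministic: resulting CDSRecords are sorted by start then
    strand.  A genome shorter than ``min_len_nt`` simply gets no CDS.
    """
    if genome.cds and not overwrite:
        raise ValueError(
            f"genome {genome.genome_id} already has CDS annotations; "
            "pass overwrite=True to replace them"
        )
    length = genome.length_bp
    found: list[tuple[int, int, str]] = []
    for frame in range(3):
        for s, e in _scan_frame(genome.sequence, frame, min_len_nt):
            found.append((s, e, "+"))
    rc = reverse_complement(genome.sequence)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, min_len_nt):
            found.append((length - e, length - s, "-"))
    found.sort(key=lambda t: (t[0], t[2]))
    cds_list = []
    for idx, (s, e, strand) in enumerate(found):
        nt = genome.sequence[s:e] if strand == "+" else rc[length - e : length - s]
        cds_list.append(
            CDSRecord(
                genome_id=genome.genome_id,
                cds_index=idx,
                start=s,
                end=e,
                strand=strand,
                protein_id=f"{genome.genome_id}_{idx + 1:04d}",
                aa_sequence=translate_cds(nt),
            )
        )
    return GenomeRecord(
        genome_id=genome.genome_id,
        name=genome.name,
        sequence=genome.sequence,
        cds=cds_list,
        partial=genome.partial,
    )


def ensure_annotated(
    genomes: Iterable[GenomeRecord], min_len_nt: int = 120
) -> list[GenomeRecord]:
    """Call ORFs on any genome lacking CDS annotations; others pass through."""
    return [g if g.cds else call_orfs(g, min_len_nt=min_len_nt) for g in genomes]


def all_proteins(genomes: Iterable[GenomeRecord]) -> list[CDSRecord]:
    """Flatten CDS records; enforces collection-wide protein_id uniqueness."""
    out: list[CDSRecord] = []
    seen: set[str] = set()
    for g in genomes:
        for c in g.cds:
            if c.protein_id in seen:
                raise ValueError(f"duplicate protein_id {c.protein_id!r}")
            seen.add(c.protein_id)
            out.append(c)
    return out


def write_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id} {g.name}\n")
            for i in range(0, g.length_bp, 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def write_protein_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            for c in g.cds:
                fh.write(f">{c.protein_id} {g.genome_id}\n{c.aa_sequence}\n")


def write_manifest(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """TSV genome manifest: genome_id, length_bp, gc_percent, n_cds."""
    with open(path, "w") as fh:
        fh.write("genome_id\tlength_bp\tgc_percent\tn_cds\n")
        for g in genomes:
            fh.write(f"{g.genome_id}\t{g.length_bp}\t{g.gc_percent:.2f}\t{g.n_cds}\n")
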