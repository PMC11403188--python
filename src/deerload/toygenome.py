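"""Small synthetic reference genomes with annotated gene models.

Generates a random chromosome with embedded multi-exon protein-coding genes on
both strands, written as FASTA + GFF3 (1-based, inclusive, with CDS phase), to
exercise codon-level consequence annotation. Every CDS begins with ATG, ends
with a stop codon and contains no internal stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

STOPS = ("TAA", "TAG", "TGA")
_B = "ACGT"


def revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class Transcript:
    """One fully-coding transcript: ordered genomic CDS pieces + strand."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_pieces: list  # [(start, end)] 1-based inclusive, ascending

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_pieces)

    def cds_sequence(self, sequences: dict) -> str:
        seq = sequences[self.chrom]
        cat = "".join(seq[s - 1 : e] for s, e in self.cds_pieces)
        return revcomp(cat) if self.strand == "-" else cat

    def cds_index(self, pos: int) -> int | None:
        """0-based position within the coding sequence, or None if not in CDS."""
        off = 0
        for s, e in self.cds_pieces:
            if s <= pos <= e:
                fwd = off + (pos - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            off += e - s + 1
        return None

    def introns(self) -> list:
        """Introns as (start, end) genomic, ascending."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds_pieces, self.cds_pieces[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def splice_sites(self) -> tuple[set, set]:
        """(donor positions, acceptor positions): first/last 2 bp of each intron
        in transcription orientation."""
        donors, acceptors = set(), set()
        for lo, hi in self.introns():
            if self.strand == "+":
                donors.update((lo, lo + 1))
                acceptors.update((hi - 1, hi))
            else:
                donors.update((hi - 1, hi))
                acceptors.update((lo, lo + 1))
        return donors, acceptors

    def translate(self, sequences: dict) -> str:
        return str(Seq(self.cds_sequence(sequences)).translate())


@dataclass
class ToyGenome:
    sequences: dict  # chrom -> str
    transcripts: list = field(default_factory=list)

    def write(self, fasta_path, gff3_path):
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.transcripts:
                g0 = min(s for s, _ in t.cds_pieces)
                g1 = max(e for _, e in t.cds_pieces)
                base = f"{t.chrom}\tdeerload\t"
                fh.write(
                    base + f"gene\t{g0}\t{g1}\t.\t{t.strand}\t.\tID={t.gene_id}\n"
                )
                mid = f"{t.gene_id}.t1"
                fh.write(
                    base
                    + f"mRNA\t{g0}\t{g1}\t.\t{t.strand}\t.\tID={mid};Parent={t.gene_id}\n"
                )
                pieces = (
                    t.cds_pieces if t.strand == "+" else list(reversed(t.cds_pieces))
                )
                off = 0
                rows = []
                for s, e in pieces:  # transcription order
                    phase = (3 - off % 3) % 3
                    rows.append((s, e, phase))
                    off += e - s + 1
                for i, (s, e, phase) in enumerate(sorted(rows)):
                    fh.write(
                        base
                        + f"exon\t{s}\t{e}\t.\t{t.strand}\t.\tID={mid}.exon{i};Parent={mid}\n"
                    )
                    fh.write(
                        base
                        + f"CDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\tID={mid}.cds;Parent={mid}\n"
                    )


def _random_coding(n_codons: int, rng) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(_B[i] for i in rng.integers(0, 4, 3))
            if c not in STOPS:
                break
        codons.append(c)
    codons.append(STOPS[rng.integers(0, len(STOPS))])
    return "".join(codons)


def generate_toy_genome(
    n_genes: int = 4,
    cds_len: int = 300,
    seed: int = 0,
    n_exons: int = 2,
    intron_len: int = 60,
    intergenic: int = 200,
    chrom: str = "chr1",
) -> ToyGenome:
    """Build one chromosome carrying ``n_genes`` coding genes.

    Genes alternate strand (+, -, +, ...); each CDS of ``cds_len`` bp
    (divisible by 3, >= 9) is split into ``n_exons`` pieces separated by
    ``intron_len``-bp introns whose first/last two bases are canonical
    GT..AG in transcription orientation.
    """
    if cds_len % 3 or cds_len < 9:
        raise ValueError("cds_len must be divisible by 3 and >= 9")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_exons < 1 or intron_len < 10:
        raise ValueError("need n_exons >= 1 and intron_len >= 10")
    per_gene = cds_len + (n_exons - 1) * intron_len
    total = intergenic + n_genes * (per_gene + intergenic)
    rng = np.random.default_rng(seed)
    seq = list("".join(_B[i] for i in rng.integers(0, 4, total)))
    transcripts = []
    cursor = intergenic
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        coding = _random_coding(cds_len // 3, rng)
        genomic_cds = coding if strand == "+" else revcomp(coding)
        # split into n_exons pieces (left-to-right on the genome)
        cuts = sorted(
            rng.choice(np.arange(3, cds_len - 3), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        bounds = [0, *cuts, cds_len]
        pieces = []
        gpos = cursor  # 0-based genomic offset of gene start
        for k in range(n_exons):
            lo, hi = bounds[k], bounds[k + 1]
            piece = genomic_cds[lo:hi]
            start = gpos
            seq[start : start + len(piece)] = list(piece)
            pieces.append((start + 1, start + len(piece)))  # 1-based inclusive
            gpos = start + len(piece)
            if k < n_exons - 1:
                # intron: canonical GT...AG in transcription orientation
                intron = ["".join(_B[i] for i in rng.integers(0, 4, intron_len))]
                intron = list(intron[0])
                if strand == "+":
                    intron[0:2] = ["G", "T"]
                    intron[-2:] = ["A", "G"]
                else:
                    intron[0:2] = ["C", "T"]
                    intron[-2:] = ["A", "C"]
                seq[gpos : gpos + intron_len] = intron
                gpos += intron_len
        cursor = gpos + intergenic
        if cursor > total:
            raise ValueError("gene layout overflows the sequence")
        transcripts.append(
            Transcript(f"gene{gi + 1}", chrom, strand, pieces)
        )
    genome = ToyGenome(sequences={chrom: "".join(seq)}, transcripts=transcripts)
    for t in transcripts:  # sanity: ORFs are clean by construction
        pep = t.translate(genome.sequences)
        assert pep.endswith("*") and "*" not in pep[:-1] and pep[0] == "M"
    return genome


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path) -> list[Transcript]:
    """Parse CDS features of a GFF3 file into :class:`Transcript` models."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    cds = df[df["type"] == "CDS"].copy()

    def parent(attrs: str) -> str:
        for item in attrs.split(";"):
            if item.startswith("Parent="):
                return item[len("Parent=") :]
        raise ValueError(f"CDS feature lacks Parent attribute: {attrs}")

    cds["tid"] = cds["attrs"].map(parent)
    out = []
    for tid, grp in cds.groupby("tid", sort=False):
        grp = grp.sort_values("start")
        out.append(
            Transcript(
                gene_id=tid.removesuffix(".t1"),
                chrom=grp["chrom"].iloc[0],
                strand=grp["strand"].iloc[0],
                cds_pieces=[(int(s), int(e)) for s, e in zip(grp["start"], grp["end"])],
            )
        )
    for t in out:
        if t.cds_length % 3:
            raise ValueError(f"CDS length of {t.gene_id} not divisible by 3")
    return out
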