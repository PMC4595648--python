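"""Gene-panel model: CDS geometry, reference access and consequence classification.

A panel is a small set of protein-coding genes (targeted cancer-driver panel
style), each described by its contig, strand and sorted, non-overlapping CDS
intervals in 1-based closed coordinates.  The reading frame is anchored at the
translation start: the first base of the first CDS interval on the plus
strand, the last base of the last interval on the minus strand.

Consequence classes follow the usual coding-panel vocabulary: an SNV inside a
CDS is missense / nonsense / silent by codon substitution; an indel inside a
CDS is frameshift or inframe-indel by length modulo 3; a variant in an intron
within 2 bases of an interior exon edge is a splice alteration; anything else
inside the gene span is intronic, and positions outside every panel gene are
off-target.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio.Seq import Seq

SPLICE_WINDOW = 2  # intronic bases next to an interior exon edge called splice

#: Consequence vocabulary used throughout the package.
CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "inframe-indel",
    "silent",
    "intronic",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(reference, contig: str, start: int, end: int) -> str:
    """Fetch reference sequence, 1-based inclusive coordinates.

    Accepts either a plain mapping contig -> sequence string or a
    ``pyfaidx.Fasta`` object (both support the same slicing protocol).
    """
    frag = reference[contig][start - 1 : end]
    return str(getattr(frag, "seq", frag)).upper()


@dataclass(frozen=True)
class Gene:
    """One panel gene: strand-aware CDS geometry on a single contig."""

    name: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]  # 1-based closed intervals, sorted

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")
        last_end = 0
        for start, end in self.cds:
            if start <= last_end:
                raise ValueError(f"gene {self.name}: CDS intervals must be sorted and non-overlapping")
            if end < start:
                raise ValueError(f"gene {self.name}: empty CDS interval ({start}, {end})")
            last_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_index(self, pos: int) -> int | None:
        """0-based position of a genomic coordinate along the coding sequence.

        Returns None when ``pos`` is not inside any CDS interval.  On the
        minus strand index 0 is the last genomic base of the last interval.
        """
        offset = 0
        for start, end in self.cds:
            if start <= pos <= end:
                plus_index = offset + (pos - start)
                if self.strand == "+":
                    return plus_index
                return self.cds_length - 1 - plus_index
            offset += end - start + 1
        return None

    def coding_sequence(self, reference) -> str:
        genomic = "".join(fetch(reference, self.contig, s, e) for s, e in self.cds)
        return genomic if self.strand == "+" else revcomp(genomic)

    def intron_context(self, pos: int) -> str | None:
        """Classify an intra-span, non-CDS position as 'splice' or 'intronic'."""
        lo, hi = self.span
        if not lo <= pos <= hi:
            return None
        if self.cds_index(pos) is not None:
            return None
        for start, end in self.cds:
            # interior edges only: distance into the intron from an exon edge
            if 0 < start - pos <= SPLICE_WINDOW and start != lo:
                return "splice"
            if 0 < pos - end <= SPLICE_WINDOW and end != hi:
                return "splice"
        return "intronic"


@dataclass
class GeneModel:
    """The panel: genes indexed by name, with lookup by genomic position."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, name: str) -> Gene:
        return self.genes[name]

    def add(self, gene: Gene) -> None:
        if gene.name in self.genes:
            raise ValueError(f"duplicate gene {gene.name}")
        self.genes[gene.name] = gene

    def gene_at(self, contig: str, pos: int) -> Gene | None:
        for gene in self.genes.values():
            lo, hi = gene.span
            if gene.contig == contig and lo <= pos <= hi:
                return gene
        return None

    # ------------------------------------------------------------------
    # consequence classification
    # ------------------------------------------------------------------
    def classify(self, contig: str, pos: int, ref: str, alt: str, reference) -> tuple[str | None, str]:
        """Return (gene name or None, consequence class or 'off-target').

        ``ref``/``alt`` are plus-strand alleles as written in tallies/VCF;
        deletions may be written with '-' as the alt allele.
        """
        gene = self.gene_at(contig, pos)
        if gene is None:
            return None, "off-target"
        ref_len = len(ref)
        alt_len = 0 if alt == "-" else len(alt)
        if ref_len == 1 and alt_len == 1:
            return gene.name, self._classify_snv(gene, pos, ref, alt, reference)
        return gene.name, self._classify_indel(gene, pos, ref_len, alt_len)

    def _classify_snv(self, gene: Gene, pos: int, ref: str, alt: str, reference) -> str:
        idx = gene.cds_index(pos)
        if idx is None:
            return gene.intron_context(pos) or "intronic"
        cds = gene.coding_sequence(reference)
        base_ref, base_alt = (ref, alt) if gene.strand == "+" else (revcomp(ref), revcomp(alt))
        if cds[idx] != base_ref.upper():
            raise ValueError(
                f"reference mismatch at {gene.contig}:{pos}: expected {cds[idx]}, tally says {base_ref}"
            )
        codon_start = (idx // 3) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        alt_codon = ref_codon[: idx % 3] + base_alt.upper() + ref_codon[idx % 3 + 1 :]
        if len(ref_codon) < 3:  # trailing partial codon in a malformed model
            return "missense"
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return "silent"
        if aa_alt == "*":
            return "nonsense"
        return "missense"

    def _classify_indel(self, gene: Gene, pos: int, ref_len: int, alt_len: int) -> str:
        span = range(pos, pos + max(ref_len, 1))
        if any(gene.cds_index(p) is not None for p in span):
            return "frameshift" if abs(ref_len - alt_len) % 3 else "inframe-indel"
        return gene.intron_context(pos) or "intronic"

    # ------------------------------------------------------------------
    # BED12 round-trip
    # ------------------------------------------------------------------
    def to_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in self.genes.values():
                lo, hi = gene.span
                sizes = ",".join(str(e - s + 1) for s, e in gene.cds)
                starts = ",".join(str(s - lo) for s, _ in gene.cds)
                fields = [
                    gene.contig, str(lo - 1), str(hi), gene.name, "0", gene.strand,
                    str(lo - 1), str(hi), "0", str(len(gene.cds)), sizes, starts,
                ]
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneModel":
        model = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                cds = tuple(
                    (chrom_start + off + 1, chrom_start + off + size)
                    for off, size in zip(starts, sizes)
                )
                model.add(Gene(name=name, contig=chrom, strand=strand, cds=cds))
        return model


# ----------------------------------------------------------------------
# synthetic panel
# ----------------------------------------------------------------------

_DEFAULT_GENES = ("EGFR", "TP53", "KRAS", "BRAF", "ARID1B", "NOTCH1", "IGF1R", "ATM")

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


def synthetic_panel(
    seed: int,
    gene_names: tuple[str, ...] = _DEFAULT_GENES,
    n_codons: tuple[int, int] = (40, 80),
    n_exons: tuple[int, int] = (2, 3),
) -> tuple[GeneModel, dict[str, str]]:
    """Generate a small panel with per-gene contigs and reference sequences.

    Each gene receives a random CDS (ATG ... stop, no internal stops), split
    into exons separated by random introns, on a random strand, embedded in a
    per-gene contig with flanking sequence.  Returns the gene model and a
    mapping contig -> reference sequence usable wherever a reference is
    expected.
    """
    rng = random.Random(seed)
    model = GeneModel()
    reference: dict[str, str] = {}
    for name in gene_names:
        codons = rng.randint(*n_codons)
        cds_seq = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(codons)) + rng.choice(sorted(_STOPS))
        strand = rng.choice("+-")
        exon_count = rng.randint(*n_exons)
        # split the CDS into exon_count chunks, each at least 9 bp
        cuts = sorted(rng.sample(range(9, len(cds_seq) - 9), exon_count - 1)) if exon_count > 1 else []
        bounds = [0, *cuts, len(cds_seq)]
        mrna_chunks = [cds_seq[a:b] for a, b in zip(bounds, bounds[1:])]
        genomic_chunks = mrna_chunks if strand == "+" else [revcomp(c) for c in reversed(mrna_chunks)]
        flank = "".join(rng.choice("ACGT") for _ in range(50))
        contig = f"ctg_{name}"
        seq_parts = [flank]
        cds_intervals = []
        cursor = len(flank)
        for i, chunk in enumerate(genomic_chunks):
            if i:
                intron = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 100)))
                seq_parts.append(intron)
                cursor += len(intron)
            cds_intervals.append((cursor + 1, cursor + len(chunk)))
            seq_parts.append(chunk)
            cursor += len(chunk)
        seq_parts.append("".join(rng.choice("ACGT") for _ in range(50)))
        reference[contig] = "".join(seq_parts)
        model.add(Gene(name=name, contig=contig, strand=strand, cds=tuple(cds_intervals)))
    return model, reference


def sample_coding_snv(
    model: GeneModel,
    reference: Mapping[str, str],
    rng: random.Random,
    want: tuple[str, ...] = ("missense", "nonsense"),
) -> tuple[str, str, int, str, str, str]:
    """Draw a random coding SNV with a desired consequence.

    Returns (gene, contig, pos, ref, alt, consequence).  Used by the
    synthetic cohort generator so that simulated somatic mutations survive
    the silent/intronic exclusion step.
    """
    genes = sorted(model.genes)
    for _ in range(10_000):
        gene = model[rng.choice(genes)]
        start, end = rng.choice(gene.cds)
        pos = rng.randint(start, end)
        ref = fetch(reference, gene.contig, pos, pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        _, csq = model.classify(gene.contig, pos, ref, alt, reference)
        if csq in want:
            return gene.name, gene.contig, pos, ref, alt, csq
    raise RuntimeError("could not sample a coding SNV with the requested consequence")
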