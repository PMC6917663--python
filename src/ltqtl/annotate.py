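"""Candidate-interval gene annotation and codon-level SNP consequences.

Gene models (exon/CDS structure from GFF3) are intersected with the BSA
candidate interval, and each SNP falling in a gene is classified at codon
level: the genomic position is mapped to a CDS coordinate in transcription
order (minus-strand CDS are reverse-complemented, and the SNP alleles
complemented accordingly), the affected codon is mutated and translated with
the standard nuclear genetic code, and the substitution is labelled
``{RefAA}{codon}{AltAA}`` in three-letter code (e.g. Arg2Cys). A change that
creates or removes a stop codon is non-synonymous with ``Ter`` in the label.

Coordinates follow GFF3/VCF: 1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "GeneModel",
    "SnpEffect",
    "read_gene_models",
    "genes_in_region",
    "annotate_snp",
    "summarize_effects",
    "effects_frame",
]


@dataclass
class GeneModel:
    """One gene with its exon and CDS intervals (genomic, 1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list  # [(start, end), ...] sorted by genomic position
    cds: list  # [(start, end), ...] sorted by genomic position

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        for intervals, kind in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {kind} intervals in {self.gene_id}")
        exon_cover = set()
        for s, e in self.exons:
            exon_cover.update(range(s, e + 1))
        for s, e in self.cds:
            if self.exons and not set(range(s, e + 1)) <= exon_cover:
                raise ValueError(f"CDS outside exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_position(self, genomic_pos: int) -> int | None:
        """1-based CDS coordinate in transcription order, or None outside CDS."""
        offsets = []
        running = 0
        for s, e in self.cds:
            offsets.append((s, e, running))
            running += e - s + 1
        for s, e, off in offsets:
            if s <= genomic_pos <= e:
                plus_pos = off + (genomic_pos - s) + 1
                if self.strand == "+":
                    return plus_pos
                return self.cds_length - plus_pos + 1
        return None

    def cds_sequence(self, genome) -> str:
        """Assembled CDS in transcription order (reverse-complemented on -)."""
        seq = "".join(_fetch(genome, self.chrom, s, e) for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


@dataclass
class SnpEffect:
    """Consequence call for one SNP against one gene model."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    region: str  # "CDS" | "intron" | "intergenic"
    cds_pos: int | None = None
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None
    label: str | None = None
    incomplete_codon: bool = False


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Subsequence [start, end] 1-based inclusive from a genome mapping.

    ``genome`` maps chromosome name to a string / Seq / SeqRecord.
    """
    seq = genome[chrom]
    if hasattr(seq, "seq"):  # SeqRecord
        seq = seq.seq
    return str(seq[start - 1 : end])


def read_gene_models(gff_path, first_transcript_only: bool = True) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    Only the first mRNA per gene is used when several are annotated; genes
    without an mRNA child take exon/CDS features parented directly on the
    gene. Requires ``gffutils``.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if (mrnas and first_transcript_only) else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons and cds:
            exons = list(cds)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def genes_in_region(
    models, chrom, start: int, end: int, mode: str = "contained"
) -> list[GeneModel]:
    """Genes inside (or overlapping) a genomic window.

    mode 'contained': the whole gene lies within [start, end];
    mode 'overlap': any intersection counts.
    """
    if start > end:
        raise ValueError("region start exceeds end")
    if mode not in ("contained", "overlap"):
        raise ValueError("mode must be 'contained' or 'overlap'")
    out = []
    for g in models:
        if g.chrom != chrom:
            continue
        if mode == "contained":
            hit = g.start >= start and g.end <= end
        else:
            hit = g.start <= end and g.end >= start
        if hit:
            out.append(g)
    return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def annotate_snp(snp, model: GeneModel, genome) -> SnpEffect:
    """Codon-level consequence of one SNP against one gene model.

    ``snp`` is a (chrom, pos, ref, alt) tuple or any object with those
    attributes. The reference base in ``genome`` must equal ``ref`` at the
    SNP position (alleles are given on the plus strand, as in a VCF); a
    mismatch raises. SNPs inside the gene but outside the CDS are labelled
    intronic; SNPs outside the gene are intergenic. A SNP in an incomplete
    terminal codon is flagged and left untranslated.
    """
    if isinstance(snp, tuple):
        chrom, pos, ref, alt = snp
    else:
        chrom, pos, ref, alt = snp.chrom, snp.pos, snp.ref, snp.alt
    ref, alt = ref.upper(), alt.upper()
    if chrom != model.chrom:
        raise ValueError(f"SNP on {chrom} but gene {model.gene_id} on {model.chrom}")
    genome_base = _fetch(genome, chrom, pos, pos).upper()
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {genome_base}, "
            f"SNP record says {ref}"
        )

    if not (model.start <= pos <= model.end):
        return SnpEffect(chrom, pos, ref, alt, None, "intergenic")

    cds_pos = model.cds_position(pos)
    if cds_pos is None:
        return SnpEffect(chrom, pos, ref, alt, model.gene_id, "intron")

    cds_seq = model.cds_sequence(genome)
    ref_tx, alt_tx = (ref, alt)
    if model.strand == "-":
        ref_tx = ref.translate(_COMPLEMENT)
        alt_tx = alt.translate(_COMPLEMENT)
    if cds_seq[cds_pos - 1] != ref_tx:  # internal consistency guard
        raise ValueError(
            f"CDS assembly inconsistent at {model.gene_id} CDS position {cds_pos}"
        )

    codon_index = (cds_pos - 1) // 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return SnpEffect(
            chrom, pos, ref, alt, model.gene_id, "CDS",
            cds_pos=cds_pos, codon_index=codon_index, ref_codon=ref_codon,
            incomplete_codon=True,
        )
    within = (cds_pos - 1) % 3
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    synonymous = ref_aa == alt_aa
    label = f"{seq3(ref_aa)}{codon_index}{seq3(alt_aa)}"
    return SnpEffect(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        gene_id=model.gene_id, region="CDS",
        cds_pos=cds_pos, codon_index=codon_index,
        ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa,
        synonymous=synonymous, label=label,
    )


def summarize_effects(effects) -> dict:
    """Counts by region class and by synonymous / non-synonymous."""
    counts = {
        "CDS": 0,
        "intron": 0,
        "intergenic": 0,
        "synonymous": 0,
        "non_synonymous": 0,
        "incomplete_codon": 0,
    }
    for e in effects:
        counts[e.region] += 1
        if e.region == "CDS":
            if e.incomplete_codon:
                counts["incomplete_codon"] += 1
            elif e.synonymous:
                counts["synonymous"] += 1
            else:
                counts["non_synonymous"] += 1
    return counts


def effects_frame(effects) -> pd.DataFrame:
    """SNP effect calls as a flat table."""
    rows = []
    for e in effects:
        rows.append(
            {
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref,
                "alt": e.alt,
                "gene_id": e.gene_id or "",
                "region": e.region,
                "cds_pos": e.cds_pos,
                "codon_index": e.codon_index,
                "ref_codon": e.ref_codon,
                "alt_codon": e.alt_codon,
                "ref_aa": e.ref_aa,
                "alt_aa": e.alt_aa,
                "synonymous": e.synonymous,
                "label": e.label,
            }
        )
    return pd.DataFrame(rows)
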