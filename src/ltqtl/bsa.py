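"""In silico bulked-segregant analysis on a resequenced germplasm panel.

Rather than pooling DNA, the "bulks" here are sets of lines with contrasting
phenotype whose genotypes are already known from resequencing. Within a QTL
region, a SNP is retained when every evaluable call in the resistant bulk is
the same homozygous allele, every evaluable call in the sensitive bulk is the
same homozygous allele, and the two alleles differ — the diagnostic-haplotype
criterion. The span of retained SNPs delimits the candidate interval.

Genotype codes per line: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing. Coordinates are 1-based inclusive,
matching VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "Bulk",
    "BsaPolicy",
    "BsaResult",
    "build_bulks",
    "extract_region",
    "concordance_filter",
    "candidate_region",
    "span_kb",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantTable:
    """Biallelic SNP calls for a panel of lines.

    ``sites`` has one row per SNP (chrom, pos, ref, alt); ``genotypes`` is an
    int8 array (n_snps, n_lines). Multi-allelic records must be split into
    biallelic rows before construction (the VCF reader does this).
    """

    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    line_ids: list
    genotypes: np.ndarray

    def __post_init__(self):
        required = {"chrom", "pos", "ref", "alt"}
        if not required <= set(self.sites.columns):
            raise ValueError(f"variant table lacks columns {sorted(required)}")
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.line_ids)):
            raise ValueError("genotype array shape does not match sites x lines")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on {chrom}")
        bad_allele = ~(
            self.sites["ref"].str.len().eq(1) & self.sites["alt"].str.len().eq(1)
        )
        if bad_allele.any():
            raise ValueError("SNP records must carry single-nucleotide alleles")

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def line_columns(self, line_ids) -> np.ndarray:
        idx = [self.line_ids.index(l) for l in line_ids]
        return self.genotypes[:, idx]

    def subset(self, row_mask) -> "VariantTable":
        return VariantTable(
            self.sites.loc[row_mask].reset_index(drop=True),
            list(self.line_ids),
            self.genotypes[np.asarray(row_mask)],
        )

    @classmethod
    def from_vcf(cls, path) -> "VariantTable":
        """Read SNPs from a VCF, splitting multi-allelic records.

        Indels and records with non-SNP alleles are skipped.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        line_ids = list(vcf.samples)
        rows, geno = [], []
        for v in vcf:
            if v.REF is None or len(v.REF) != 1:
                continue
            # allele index per haplotype for multi-allelic splitting
            calls = np.array([g[:2] for g in v.genotypes], dtype=int)
            for ai, alt in enumerate(v.ALT, start=1):
                if len(alt) != 1:
                    continue
                codes = np.full(len(line_ids), MISSING, dtype=np.int8)
                for s in range(len(line_ids)):
                    a, b = calls[s]
                    if a < 0 or b < 0:
                        continue
                    n_alt = int(a == ai) + int(b == ai)
                    # calls involving a different alt allele stay missing
                    if {a, b} - {0, ai}:
                        continue
                    codes[s] = (HOM_REF, HET, HOM_ALT)[n_alt]
                rows.append((v.CHROM, v.POS, v.REF, alt))
                geno.append(codes)
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        genotypes = (
            np.array(geno, dtype=np.int8)
            if geno
            else np.empty((0, len(line_ids)), dtype=np.int8)
        )
        return cls(sites, line_ids, genotypes)


@dataclass
class Bulk:
    """A named set of panel lines sharing a phenotype class."""

    name: str
    phenotype_class: str  # "resistant" | "sensitive"
    line_ids: list

    def __post_init__(self):
        if not self.line_ids:
            raise ValueError(f"bulk {self.name} is empty")
        if self.phenotype_class not in ("resistant", "sensitive"):
            raise ValueError("phenotype_class must be 'resistant' or 'sensitive'")


@dataclass
class BsaPolicy:
    """Evaluability rules for the concordance filter.

    ``min_called``: minimum non-missing calls required per bulk (default:
    every line, i.e. a missing call fails the SNP). ``ignore_het``: treat
    heterozygous calls as missing instead of failing the SNP outright.
    """

    min_called: int | None = None
    ignore_het: bool = False


@dataclass
class BsaResult:
    passing: pd.DataFrame  # chrom, pos, ref, alt, bulk_r_allele, bulk_s_allele
    interval: tuple | None  # (chrom, min_pos, max_pos) or None
    span_kb: int | None
    n_passing: int = 0
    pass_mask: np.ndarray = field(default=None, repr=False)


def build_bulks(phenotypes, k: int = 5, labels: dict | None = None) -> tuple[Bulk, Bulk]:
    """Choose contrasting bulks from panel phenotypes.

    With explicit ``labels`` (line id -> 'resistant'/'sensitive') the bulks
    are exactly as labelled and ``phenotypes``/``k`` are ignored. Otherwise
    ``phenotypes`` maps line id -> injury index; the k lowest-injury lines
    form the resistant bulk and the k highest the sensitive bulk. Ties that
    straddle either cut are refused, since the choice would be arbitrary.
    """
    if labels is not None:
        res = [l for l, c in labels.items() if c == "resistant"]
        sen = [l for l, c in labels.items() if c == "sensitive"]
        if set(res) & set(sen):
            raise ValueError("a line cannot belong to both bulks")
        return (
            Bulk("bulk_R", "resistant", res),
            Bulk("bulk_S", "sensitive", sen),
        )
    if k <= 0:
        raise ValueError("bulk size k must be positive")
    s = pd.Series(phenotypes).astype(float)
    if len(s) < 2 * k:
        raise ValueError(f"need at least {2 * k} lines for two bulks of {k}")
    ranked = s.sort_values(kind="stable")
    low, high = ranked.iloc[:k], ranked.iloc[::-1].iloc[:k]
    if (ranked.iloc[k - 1] == ranked.iloc[k]) or (
        ranked.iloc[-k] == ranked.iloc[-k - 1]
    ):
        raise ValueError(
            "phenotype ties straddle a bulk cut; supply explicit class labels"
        )
    return (
        Bulk("bulk_R", "resistant", list(low.index)),
        Bulk("bulk_S", "sensitive", list(high.index)),
    )


def extract_region(variants: VariantTable, chrom, start: int, end: int) -> VariantTable:
    """SNPs with start <= pos <= end on one chromosome (1-based inclusive)."""
    if start > end:
        raise ValueError("region start exceeds end")
    if variants.n_snps and chrom not in set(variants.sites["chrom"]):
        warnings.warn(f"chromosome {chrom!r} not present in variant table", stacklevel=2)
    mask = (
        (variants.sites["chrom"] == chrom)
        & (variants.sites["pos"] >= start)
        & (variants.sites["pos"] <= end)
    ).to_numpy()
    return variants.subset(mask)


def _bulk_consensus(calls: np.ndarray, policy: BsaPolicy, bulk_size: int) -> np.ndarray:
    """Per-SNP consensus allele of one bulk: 0/2, or -1 where the bulk fails.

    calls: (n_snps, n_lines_in_bulk). A bulk passes at a SNP when all
    evaluable calls are the same homozygous allele and at least
    ``min_called`` calls are evaluable.
    """
    min_called = policy.min_called if policy.min_called is not None else bulk_size
    evaluable = calls != MISSING
    if policy.ignore_het:
        evaluable &= calls != HET
        has_het = np.zeros(calls.shape[0], dtype=bool)
    else:
        has_het = (calls == HET).any(axis=1)
    n_eval = evaluable.sum(axis=1)
    any_ref = ((calls == HOM_REF) & evaluable).any(axis=1)
    any_alt = ((calls == HOM_ALT) & evaluable).any(axis=1)
    ok = (n_eval >= max(min_called, 1)) & ~has_het & (any_ref ^ any_alt)
    consensus = np.full(calls.shape[0], MISSING, dtype=np.int8)
    consensus[ok & any_ref] = HOM_REF
    consensus[ok & any_alt] = HOM_ALT
    return consensus


def concordance_filter(
    variants: VariantTable,
    bulk_r: Bulk,
    bulk_s: Bulk,
    policy: BsaPolicy | None = None,
) -> BsaResult:
    """Retain SNPs identical within each bulk and different between bulks.

    Under the default strict policy a heterozygous call anywhere in either
    bulk fails the SNP (these are inbred lines; residual heterozygosity or a
    call error makes the site undiagnostic), as does any missing call.
    """
    policy = policy or BsaPolicy()
    missing_lines = (set(bulk_r.line_ids) | set(bulk_s.line_ids)) - set(variants.line_ids)
    if missing_lines:
        raise ValueError(f"bulk lines absent from variant table: {sorted(missing_lines)}")
    if set(bulk_r.line_ids) & set(bulk_s.line_ids):
        raise ValueError("bulks are not disjoint")

    if variants.n_snps == 0:
        empty = variants.sites.assign(bulk_r_allele="", bulk_s_allele="")
        return BsaResult(empty, None, None, 0, np.zeros(0, dtype=bool))

    calls_r = variants.line_columns(bulk_r.line_ids)
    calls_s = variants.line_columns(bulk_s.line_ids)
    cons_r = _bulk_consensus(calls_r, policy, len(bulk_r.line_ids))
    cons_s = _bulk_consensus(calls_s, policy, len(bulk_s.line_ids))
    passing = (cons_r != MISSING) & (cons_s != MISSING) & (cons_r != cons_s)

    def allele(row, code):
        return row["ref"] if code == HOM_REF else row["alt"]

    table = variants.sites.loc[passing].reset_index(drop=True).copy()
    table["bulk_r_allele"] = [
        allele(row, c) for (_, row), c in zip(table.iterrows(), cons_r[passing])
    ]
    table["bulk_s_allele"] = [
        allele(row, c) for (_, row), c in zip(table.iterrows(), cons_s[passing])
    ]

    if passing.any():
        chrom, lo, hi, kb = candidate_region(table)
        interval, span = (chrom, lo, hi), kb
    else:
        interval, span = None, None
    return BsaResult(table, interval, span, int(passing.sum()), passing)


def span_kb(start: int, end: int) -> int:
    """Interval span in whole kb (truncated), for 1-based inclusive bounds."""
    if end < start:
        raise ValueError("end precedes start")
    return (end - start) // 1000


def candidate_region(passing: pd.DataFrame) -> tuple:
    """Bounding interval of the passing SNPs: (chrom, min pos, max pos, kb).

    Raises when no SNP passed the concordance filter.
    """
    if passing is None or len(passing) == 0:
        raise ValueError("no concordant SNPs: candidate region undefined")
    chroms = set(passing["chrom"])
    if len(chroms) > 1:
        raise ValueError(f"passing SNPs span multiple chromosomes: {sorted(chroms)}")
    lo = int(passing["pos"].min())
    hi = int(passing["pos"].max())
    return (next(iter(chroms)), lo, hi, span_kb(lo, hi))
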