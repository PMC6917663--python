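"""Synthetic study data: F2:3 cross, germplasm panel, toy locus, qPCR table.

Every input the pipeline consumes can be generated here under a single seed:

* an F2 intercross of 189 individuals on a seven-chromosome map (about 190
  markers, ~990 cM total, mirroring the real map's scale), segregating three
  QTLs of unequal effect for a liability that is scored as ordinal injury
  grades {0,1,3,5,7,9} on selfed F3 families (3 replicates x 8 plants);
* a resequenced panel of 10 inbred lines in two phenotype classes carrying a
  planted diagnostic haplotype block inside a known window of the major-QTL
  region, written as VCF;
* a small annotated locus (FASTA + GFF3 + SNPs) for codon-level effect calls;
* a qPCR Ct table over the cold time course for expression validation.

Gametes are generated by a Markov walk along each chromosome with
inter-marker recombination probabilities from the (Haldane, by default) map
function; there is no crossover interference or epistasis. F3 family
genotypes are drawn per QTL independently from the F2 parent's selfing
distribution, ignoring within-family linkage between QTLs — adequate at this
scale, and documented as an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa import HET, HOM_ALT, HOM_REF, MISSING, VariantTable
from .annotate import GeneModel
from .linkage import GeneticMap, GenotypeMatrix
from .mapfun import get_map_function
from .phenotype import GRADES
from .validate import CT_COLUMNS, TIMEPOINTS_H

__all__ = [
    "ChromSpec",
    "QTLSpec",
    "CrossSimConfig",
    "PanelSimConfig",
    "F2Simulation",
    "PanelSimulation",
    "default_chromosomes",
    "default_qtls",
    "default_polygenic_sd",
    "calibrate_additive_effects",
    "calibrate_family_variance",
    "simulate_f2",
    "simulate_family_phenotypes",
    "simulate_panel",
    "simulate_ct_table",
    "make_toy_locus",
    "write_vcf",
    "write_fixture_bundle",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromSpec:
    """Marker scaffold of one chromosome: cM and bp positions, co-sorted."""

    name: str
    cm: tuple
    bp: tuple

    def __post_init__(self):
        cm = np.asarray(self.cm, float)
        bp = np.asarray(self.bp, float)
        if len(cm) != len(bp) or len(cm) == 0:
            raise ValueError(f"chromosome {self.name}: cM/bp lists must match")
        if np.any(np.diff(cm) < 0) or np.any(np.diff(bp) <= 0):
            raise ValueError(f"chromosome {self.name}: marker positions must increase")

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])


@dataclass(frozen=True)
class QTLSpec:
    """One simulated QTL: location plus additive and dominance effects.

    ``add_effect`` is the liability-scale deviation of the sensitive-parent
    homozygote from the genotype midpoint (positive = more injury);
    ``dom_effect`` the heterozygote's deviation from that midpoint.
    """

    chrom: str
    cm: float
    add_effect: float
    dom_effect: float = 0.0
    name: str = ""


def default_chromosomes(
    n_chrom: int = 7,
    markers_per_chrom: int = 27,
    spacing_cm: float = 5.4,
    bp_per_cm: float = 200_000.0,
) -> list[ChromSpec]:
    """Seven ~140-cM chromosomes, 27 markers each (189 markers, ~983 cM).

    The scale matches the real map (190 markers, 990.8 cM, 5.2 cM mean
    spacing). Physical positions use a uniform 200 kb/cM.
    """
    chroms = []
    for c in range(1, n_chrom + 1):
        cm = tuple(round(i * spacing_cm, 6) for i in range(markers_per_chrom))
        bp = tuple(int(x * bp_per_cm) + 1 for x in cm)
        chroms.append(ChromSpec(name=str(c), cm=cm, bp=bp))
    return chroms


def calibrate_family_variance(
    pve_targets: dict,
    repeatability: float | None = None,
    residual_sd: float = 1.5,
    plants_per_family: int = 24,
    dom_ratio: float = -0.5,
    grade_quant_var: float = 1.0 / 3.0,
) -> tuple[dict, float]:
    """QTL effects (and polygenic SD) giving target variance fractions.

    For an F2:3 design with family means over ``m`` plants, a QTL with
    additive effect a and dominance d = dom_ratio * a contributes
    among-family variance a^2/2 + d^2/16 and (for heterozygous parents)
    within-family genetic variance averaging a^2/4 + d^2/8. The grade scale
    adds roughly bin_width^2/12 of quantisation variance per plant
    (``grade_quant_var``; the middle grade bins are 2 units wide). A
    family-level polygenic effect (shared between experiments, like the QTL
    genotypes) can be sized so the expected between-experiment correlation
    of family means equals ``repeatability``; that requires
    repeatability > sum of the QTL fractions. Solving the resulting linear
    system gives the per-QTL additive effects and the polygenic SD.

    Returns ``({qtl_name: additive_effect}, polygenic_sd)``.
    """
    f = np.array(list(pve_targets.values()), float)
    if np.any(f <= 0) or f.sum() >= 1:
        raise ValueError("variance fractions must be positive and sum to < 1")
    c1 = 0.5 + dom_ratio**2 / 16.0
    c2 = 0.25 + dom_ratio**2 / 8.0
    m = plants_per_family
    sigma0_sq = residual_sd**2 + grade_quant_var
    t = f.sum()
    pg_frac = 0.0
    if repeatability is not None:
        if not t < repeatability < 1:
            raise ValueError(
                "repeatability must exceed the summed QTL fractions and be < 1"
            )
        pg_frac = repeatability - t
    denom = 1.0 - t - pg_frac - t * c2 / (c1 * m)
    if denom <= 0:
        raise ValueError("requested variance fractions are unattainable")
    v_total = sigma0_sq / m / denom
    effects = np.sqrt(f * v_total / c1)
    polygenic_sd = float(np.sqrt(pg_frac * v_total))
    return dict(zip(pve_targets.keys(), effects.tolist())), polygenic_sd


def calibrate_additive_effects(pve_targets: dict, **kwargs) -> dict:
    """Additive effects for target variance fractions (no polygenic term)."""
    effects, _ = calibrate_family_variance(pve_targets, repeatability=None, **kwargs)
    return effects


#: Per-QTL family-mean variance fractions echoing the mapped loci, and the
#: between-experiment repeatability of family means.
DEFAULT_PVE_TARGETS = {"q5.1": 0.10, "q6.1": 0.09, "q6.2": 0.25}
DEFAULT_REPEATABILITY = 0.87


def _default_calibration() -> tuple[dict, float]:
    return calibrate_family_variance(DEFAULT_PVE_TARGETS, DEFAULT_REPEATABILITY)


def default_polygenic_sd() -> float:
    return _default_calibration()[1]


def default_qtls() -> list[QTLSpec]:
    """Three QTLs of unequal effect, echoing the mapped loci.

    One minor QTL on chromosome 5 (~10% of family-mean variance), a minor
    and a major QTL on chromosome 6 (~9% and ~25%). Dominance is set to
    -a/2, i.e. partial dominance of the tolerant allele, consistent with an
    F1 leaning toward the tolerant parent.
    """
    effects = _default_calibration()[0]
    locs = {"q5.1": ("5", 66.9), "q6.1": ("6", 63.1), "q6.2": ("6", 113.2)}
    return [
        QTLSpec(
            chrom=locs[name][0],
            cm=locs[name][1],
            add_effect=a,
            dom_effect=-0.5 * a,
            name=name,
        )
        for name, a in effects.items()
    ]


@dataclass
class CrossSimConfig:
    """Study conditions for the simulated F2:3 cross."""

    n_individuals: int = 189
    chromosomes: list = field(default_factory=default_chromosomes)
    qtls: list = field(default_factory=default_qtls)
    polygenic_sd: float = field(default_factory=default_polygenic_sd)
    residual_sd: float = 1.5
    liability_mean: float = 4.5
    grade_cuts: tuple = (0.5, 2.0, 4.0, 6.0, 8.0)
    n_replicates: int = 3
    plants_per_replicate: int = 8
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least two F2 individuals")
        cuts = np.asarray(self.grade_cuts, float)
        if len(cuts) != 5 or np.any(np.diff(cuts) <= 0):
            raise ValueError("grade_cuts must be 5 strictly increasing thresholds")
        by_name = {c.name: c for c in self.chromosomes}
        for q in self.qtls:
            if q.chrom not in by_name:
                raise ValueError(f"QTL chromosome {q.chrom!r} not in the map")
            c = by_name[q.chrom]
            if not (c.cm[0] <= q.cm <= c.cm[-1]):
                raise ValueError(
                    f"QTL at {q.cm} cM lies outside chromosome {q.chrom} "
                    f"({c.cm[0]}-{c.cm[-1]} cM)"
                )


@dataclass
class F2Simulation:
    """Simulated F2 genotypes with the generating map and true QTL genotypes.

    ``polygenic`` is the family-level polygenic liability deviation of each
    F2 individual — a property of the family, so it is shared by every
    replicate and every phenotyping experiment on the same cross.
    """

    genotypes: GenotypeMatrix
    gmap: GeneticMap
    qtl_genotypes: pd.DataFrame  # individuals x QTL names, codes 0/1/2
    config: CrossSimConfig
    polygenic: np.ndarray = None


def _simulate_gametes(rng, positions_cm: np.ndarray, n_gametes: int, to_r) -> np.ndarray:
    """Markov walk along one chromosome: allele (0/1) per gamete per locus."""
    n_loci = len(positions_cm)
    alleles = np.empty((n_gametes, n_loci), dtype=np.int8)
    alleles[:, 0] = rng.integers(0, 2, size=n_gametes)
    rs = to_r(np.diff(positions_cm))
    for j in range(1, n_loci):
        flip = rng.random(n_gametes) < rs[j - 1]
        alleles[:, j] = np.where(flip, 1 - alleles[:, j - 1], alleles[:, j - 1])
    return alleles


def simulate_f2(config: CrossSimConfig) -> F2Simulation:
    """Simulate an F2 population by uniting two independent F1 gametes.

    QTL positions are inserted into each chromosome's locus list for the
    gamete walk and then separated from the marker columns, so the true QTL
    genotype of every individual is linked to its flanking markers exactly
    as the map function dictates. Allele code counts the sensitive-parent
    allele: 0 = AA (tolerant homozygote), 1 = AB, 2 = BB.
    """
    rng = np.random.default_rng(config.seed)
    to_r, _ = get_map_function(config.map_function)
    n = config.n_individuals

    ids = [f"F2_{i + 1:03d}" for i in range(n)]
    marker_cols, marker_rows = [], []
    qtl_cols = {}
    for chrom in config.chromosomes:
        mcm = np.asarray(chrom.cm, float)
        qtls_here = [q for q in config.qtls if q.chrom == chrom.name]
        qcm = np.array([q.cm for q in qtls_here], float)
        all_cm = np.unique(np.concatenate([mcm, qcm])) if len(qcm) else mcm
        gametes = _simulate_gametes(rng, all_cm, 2 * n, to_r)
        geno = gametes[:n] + gametes[n:]  # codes 0/1/2

        pos_index = {c: j for j, c in enumerate(all_cm)}
        for mid_cm, bp, k in zip(mcm, chrom.bp, range(len(mcm))):
            marker_id = f"M{chrom.name}_{k + 1:02d}"
            marker_rows.append((marker_id, chrom.name, float(mid_cm), int(bp)))
            marker_cols.append(geno[:, pos_index[mid_cm]])
        for q in qtls_here:
            qtl_cols[q.name or f"q{q.chrom}@{q.cm}"] = geno[:, pos_index[q.cm]]

    codes = np.column_stack(marker_cols).astype(np.int8)
    gmap = GeneticMap(
        pd.DataFrame(marker_rows, columns=["marker_id", "chrom", "cm", "bp"])
    )
    genotypes = GenotypeMatrix(ids, list(gmap.markers["marker_id"]), codes)
    qtl_geno = pd.DataFrame(qtl_cols, index=ids)
    polygenic = rng.normal(0.0, config.polygenic_sd, size=n)
    return F2Simulation(genotypes, gmap, qtl_geno, config, polygenic)


def simulate_family_phenotypes(
    sim: F2Simulation,
    config: CrossSimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Injury-grade tallies for the F3 family of every F2 individual.

    Each family is phenotyped as ``n_replicates`` replicates of
    ``plants_per_replicate`` selfed F3 plants. Per plant and per QTL the
    genotype is drawn from the parent's selfing distribution (AA -> AA,
    BB -> BB, AB -> 1/4 AA : 1/2 AB : 1/4 BB, independently across QTLs);
    liability = mean + sum of QTL effects + Normal(0, residual_sd), and the
    grade is the liability's bin under ``grade_cuts``.

    Returns the phenotype CSV schema: family_id, replicate, S0..S9.
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(sim.qtl_genotypes)
    reps, m = config.n_replicates, config.plants_per_replicate
    n_plants = reps * m

    liability = np.full((n, n_plants), config.liability_mean)
    if sim.polygenic is not None:
        liability += sim.polygenic[:, None]
    for q in config.qtls:
        parent = sim.qtl_genotypes[q.name].to_numpy()[:, None]  # (n, 1)
        drawn = rng.binomial(2, 0.5, size=(n, n_plants))
        plant = np.where(parent == 1, drawn, parent)
        liability += q.add_effect * (plant - 1) + q.dom_effect * (plant == 1)
    liability += rng.normal(0.0, config.residual_sd, size=(n, n_plants))

    grade_idx = np.digitize(liability, np.asarray(config.grade_cuts, float))
    rows = []
    grade_values = np.asarray(GRADES)
    for i, fam in enumerate(sim.qtl_genotypes.index):
        for r in range(reps):
            sel = grade_idx[i, r * m : (r + 1) * m]
            counts = [(sel == g).sum() for g in range(len(grade_values))]
            rows.append((fam, r + 1, *counts))
    return pd.DataFrame(
        rows, columns=["family_id", "replicate", "S0", "S1", "S3", "S5", "S7", "S9"]
    )


# ---------------------------------------------------------------------------
# germplasm panel


@dataclass
class PanelSimConfig:
    """Study conditions for the resequenced germplasm panel.

    Defaults emulate the real design: five resistant and five sensitive
    lines, the major-QTL physical region on chromosome 6, and a diagnostic
    block of 214 concordant SNPs confined to the 42-kb candidate window.
    """

    n_per_class: int = 5
    region: tuple = ("6", 20_591_185, 21_186_690)
    diagnostic_window: tuple = (20_779_616, 20_821_620)
    n_diagnostic_snps: int = 214
    n_background_snps: int = 600
    missing_rate: float = 0.02
    het_rate: float = 0.02
    exclude_concordant_background: bool = True
    seed: int = 0

    def __post_init__(self):
        chrom, start, end = self.region
        ws, we = self.diagnostic_window
        if not (start <= ws <= we <= end):
            raise ValueError("diagnostic window must lie inside the region")
        for rate in (self.missing_rate, self.het_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("need at least one line per class")


@dataclass
class PanelSimulation:
    variants: VariantTable
    classes: dict  # line id -> "resistant" | "sensitive"
    diagnostic_positions: np.ndarray
    config: PanelSimConfig


def simulate_panel(config: PanelSimConfig) -> PanelSimulation:
    """Simulate the 10-line panel with a planted diagnostic haplotype block.

    Diagnostic SNPs are homozygous, identical within each phenotype class
    and different between classes. Background SNPs get class-independent
    random homozygous alleles, with heterozygous and missing calls injected
    at the configured rates (never at diagnostic SNPs). By default a
    background SNP that happens to mimic the diagnostic pattern is redrawn
    (``exclude_concordant_background``), so the planted window is the unique
    concordant signal; switch it off to study chance concordance.
    """
    rng = np.random.default_rng(config.seed)
    chrom, start, end = config.region
    ws, we = config.diagnostic_window
    lines = [f"R{i + 1}" for i in range(config.n_per_class)] + [
        f"S{i + 1}" for i in range(config.n_per_class)
    ]
    classes = {l: ("resistant" if l.startswith("R") else "sensitive") for l in lines}
    n_lines = len(lines)

    diag_pos = np.sort(
        rng.choice(np.arange(ws, we + 1), size=config.n_diagnostic_snps, replace=False)
    )
    pool = np.setdiff1d(np.arange(start, end + 1), diag_pos, assume_unique=False)
    bg_pos = np.sort(rng.choice(pool, size=config.n_background_snps, replace=False))

    pos = np.concatenate([diag_pos, bg_pos])
    is_diag = np.concatenate(
        [np.ones(len(diag_pos), bool), np.zeros(len(bg_pos), bool)]
    )
    order = np.argsort(pos, kind="stable")
    pos, is_diag = pos[order], is_diag[order]
    n_snps = len(pos)

    ref = rng.choice(BASES, size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)
    alt = BASES[(np.searchsorted(BASES, ref) + shift) % 4]

    geno = np.empty((n_snps, n_lines), dtype=np.int8)
    res_mask = np.array([classes[l] == "resistant" for l in lines])
    # diagnostic rows: one class hom-ref, the other hom-alt, orientation random
    res_is_ref = rng.random(n_snps) < 0.5
    diag_rows = np.where(is_diag)[0]
    for i in diag_rows:
        r_code = HOM_REF if res_is_ref[i] else HOM_ALT
        s_code = HOM_ALT if res_is_ref[i] else HOM_REF
        geno[i] = np.where(res_mask, r_code, s_code)
    # background rows: class-independent alleles plus het/missing noise
    bg_rows = np.where(~is_diag)[0]

    def draw_background(k: int) -> np.ndarray:
        hom = rng.choice([HOM_REF, HOM_ALT], size=(k, n_lines))
        het = rng.random((k, n_lines)) < config.het_rate
        miss = rng.random((k, n_lines)) < config.missing_rate
        calls = np.where(het, HET, hom)
        return np.where(miss, MISSING, calls).astype(np.int8)

    def mimics_diagnostic(calls: np.ndarray) -> np.ndarray:
        res = calls[:, res_mask]
        sen = calls[:, ~res_mask]
        clean = ((calls == HOM_REF) | (calls == HOM_ALT)).all(axis=1)
        res_same = (res == res[:, :1]).all(axis=1)
        sen_same = (sen == sen[:, :1]).all(axis=1)
        return clean & res_same & sen_same & (res[:, 0] != sen[:, 0])

    if len(bg_rows):
        calls = draw_background(len(bg_rows))
        if config.exclude_concordant_background:
            for _ in range(1000):
                bad = mimics_diagnostic(calls)
                if not bad.any():
                    break
                calls[bad] = draw_background(int(bad.sum()))
        geno[bg_rows] = calls

    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    )
    variants = VariantTable(sites, lines, geno)
    diag_sorted = np.sort(diag_pos)
    return PanelSimulation(variants, classes, diag_sorted, config)


_VCF_CODE = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(variants: VariantTable, path, contig_lengths: dict | None = None):
    """Write a variant table as VCF v4.2 (GT only)."""
    path = Path(path)
    lengths = dict(contig_lengths or {})
    for chrom, sub in variants.sites.groupby("chrom", sort=False):
        lengths.setdefault(chrom, int(sub["pos"].max()) + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ltqtl-synthetic-panel\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.line_ids)
            + "\n"
        )
        for i, row in variants.sites.iterrows():
            calls = "\t".join(_VCF_CODE[int(c)] for c in variants.genotypes[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
    return path


# ---------------------------------------------------------------------------
# toy annotated locus


def make_toy_locus(seed: int = 0):
    """A 12-kb contig with three toy genes and a handful of SNPs.

    Returns ``(genome, models, snps)`` where genome maps contig -> sequence
    string, models are :class:`GeneModel` on both strands, and snps are
    (chrom, pos, ref, alt) tuples hitting CDS, intron and intergenic space.
    Used by the demo pipeline for end-to-end effect annotation.
    """
    rng = np.random.default_rng(seed)
    length = 12_000
    seq = rng.choice(BASES, size=length)
    genome = {"toy_chr6": "".join(seq)}
    models = [
        GeneModel(
            gene_id="toyARF",
            chrom="toy_chr6",
            start=1001,
            end=3400,
            strand="+",
            exons=[(1001, 1600), (2001, 2800)],
            cds=[(1201, 1600), (2001, 2602)],
        ),
        GeneModel(
            gene_id="toyEIN2",
            chrom="toy_chr6",
            start=5001,
            end=8000,
            strand="-",
            exons=[(5001, 5900), (6501, 7800)],
            cds=[(5101, 5900), (6501, 7500)],
        ),
        GeneModel(
            gene_id="toyCASP",
            chrom="toy_chr6",
            start=9001,
            end=9903,
            strand="+",
            exons=[(9001, 9903)],
            cds=[(9001, 9903)],
        ),
    ]
    snp_positions = [1300, 1650, 2050, 5500, 6200, 7000, 9500, 11000]
    snps = []
    for pos in snp_positions:
        ref = genome["toy_chr6"][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snps.append(("toy_chr6", pos, ref, str(alt)))
    return genome, models, snps


def write_fasta(genome: dict, path, width: int = 70):
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_gff3(models, path):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chrom}\tltqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tltqtl\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tltqtl\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            phase = 0
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            for s, e in cds:
                fh.write(
                    f"{g.chrom}\tltqtl\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={mrna}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    return path


# ---------------------------------------------------------------------------
# qPCR table


#: Per-timepoint log2 fold-change profiles of the demo genes under cold.
_EXPRESSION_PROFILES = {
    # gene -> {line class -> log2 fold per timepoint}
    "toyARF": {
        "tolerant": (0.0, 0.6, 1.2, 1.9, 2.6, 2.3, 1.9, 1.5, 1.2, 1.0),
        "sensitive": (0.0, 0.1, 0.2, 0.3, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1),
    },
    "toyEIN2": {
        "tolerant": (0.0, 0.4, 1.0, 1.6, 2.1, 2.4, 2.0, 1.6, 1.3, 1.1),
        "sensitive": (0.0, 0.1, 0.3, 0.3, 0.4, 0.4, 0.3, 0.2, 0.2, 0.1),
    },
    "toyCASP": {
        "tolerant": (0.0,) * 10,
        "sensitive": (0.0,) * 10,
    },
}


def simulate_ct_table(
    seed: int = 0,
    lines: dict | None = None,
    genes=("toyARF", "toyEIN2", "toyCASP"),
    n_bio: int = 3,
    n_tech: int = 3,
    reference_ct: float = 18.0,
    baseline_dct: float = 6.0,
    bio_sd: float = 0.25,
    tech_sd: float = 0.12,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for a tolerant vs sensitive line pair.

    Target Ct = reference Ct + baseline dCt - log2(fold(t)) + replicate
    noise, so the 2^-ddCt analysis recovers the planted fold profiles. Two
    genes are cold-induced in the tolerant line only; one is unresponsive.
    """
    lines = lines or {"CG104": "tolerant", "CG37": "sensitive"}
    rng = np.random.default_rng(seed)
    rows = []
    for line, cls in lines.items():
        for gene in genes:
            profile = _EXPRESSION_PROFILES[gene][cls]
            for t, log2fc in zip(TIMEPOINTS_H, profile):
                for b in range(1, n_bio + 1):
                    bio_shift = rng.normal(0.0, bio_sd)
                    for k in range(1, n_tech + 1):
                        ct_ref = reference_ct + rng.normal(0.0, tech_sd)
                        ct_tgt = (
                            reference_ct
                            + baseline_dct
                            - log2fc
                            + bio_shift
                            + rng.normal(0.0, tech_sd)
                        )
                        rows.append((line, t, gene, round(ct_tgt, 4), round(ct_ref, 4), b, k))
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    out_dir,
    cross_config: CrossSimConfig | None = None,
    panel_config: PanelSimConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Emit every input file of the demo pipeline into ``out_dir``.

    Files: genotypes.csv, phenotypes_exp1.csv, phenotypes_exp2.csv,
    marker_map.csv, panel.vcf, panel_classes.csv, genes.gff3, genome.fasta,
    locus_snps.vcf, ct_table.csv, qtl_truth.csv. Byte-stable under a fixed
    seed. Returns a name -> Path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        streams = np.random.SeedSequence(seed).generate_state(4) % (2**31)
        cross_config = replace(
            cross_config or CrossSimConfig(), seed=int(streams[0])
        )
        panel_config = replace(
            panel_config or PanelSimConfig(), seed=int(streams[1])
        )
        pheno2_seed = int(streams[2])
        ct_seed = int(streams[3])
    else:
        cross_config = cross_config or CrossSimConfig()
        panel_config = panel_config or PanelSimConfig()
        pheno2_seed = cross_config.seed + 1001
        ct_seed = cross_config.seed + 2002

    paths = {}
    sim = simulate_f2(cross_config)
    paths["genotypes"] = out / "genotypes.csv"
    sim.genotypes.to_csv(paths["genotypes"])
    paths["marker_map"] = out / "marker_map.csv"
    sim.gmap.to_csv(paths["marker_map"])
    paths["qtl_truth"] = out / "qtl_truth.csv"
    sim.qtl_genotypes.rename_axis("individual_id").to_csv(paths["qtl_truth"])

    pheno1 = simulate_family_phenotypes(sim, cross_config)
    pheno2 = simulate_family_phenotypes(sim, cross_config, seed=pheno2_seed)
    paths["phenotypes_exp1"] = out / "phenotypes_exp1.csv"
    paths["phenotypes_exp2"] = out / "phenotypes_exp2.csv"
    pheno1.to_csv(paths["phenotypes_exp1"], index=False)
    pheno2.to_csv(paths["phenotypes_exp2"], index=False)

    panel = simulate_panel(panel_config)
    paths["panel_vcf"] = out / "panel.vcf"
    write_vcf(panel.variants, paths["panel_vcf"])
    paths["panel_classes"] = out / "panel_classes.csv"
    pd.Series(panel.classes, name="phenotype_class").rename_axis("line_id").to_csv(
        paths["panel_classes"]
    )

    genome, models, snps = make_toy_locus(seed=cross_config.seed)
    paths["genome_fasta"] = out / "genome.fasta"
    write_fasta(genome, paths["genome_fasta"])
    paths["genes_gff3"] = out / "genes.gff3"
    write_gff3(models, paths["genes_gff3"])
    locus_sites = pd.DataFrame(snps, columns=["chrom", "pos", "ref", "alt"])
    locus_vt = VariantTable(
        locus_sites, ["CG104", "CG37"],
        np.tile([[HOM_REF, HOM_ALT]], (len(locus_sites), 1)).astype(np.int8),
    )
    paths["locus_snps"] = out / "locus_snps.vcf"
    write_vcf(locus_vt, paths["locus_snps"], {"toy_chr6": len(genome["toy_chr6"])})

    paths["ct_table"] = out / "ct_table.csv"
    simulate_ct_table(seed=ct_seed).to_csv(paths["ct_table"], index=False)
    return paths
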